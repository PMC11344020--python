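"""Latent-normal AR(1) eGFR panels for censored-regression recovery studies.

The cohort simulator produces regime-conditional *truncated* eGFR draws —
the right behaviour for projection, but not the data-generating process the
censored-normal (Tobit) likelihood assumes. Recovery experiments for
:func:`riskpath.estimate.fit_tobit` therefore use this generator: eGFR
evolves as an uncensored latent AR(1) normal around the chosen regime's
linear predictor, and censoring is applied only at fitting time (values
beyond the regime limit contribute probability mass, as in the estimator's
own model class).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._covariates import DURATION_FLOOR
from .coeffs import CoefficientBundle, TobitCoefficients
from .estimate import PanelDataset
from .synthdata import CohortSpec, generate_cohort


def generate_tobit_panel(coef: TobitCoefficients, n_patients: int = 10000,
                         follow_up: int = 6, seed: int = 0,
                         cohort_spec: CohortSpec | None = None,
                         sbp_sd: float = 8.0) -> PanelDataset:
    """Panel whose eGFR follows ``coef``'s latent normal AR(1) exactly.

    Systolic blood pressure (a Tobit covariate) varies around each patient's
    baseline with SD ``sbp_sd``; all other covariates come from the baseline
    cohort. Year-1 eGFR seeds the recursion from the baseline value; the
    ``first:`` anchor is the year-1 value, as in trial panels.
    """
    spec = cohort_spec or CohortSpec(n_patients=n_patients, seed=seed)
    cohort = generate_cohort(spec, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 40417]))
    n = len(cohort)
    age = np.array([p.age_at_rand for p in cohort])
    dur0 = np.array([p.duration for p in cohort])
    sbp0 = np.array([p.current["sbp"] for p in cohort])
    e_base = np.array([p.egfr for p in cohort])
    ids = np.array([p.id for p in cohort], dtype=object)

    b = coef.betas
    rows = []
    sbp_prev = sbp0.copy()
    e_prev = e_base.copy()
    e_first = None
    for year in range(1, follow_up + 1):
        dur = dur0 + year
        anchor = e_prev if e_first is None else e_first
        mean = (b.get("constant", 0.0)
                + b.get("age_at_rand", 0.0) * age
                + b.get("first:egfr", 0.0) * anchor
                + b.get("lag:egfr", 0.0) * e_prev
                + b.get("lag:sbp", 0.0) * sbp_prev
                + b.get("ln_duration", 0.0) * np.log(np.maximum(dur, DURATION_FLOOR)))
        e_now = mean + rng.normal(0.0, coef.sigma, n)
        sbp_now = sbp0 + rng.normal(0.0, sbp_sd, n)
        rows.append(pd.DataFrame({
            "patient": ids, "year": year, "duration": dur,
            "age_at_rand": age, "female": [p.female for p in cohort],
            "ethnicity": [p.ethnicity for p in cohort],
            "smoker_baseline": [p.smoker_baseline for p in cohort],
            "sbp": sbp_now, "egfr": e_now}))
        if e_first is None:
            e_first = e_now.copy()
        e_prev, sbp_prev = e_now, sbp_now

    data = pd.concat(rows, ignore_index=True)
    for fac in ("hdl", "ldl", "hba1c", "haemoglobin", "heart_rate", "bmi"):
        data[fac] = np.nan
    events = pd.DataFrame(columns=["patient", "outcome", "entry", "time", "event"])
    return PanelDataset(data=data, events=events,
                        meta={"seed": int(seed), "generator": "tobit-latent"})
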