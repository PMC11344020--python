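"""Synthetic cohorts and panels.

The generators emulate a pooled contemporary type-2-diabetes trial population
(mean age ~64 at randomisation, mean diabetes duration ~16 years, mixed
sex/ethnicity/smoking, annual measurements over up to six years with
dropout). Baseline risk-factor means, SDs and correlations are clinically
plausible defaults, NOT estimates from any trial (patient-level baseline
tables are not public); every number is overridable through the spec
objects.

``generate_panel`` simulates forward from a known coefficient bundle with the
package's own stochastic engines, then degrades the data (measurement noise,
annual dropout, per-factor missingness), so the estimation modules can be
exercised end-to-end: the module's core contract is that fitting a generated
panel recovers the generating bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._covariates import RISK_FACTORS, OUTCOMES
from .coeffs import CoefficientBundle, default_bundle
from .estimate import PanelDataset
from .simulate import SimulationConfig, simulate_cohort
from .trajectory import PatientState

#: clinically plausible baseline distribution defaults (mean, SD); the eighth
#: variable is eGFR, drawn jointly with the seven dynamic factors
BASELINE_FACTORS = RISK_FACTORS + ("egfr",)
DEFAULT_MEANS = {"hdl": 1.1, "ldl": 2.2, "sbp": 135.0, "hba1c": 7.5,
                 "haemoglobin": 13.8, "heart_rate": 72.0, "bmi": 31.0,
                 "egfr": 75.0}
DEFAULT_SDS = {"hdl": 0.3, "ldl": 0.9, "sbp": 16.0, "hba1c": 1.2,
               "haemoglobin": 1.5, "heart_rate": 11.0, "bmi": 5.5,
               "egfr": 18.0}
#: physiological floors applied to baseline draws
FLOORS = {"hdl": 0.3, "ldl": 0.3, "sbp": 80.0, "hba1c": 4.5,
          "haemoglobin": 8.0, "heart_rate": 40.0, "bmi": 15.0, "egfr": 15.0}

#: plausibility ranges for the preprocessing filter (placeholder defaults —
#: the published range list is not reproduced here; override as needed)
DEFAULT_RANGES = {"hdl": (0.2, 5.0), "ldl": (0.2, 10.0), "sbp": (60.0, 250.0),
                  "hba1c": (3.0, 20.0), "haemoglobin": (5.0, 20.0),
                  "heart_rate": (30.0, 200.0), "bmi": (12.0, 70.0),
                  "egfr": (1.0, 250.0)}


def _default_corr() -> np.ndarray:
    """Mild positive exchangeable correlation with a few clinical pairs."""
    k = len(BASELINE_FACTORS)
    c = np.full((k, k), 0.05)
    np.fill_diagonal(c, 1.0)
    idx = {f: i for i, f in enumerate(BASELINE_FACTORS)}

    def put(a, b, r):
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r

    put("sbp", "bmi", 0.2)
    put("hdl", "bmi", -0.2)
    put("hdl", "ldl", 0.1)
    return c


@dataclass
class CohortSpec:
    """Baseline cohort distribution (trial-population anchors as defaults)."""

    n_patients: int = 1000
    age_mean: float = 64.0
    age_sd: float = 8.0
    duration_mean: float = 16.0          # lognormal mean, years
    duration_sdlog: float = 0.5
    female_prop: float = 0.30
    ethnicity_props: dict = field(default_factory=lambda: {
        "white": 0.75, "black": 0.06, "asian": 0.12, "other": 0.07})
    smoking_prev: float = 0.11
    factor_means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    factor_sds: dict = field(default_factory=lambda: dict(DEFAULT_SDS))
    corr: Optional[np.ndarray] = None
    flag_prevalence: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        props = self.ethnicity_props
        if any(not 0 <= v <= 1 for v in props.values()) or abs(sum(props.values()) - 1) > 1e-9:
            raise ValueError("ethnicity proportions must lie in [0,1] and sum to 1")
        if any(v < 0 for v in self.factor_sds.values()):
            raise ValueError("factor SDs must be >= 0")


@dataclass
class PanelSpec:
    """Cohort plus follow-up / degradation settings and a generating bundle."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    follow_up: int = 6
    dropout: float = 0.04                # annual probability after year 1
    noise_sd: dict = field(default_factory=dict)      # measurement noise
    missing_rate: dict = field(default_factory=dict)  # per factor, per row
    bundle: Optional[CoefficientBundle] = None

    def __post_init__(self):
        if self.follow_up < 2:
            raise ValueError("follow_up must be >= 2 (lag construction)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def nearest_positive_definite(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped repair of an infeasible correlation matrix."""
    w, v = np.linalg.eigh((corr + corr.T) / 2)
    if w.min() > 0:
        return corr
    w = np.clip(w, eps, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def generate_cohort(spec: CohortSpec, seed: Optional[int] = None):
    """Draw a baseline cohort; fully reproducible from the seed.

    Baseline ``current`` equals ``first_recorded``; condition flags are false
    unless ``spec.flag_prevalence`` sets baseline prevalences.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 12052]))
    n = spec.n_patients
    age = rng.normal(spec.age_mean, spec.age_sd, n)
    if spec.duration_sdlog > 0:
        mu_log = np.log(spec.duration_mean) - spec.duration_sdlog ** 2 / 2
        duration = rng.lognormal(mu_log, spec.duration_sdlog, n)
    else:
        duration = np.full(n, float(spec.duration_mean))
    duration = np.maximum(duration, 1.0)
    female = rng.uniform(size=n) < spec.female_prop
    eths = list(spec.ethnicity_props)
    eth = rng.choice(eths, size=n, p=[spec.ethnicity_props[e] for e in eths])
    smoker = rng.uniform(size=n) < spec.smoking_prev

    corr = spec.corr if spec.corr is not None else _default_corr()
    corr = np.asarray(corr, float)
    w = np.linalg.eigvalsh((corr + corr.T) / 2)
    if w.min() <= 0:
        import warnings
        warnings.warn("correlation matrix not positive definite; "
                      "applying nearest-PD repair")
        corr = nearest_positive_definite(corr)
    sds = np.array([spec.factor_sds[f] for f in BASELINE_FACTORS])
    means = np.array([spec.factor_means[f] for f in BASELINE_FACTORS])
    cov = corr * np.outer(sds, sds)
    z = rng.multivariate_normal(np.zeros(len(BASELINE_FACTORS)), cov, size=n,
                                method="cholesky" if sds.min() > 0 else "svd")
    vals = means + z
    for j, f in enumerate(BASELINE_FACTORS):
        vals[:, j] = np.maximum(vals[:, j], FLOORS[f])

    cohort = []
    for i in range(n):
        current = {f: float(vals[i, j]) for j, f in enumerate(RISK_FACTORS)}
        flags = {o: bool(rng.uniform() < spec.flag_prevalence.get(o, 0.0))
                 for o in OUTCOMES}
        cohort.append(PatientState(
            id=f"P{i:06d}", age_at_rand=float(age[i]), female=bool(female[i]),
            ethnicity=str(eth[i]), smoker_baseline=bool(smoker[i]),
            duration=float(duration[i]),
            current=current, first_recorded=dict(current),
            egfr=float(vals[i, -1]), egfr_first=float(vals[i, -1]),
            flags=flags))
    return cohort


def generate_panel(spec: PanelSpec, seed: Optional[int] = None) -> PanelDataset:
    """Simulate a trial-like panel from a known bundle.

    Runs the stochastic annual-cycle engine over ``follow_up`` years, records
    exact event/censoring times on the duration scale (entry truncation at
    the baseline duration), then applies measurement noise, annual dropout
    and per-factor missingness. With all three at zero the panel equals each
    patient's stochastic trajectory exactly.
    """
    bundle = spec.bundle if spec.bundle is not None else default_bundle()
    seed = spec.cohort.seed if seed is None else seed
    cohort = generate_cohort(replace(spec.cohort, seed=seed))
    config = SimulationConfig(horizon=spec.follow_up, mode="stochastic",
                              seed=seed, y_first_source="first_simulated")
    traj = simulate_cohort(bundle, cohort, config)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77001]))
    n = len(cohort)
    # observed years: everyone contributes year 1; each later year drops out
    # independently with the annual dropout probability (non-informative)
    if spec.dropout > 0:
        alive = rng.uniform(size=(n, spec.follow_up - 1)) >= spec.dropout
        observed_years = 1 + np.cumprod(alive, axis=1).sum(axis=1)
    else:
        observed_years = np.full(n, spec.follow_up)
    obs_map = {p.id: int(g) for p, g in zip(cohort, observed_years)}

    base_rows = []
    for p in cohort:
        row = {"patient": p.id, "year": 0, "duration": p.duration,
               "age_at_rand": p.age_at_rand, "female": p.female,
               "ethnicity": p.ethnicity, "smoker_baseline": p.smoker_baseline,
               "egfr": p.egfr}
        row.update({f: p.current[f] for f in RISK_FACTORS})
        base_rows.append(row)
    base = pd.DataFrame(base_rows)

    demo = base[["patient", "age_at_rand", "female", "ethnicity",
                 "smoker_baseline"]]
    sim = traj.data.merge(demo, on="patient", how="left")
    sim["obs"] = sim["patient"].map(obs_map)
    sim = sim[sim["year"] <= sim["obs"]]
    cols = ["patient", "year", "duration", "age_at_rand", "female",
            "ethnicity", "smoker_baseline"] + list(RISK_FACTORS) + ["egfr"]
    data = pd.concat([base[cols[:7] + list(RISK_FACTORS) + ["egfr"]],
                      sim[cols]], ignore_index=True)
    data = data.sort_values(["patient", "year"], ignore_index=True)

    # measurement degradation
    for fac in list(RISK_FACTORS) + ["egfr"]:
        sd = spec.noise_sd.get(fac, 0.0)
        post = data["year"] >= 1
        if sd > 0:
            data.loc[post, fac] += rng.normal(0.0, sd, post.sum())
        mr = spec.missing_rate.get(fac, 0.0)
        if mr > 0:
            drop = post & (rng.uniform(size=len(data)) < mr)
            data.loc[drop, fac] = np.nan

    ev = traj.event_times.copy()
    ev["censor"] = ev["patient"].map(obs_map) + ev["entry"]
    late = ev["time"] > ev["censor"]
    ev.loc[late, "event"] = False
    ev["time"] = np.minimum(ev["time"], ev["censor"])
    events = ev[["patient", "outcome", "entry", "time", "event"]].reset_index(drop=True)

    return PanelDataset(data=data, events=events,
                        meta={"seed": int(seed), "follow_up": spec.follow_up,
                              "dropout": spec.dropout,
                              "provenance": bundle.provenance})


def preprocess_panel(raw: pd.DataFrame, ranges: Optional[dict] = None,
                     demographics: Optional[pd.DataFrame] = None,
                     early_window_months: float = 6.0):
    """Annualise raw visit-level measurements with the trial exclusion rules.

    ``raw`` columns: patient, month (relative to randomisation; <= 0 is the
    randomisation/baseline visit), variable, value. Steps, each logged:

    * drop post-randomisation measurements made < ``early_window_months``
      after treatment start (initial treatment effect);
    * drop values outside the per-variable plausibility ``ranges``;
    * average measurements within each patient-year window (12-month windows
      from randomisation; baseline stays year 0);
    * exclude, per variable, patients with no baseline value and patients
      with a baseline value but no follow-up values;
    * exclude patients who withdrew on the randomisation day and (if
      ``demographics`` given) patients with missing ethnicity.

    Returns ``(annualised long DataFrame, exclusion log dict)``. The
    operation is idempotent: reapplying it to its own output is a no-op.
    """
    ranges = dict(DEFAULT_RANGES) if ranges is None else ranges
    log = {}
    df = raw.copy()
    n0 = len(df)
    bad = pd.to_numeric(df["value"], errors="coerce").isna()
    if bad.any():
        log["unparseable_rows"] = int(bad.sum())
        df = df[~bad]
    df["value"] = df["value"].astype(float)

    early = (df["month"] > 0) & (df["month"] < early_window_months)
    log["early_measurements_dropped"] = int(early.sum())
    df = df[~early]

    out_of_range = pd.Series(False, index=df.index)
    for var, (lo, hi) in ranges.items():
        m = df["variable"] == var
        out_of_range |= m & ((df["value"] < lo) | (df["value"] > hi))
    log["out_of_range_dropped"] = int(out_of_range.sum())
    df = df[~out_of_range]

    # withdrawal on randomisation day: no measurement after month 0 at all
    last = df.groupby("patient")["month"].max()
    withdrew = set(last[last <= 0].index)
    log["withdrew_at_randomisation"] = len(withdrew)
    df = df[~df["patient"].isin(withdrew)]

    if demographics is not None:
        miss = set(demographics.loc[demographics["ethnicity"].isna(), "patient"])
        log["missing_ethnicity"] = len(miss)
        df = df[~df["patient"].isin(miss)]

    year = np.where(df["month"] <= 0, 0, np.ceil(df["month"] / 12.0)).astype(int)
    df = df.assign(year=year)
    annual = (df.groupby(["patient", "variable", "year"], as_index=False)["value"]
              .mean())
    annual["month"] = np.where(annual["year"] == 0, 0.0, 12.0 * annual["year"] - 6.0)

    # per-variable exclusions: need a baseline value AND >= 1 follow-up value
    has_base = annual[annual["year"] == 0].set_index(["patient", "variable"]).index
    has_follow = (annual[annual["year"] >= 1]
                  .drop_duplicates(["patient", "variable"])
                  .set_index(["patient", "variable"]).index)
    key = pd.MultiIndex.from_frame(annual[["patient", "variable"]])
    keep = key.isin(has_base) & key.isin(has_follow)
    log["no_baseline_value"] = int((~key.isin(has_base)).sum())
    log["baseline_only"] = int((key.isin(has_base) & ~key.isin(has_follow)).sum())
    annual = annual[keep]

    annual = annual[["patient", "month", "variable", "value", "year"]]
    annual = annual.sort_values(["patient", "variable", "year"],
                                ignore_index=True)
    log["rows_in"] = n0
    log["rows_out"] = len(annual)
    return annual, log


def assemble_panel(annual: pd.DataFrame, demographics: pd.DataFrame,
                   events: Optional[pd.DataFrame] = None) -> PanelDataset:
    """Pivot preprocessed long data into a :class:`PanelDataset`.

    ``demographics`` columns: patient, age_at_rand, female, ethnicity,
    smoker_baseline, duration (diabetes duration at randomisation, years).
    """
    wide = (annual.pivot_table(index=["patient", "year"], columns="variable",
                               values="value", aggfunc="mean").reset_index())
    wide = wide.merge(demographics, on="patient", how="inner")
    wide["duration"] = wide["duration"] + wide["year"]
    for fac in list(RISK_FACTORS) + ["egfr"]:
        if fac not in wide.columns:
            wide[fac] = np.nan
    cols = ["patient", "year", "duration", "age_at_rand", "female",
            "ethnicity", "smoker_baseline"] + list(RISK_FACTORS) + ["egfr"]
    if events is None:
        events = pd.DataFrame(columns=["patient", "outcome", "entry",
                                       "time", "event"])
    return PanelDataset(data=wide[cols], events=events)
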