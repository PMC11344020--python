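"""Annual-cycle cohort simulator.

Each simulated year executes, for every patient still in the cohort (no
mortality is modelled — trajectories are conditional on survival):

1. **events** — annual Weibull probabilities for AF, albuminuria and PVD,
   evaluated on last year's risk-factor values; stochastic mode flips the
   absorbing flags by Monte Carlo, expected mode records probabilities only;
2. **eGFR** — the below-60 crossing (same Weibull machinery) followed by the
   regime-matched Tobit value, again from last year's values;
3. **continuous factors** — the seven dynamic equations advance one year.

All three sub-steps read the start-of-cycle (lagged) state, so their order
within a cycle does not affect results. An optional intervention applies a
one-off additive shift to the year-1 simulated values (and to the
first-recorded anchor, so the shift persists through the ``phi2`` channel),
mirroring the convention that modellers impose their own first-year treatment
effect and let the equations extrapolate afterwards.

Random-number discipline: every patient owns one substream per equation
(keyed by a hash of the patient id), so permuting the cohort permutes the
output rows only, common random numbers hold across scenario arms run with
the same seed, and adding an equation does not perturb the others' draws.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from ._covariates import (RISK_FACTORS, OUTCOMES, MissingCovariateError,
                          linear_predictor)
from .coeffs import (CoefficientBundle, DynamicCoefficients,
                     SurvivalCoefficients, TobitCoefficients)
from .egfr import (DEFAULT_EGFR_CAP, truncated_normal_mean,
                   truncated_normal_ppf)
from .trajectory import PatientState, deterministic_prediction

logger = logging.getLogger("riskpath.simulate")

# fixed registry of per-patient substreams; append-only so adding an
# equation never perturbs existing draws
_STREAMS = [f"dyn:{f}" for f in RISK_FACTORS] + [f"evt:{o}" for o in OUTCOMES] + ["egfr"]


@dataclass
class SimulationConfig:
    horizon: int = 10
    mode: str = "deterministic"            # deterministic | stochastic | expected
    seed: int = 0
    intervention: Optional[dict] = None    # risk factor -> additive year-1 shift
    y_first_source: str = "baseline"       # baseline | first_simulated
    clamp: bool = False
    clamp_ranges: Optional[dict] = None
    egfr_cap: float = DEFAULT_EGFR_CAP
    #: None follows ``mode``; "deterministic" holds the eGFR *value* draw at
    #: the truncated mean even in stochastic runs (the crossing stays Monte
    #: Carlo), which isolates event binarization from value-path noise
    egfr_value_mode: Optional[str] = None

    def __post_init__(self):
        if not 1 <= int(self.horizon) <= 70:
            raise ValueError("horizon must be in 1..70")
        if self.mode not in ("deterministic", "stochastic", "expected"):
            raise ValueError("mode must be deterministic|stochastic|expected")
        if self.y_first_source not in ("baseline", "first_simulated"):
            raise ValueError("y_first_source must be baseline|first_simulated")
        if self.intervention:
            unknown = set(self.intervention) - set(RISK_FACTORS)
            if unknown:
                raise ValueError(f"intervention names unknown factors: {sorted(unknown)}")


@dataclass
class CohortTrajectory:
    """Long simulation output: one record per patient per simulated year."""

    data: pd.DataFrame                     # patient, year, duration, factors, egfr, flags, probs
    event_times: Optional[pd.DataFrame]    # stochastic mode only: exact onset times
    config: SimulationConfig
    provenance: str = ""

    def to_long(self) -> pd.DataFrame:
        """(patient, year, variable, value) export format."""
        value_cols = [c for c in self.data.columns if c not in ("patient", "year")]
        out = self.data.melt(id_vars=["patient", "year"], value_vars=value_cols,
                             var_name="variable", value_name="value")
        return out.sort_values(["patient", "year", "variable"], kind="stable",
                               ignore_index=True)

    def write(self, path, sidecar=True) -> str:
        """Write delimited long-format output plus a run-metadata sidecar."""
        self.to_long().to_csv(path, sep="\t", index=False)
        if sidecar:
            meta = {"config": asdict(self.config), "provenance": self.provenance,
                    "n_patients": int(self.data["patient"].nunique()),
                    "n_records": int(len(self.data))}
            with open(str(path) + ".meta.json", "w", encoding="utf-8") as fh:
                json.dump(meta, fh, indent=1)
        return str(path)


class _CohortArrays:
    """Vectorised mirror of a list of PatientState, consumable by resolve()."""

    is_vectorized = True

    def __init__(self, cohort):
        n = len(cohort)
        self.ids = np.array([p.id for p in cohort], dtype=object)
        self.age_at_rand = np.array([p.age_at_rand for p in cohort], float)
        self.female = np.array([p.female for p in cohort], bool)
        self.ethnicity = np.array([p.ethnicity for p in cohort], object)
        self.smoker_baseline = np.array([p.smoker_baseline for p in cohort], bool)
        self.duration = np.array([p.duration for p in cohort], float)
        self.Y = np.full((n, len(RISK_FACTORS)), np.nan)
        self.Y0 = np.full((n, len(RISK_FACTORS)), np.nan)
        missing = []
        for i, p in enumerate(cohort):
            for j, fac in enumerate(RISK_FACTORS):
                if fac in p.current:
                    self.Y[i, j] = p.current[fac]
                if fac in p.first_recorded:
                    self.Y0[i, j] = p.first_recorded[fac]
            bad = [fac for fac in RISK_FACTORS if fac not in p.current]
            bad += [f"first:{fac}" for fac in RISK_FACTORS if fac not in p.first_recorded]
            if not np.isfinite(p.egfr):
                bad.append("egfr")
            if not np.isfinite(p.egfr_first):
                bad.append("egfr_first")
            if bad:
                missing.append((p.id, bad))
        if missing:
            lines = "; ".join(f"{pid}: {fields}" for pid, fields in missing[:20])
            raise MissingCovariateError(
                f"{len(missing)} patient(s) incomplete for simulation — {lines}")
        self.egfr = np.array([p.egfr for p in cohort], float)
        self.egfr_first = np.array([p.egfr_first for p in cohort], float)
        self.flags = {o: np.array([p.flags.get(o, False) for p in cohort], bool)
                      for o in OUTCOMES}

    @property
    def current(self):
        return {fac: self.Y[:, j] for j, fac in enumerate(RISK_FACTORS)}

    @property
    def first_recorded(self):
        return {fac: self.Y0[:, j] for j, fac in enumerate(RISK_FACTORS)}


def _patient_key(pid) -> int:
    """Stable 32-bit key for a patient id (platform-independent)."""
    return zlib.crc32(str(pid).encode("utf-8"))


def _draws(cohort, config):
    """Per-patient, per-equation draw tensors (stochastic mode only)."""
    n, h = len(cohort), config.horizon
    k = len(RISK_FACTORS)
    mu = np.empty((n, k))
    eps = np.empty((n, h, k))
    event_u = np.empty((n, h, len(OUTCOMES)))
    egfr_u = np.empty((n, h))
    for i, p in enumerate(cohort):
        ss = np.random.SeedSequence([int(config.seed), _patient_key(p.id)])
        children = ss.spawn(len(_STREAMS))
        for j in range(k):
            g = np.random.default_rng(children[j])
            z = g.standard_normal(h + 1)
            mu[i, j] = z[0]
            eps[i, :, j] = z[1:]
        for j in range(len(OUTCOMES)):
            g = np.random.default_rng(children[k + j])
            event_u[i, :, j] = g.uniform(size=h)
        g = np.random.default_rng(children[k + len(OUTCOMES)])
        egfr_u[i] = g.uniform(size=h)
    return mu, eps, event_u, egfr_u


def _weibull_event_step(coef: SurvivalCoefficients, vec, at_risk):
    """(eta, p) arrays for patients at risk; NaN elsewhere."""
    n = len(vec.duration)
    p = np.full(n, np.nan)
    eta = np.full(n, np.nan)
    if not at_risk.any():
        return eta, p
    e = np.broadcast_to(np.asarray(linear_predictor(coef.betas, vec), float), (n,))
    t = vec.duration
    gamma = coef.gamma
    scale = np.exp(e[at_risk])
    h0 = scale * t[at_risk] ** gamma
    h1 = scale * (t[at_risk] + 1.0) ** gamma
    p[at_risk] = np.clip(-np.expm1(h0 - h1), 0.0, 1.0)
    eta[at_risk] = e[at_risk]
    return eta, p


def _invert_event_time(eta, gamma, t0, u):
    """Exact onset time in (t0, t0+1] given the uniform that triggered it."""
    tpow = t0 ** gamma - np.log1p(-u) / np.exp(eta)
    return np.clip(tpow ** (1.0 / gamma), t0, t0 + 1.0)


def simulate_cohort(bundle: CoefficientBundle, cohort, config: SimulationConfig
                    ) -> CohortTrajectory:
    """Simulate the cohort for ``config.horizon`` annual cycles.

    Returns one record per patient per year (no attrition). Identical
    (bundle, cohort, config) inputs produce byte-identical output.
    """
    bundle.require_complete()
    t_start = time.perf_counter()
    vec = _CohortArrays(cohort)
    n, h = len(cohort), config.horizon
    stoch = config.mode == "stochastic"
    if stoch:
        mu_z, eps_z, event_u, egfr_u = _draws(cohort, config)
        re_sd = np.array([bundle.dynamic[f].re_sd for f in RISK_FACTORS])
        resid_sd = np.array([bundle.dynamic[f].resid_sd for f in RISK_FACTORS])
        mu = mu_z * re_sd
    entry_duration = vec.duration.copy()
    onset = {o: np.full(n, np.nan) for o in OUTCOMES}

    records = []
    clamp = config.clamp_ranges if config.clamp else None
    for year in range(1, h + 1):
        t0 = vec.duration
        probs = {}
        # -- step 1: absorbing events (AF, ALB, PVD), lagged covariates
        for j, out in enumerate(OUTCOMES):
            if out == "EGFR_LT60":
                continue
            at_risk = ~vec.flags[out]
            eta, p = _weibull_event_step(bundle.survival[out], vec, at_risk)
            probs[out] = p
            if stoch:
                flip = at_risk & (event_u[:, year - 1, j] < np.nan_to_num(p))
                if flip.any():
                    gamma = bundle.survival[out].gamma
                    onset[out][flip] = _invert_event_time(
                        eta[flip], gamma, t0[flip], event_u[flip, year - 1, j])
                    vec.flags[out][flip] = True
        # -- step 2: eGFR crossing + regime-matched Tobit value
        j = OUTCOMES.index("EGFR_LT60")
        at_risk = ~vec.flags["EGFR_LT60"]
        eta, p = _weibull_event_step(bundle.survival["EGFR_LT60"], vec, at_risk)
        probs["EGFR_LT60"] = p
        if stoch:
            flip = at_risk & (event_u[:, year - 1, j] < np.nan_to_num(p))
            if flip.any():
                gamma = bundle.survival["EGFR_LT60"].gamma
                onset["EGFR_LT60"][flip] = _invert_event_time(
                    eta[flip], gamma, t0[flip], event_u[flip, year - 1, j])
                vec.flags["EGFR_LT60"][flip] = True
        below = vec.flags["EGFR_LT60"]
        new_egfr = np.empty(n)
        for regime, mask in (("below60", below), ("atabove60", ~below)):
            if not mask.any():
                continue
            coef = bundle.tobit[regime]
            upper = coef.upper_limit
            if regime == "atabove60" and not np.isfinite(upper):
                upper = config.egfr_cap
            lat = np.broadcast_to(np.asarray(
                linear_predictor(coef.betas, vec, duration=t0 + 1.0), float), (n,))
            if stoch and config.egfr_value_mode != "deterministic":
                vals = truncated_normal_ppf(egfr_u[:, year - 1], lat, coef.sigma,
                                            coef.lower_limit, upper)
            else:
                vals = truncated_normal_mean(lat, coef.sigma,
                                             coef.lower_limit, upper)
            new_egfr[mask] = np.asarray(vals)[mask]
        # -- step 3: the seven continuous factors, lagged covariates
        new_y = np.empty_like(vec.Y)
        for jf, fac in enumerate(RISK_FACTORS):
            coef = bundle.dynamic[fac]
            pred = deterministic_prediction(
                coef, vec.Y[:, jf], vec.Y0[:, jf], vec.female, vec.ethnicity,
                vec.age_at_rand, t0 + 1.0)
            if stoch:
                pred = pred + mu[:, jf] + resid_sd[jf] * eps_z[:, year - 1, jf]
            if clamp and fac in clamp:
                lo, hi = clamp[fac]
                pred = np.clip(pred, lo, hi)
            new_y[:, jf] = pred
        # -- intervention: one-off shift on the year-1 values and the anchor
        if year == 1 and config.intervention:
            for fac, shift in config.intervention.items():
                jf = RISK_FACTORS.index(fac)
                new_y[:, jf] += shift
                vec.Y0[:, jf] += shift
        vec.Y = new_y
        vec.egfr = new_egfr
        vec.duration = t0 + 1.0
        if year == 1 and config.y_first_source == "first_simulated":
            vec.Y0 = vec.Y.copy()
            vec.egfr_first = vec.egfr.copy()
        rec = {"patient": vec.ids, "year": year, "duration": vec.duration.copy()}
        for jf, fac in enumerate(RISK_FACTORS):
            rec[fac] = vec.Y[:, jf].copy()
        rec["egfr"] = vec.egfr.copy()
        for out in OUTCOMES:
            rec[out] = vec.flags[out].copy()
            rec[f"p_{out}"] = probs[out]
        records.append(pd.DataFrame(rec))

    data = pd.concat(records, ignore_index=True)
    data = data.sort_values(["patient", "year"], kind="stable", ignore_index=True)
    event_times = None
    if stoch:
        rows = []
        for out in OUTCOMES:
            ev = np.isfinite(onset[out])
            rows.append(pd.DataFrame({
                "patient": vec.ids, "outcome": out,
                "entry": entry_duration,
                "time": np.where(ev, onset[out], entry_duration + h),
                "event": ev}))
        event_times = pd.concat(rows, ignore_index=True)
    logger.info("simulated %d patients x %d years (%s mode) in %.2fs",
                n, h, config.mode, time.perf_counter() - t_start)
    return CohortTrajectory(data=data, event_times=event_times, config=config,
                            provenance=bundle.provenance)


def compare_scenarios(bundle, cohort, config_a: SimulationConfig,
                      config_b: SimulationConfig) -> pd.DataFrame:
    """Paired per-year mean differences (arm B minus arm A) with 95% CIs.

    The two configs may differ only in intervention and mode; identical
    seeds give common random numbers across arms.
    """
    for fld in ("horizon", "seed", "y_first_source", "clamp", "egfr_cap",
                "egfr_value_mode"):
        if getattr(config_a, fld) != getattr(config_b, fld):
            raise ValueError(f"configs must agree on {fld!r}")
    ta = simulate_cohort(bundle, cohort, config_a)
    tb = simulate_cohort(bundle, cohort, config_b)
    if not (ta.data["patient"] == tb.data["patient"]).all():
        raise ValueError("cohort mismatch between arms")
    out_rows = []
    variables = list(RISK_FACTORS) + ["egfr"]
    for year, ga in ta.data.groupby("year"):
        gb = tb.data[tb.data["year"] == year]
        for var in variables:
            d = gb[var].to_numpy() - ga[var].to_numpy()
            m = d.mean()
            se = d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else 0.0
            out_rows.append({"year": year, "variable": var, "mean_diff": m,
                             "ci_lower": m - 1.96 * se, "ci_upper": m + 1.96 * se,
                             "n": len(d)})
    return pd.DataFrame(out_rows)


def locf_bundle() -> CoefficientBundle:
    """Last-observation-carried-forward comparator bundle.

    Dynamic equations are the identity (phi1 = 1, everything else 0), event
    hazards are numerically zero, and the eGFR value equations reproduce last
    year's value, so every risk factor stays at its baseline forever and no
    flag ever fires.
    """
    dynamic = {fac: DynamicCoefficients(
        risk_factor=fac, phi0=0.0, phi1=1.0, phi2=0.0, phi3=0.0,
        phi4_white=0.0, phi4_black=0.0, phi4_asian=0.0, phi5=0.0, phi6=0.0)
        for fac in RISK_FACTORS}
    survival = {out: SurvivalCoefficients(
        outcome=out, betas={"constant": -1e9}, ln_gamma=0.0, covariate_spec=[])
        for out in OUTCOMES}
    tobit = {reg: TobitCoefficients(
        regime=reg, betas={"constant": 0.0, "lag:egfr": 1.0}, sigma=1e-9,
        lower_limit=0.0, upper_limit=None)
        for reg in ("below60", "atabove60")}
    return CoefficientBundle(dynamic=dynamic, survival=survival, tobit=tobit,
                             provenance="LOCF comparator (identity dynamics, zero hazards)")
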