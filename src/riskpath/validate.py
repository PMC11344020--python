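"""Internal-validation machinery.

Observed-vs-predicted mean time paths (with 95% CIs) by integer diabetes
duration, quintile-stratified calibration, and Kaplan–Meier observed
cumulative incidence against model-implied incidence. Binning by diabetes
duration pools patients with different durations period-life-table style, so
six years of follow-up per patient still trace out a multi-decade path.

Agreement convention: predictions are judged adequate when they fall inside
the 95% CI of the observed bin means. Comparison outputs are plain tables;
thin matplotlib writers render the standard time-path / incidence graphics.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from ._covariates import RISK_FACTORS
from .coeffs import CoefficientBundle
from .estimate import PanelDataset, build_dynamic_frame, build_ph_intervals
from .events import annual_probability
from .simulate import SimulationConfig, simulate_cohort
from .trajectory import PatientState, deterministic_prediction

logger = logging.getLogger("riskpath.validate")


def _one_step_predictions(panel: PanelDataset, bundle: CoefficientBundle,
                          factor: str) -> pd.DataFrame:
    """Deterministic one-step-ahead predictions on observed lags."""
    frame = build_dynamic_frame(panel, factor)
    coef = bundle.dynamic[factor]
    eth = np.select(
        [frame["eth_white"] == 1, frame["eth_black"] == 1, frame["eth_asian"] == 1],
        ["white", "black", "asian"], default="other")
    # frame rows carry ln_duration of the predicted year already
    pred = (coef.phi0
            + coef.phi1 * frame[f"lag:{factor}"]
            + coef.phi2 * frame[f"first:{factor}"]
            + coef.phi3 * frame["female"]
            + np.select([eth == "white", eth == "black", eth == "asian"],
                        [coef.phi4_white, coef.phi4_black, coef.phi4_asian], 0.0)
            + coef.phi5 * frame["age_at_rand"]
            + coef.phi6 * frame["ln_duration"])
    return pd.DataFrame({"patient": frame["_patient"],
                         "duration": np.exp(frame["ln_duration"]),
                         "observed": frame["_y"], "predicted": pred})


def _resimulated_predictions(panel: PanelDataset, bundle: CoefficientBundle,
                             factor: str) -> pd.DataFrame:
    """Fully re-fed deterministic simulation from each patient's baseline."""
    d = panel.data
    base = d[d["year"] == 0].set_index("patient")
    horizon = int(d["year"].max())
    cohort = []
    for pid, row in base.iterrows():
        vals = {f: row[f] for f in RISK_FACTORS if np.isfinite(row[f])}
        if len(vals) < len(RISK_FACTORS) or not np.isfinite(row["egfr"]):
            continue
        cohort.append(PatientState(
            id=str(pid), age_at_rand=row["age_at_rand"], female=bool(row["female"]),
            ethnicity=row["ethnicity"], smoker_baseline=bool(row["smoker_baseline"]),
            duration=float(row["duration"]), current=vals,
            first_recorded=dict(vals), egfr=float(row["egfr"]),
            egfr_first=float(row["egfr"])))
    traj = simulate_cohort(bundle, cohort,
                           SimulationConfig(horizon=horizon, mode="deterministic",
                                            y_first_source="first_simulated"))
    sim = traj.data[["patient", "year", factor]].rename(columns={factor: "predicted"})
    obs = d[d["year"] >= 1][["patient", "year", "duration", factor]]
    obs = obs.rename(columns={factor: "observed"}).dropna(subset=["observed"])
    obs["patient"] = obs["patient"].astype(str)
    merged = obs.merge(sim, on=["patient", "year"], how="inner")
    return merged[["patient", "duration", "observed", "predicted"]]


def timepath_agreement(panel: PanelDataset, bundle: CoefficientBundle,
                       factor: str, lag_source: str = "observed",
                       min_n: int = 2) -> pd.DataFrame:
    """Observed vs predicted mean time path by integer diabetes duration.

    ``lag_source='observed'`` scores one-step-ahead predictions from observed
    lags (internal validation); ``'simulated'`` re-feeds predictions as lags
    from baseline onwards (extrapolation-style). Returns one row per duration
    bin [k, k+1): n, observed mean and normal-approximation 95% CI, predicted
    mean, and a coverage flag (predicted inside the CI).
    """
    if factor not in RISK_FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    if lag_source == "observed":
        df = _one_step_predictions(panel, bundle, factor)
    elif lag_source == "simulated":
        df = _resimulated_predictions(panel, bundle, factor)
    else:
        raise ValueError("lag_source must be 'observed' or 'simulated'")
    df = df.assign(bin=np.floor(df["duration"]).astype(int))
    rows = []
    dropped = []
    for b, g in df.groupby("bin"):
        if len(g) < max(min_n, 2):
            dropped.append(b)
            continue
        m = g["observed"].mean()
        se = g["observed"].std(ddof=1) / np.sqrt(len(g))
        lo, hi = m - 1.96 * se, m + 1.96 * se
        pm = g["predicted"].mean()
        rows.append({"bin": b, "n": len(g), "obs_mean": m, "obs_lo": lo,
                     "obs_hi": hi, "pred_mean": pm,
                     "covered": bool(lo <= pm <= hi)})
    if dropped:
        logger.warning("%s: %d under-populated duration bins dropped (< %d obs)",
                       factor, len(dropped), max(min_n, 2))
    return pd.DataFrame(rows).sort_values("bin", ignore_index=True)


def quintile_agreement(panel: PanelDataset, bundle: CoefficientBundle,
                       factor: str, lag_source: str = "observed") -> dict:
    """Time-path agreement stratified by quintile of the first observed value.

    Quintile cut-points come from the empirical distribution of first
    observed values; values tied with a cut-point go to the lower quintile.
    """
    d = panel.data[panel.data["year"] >= 1].dropna(subset=[factor])
    first = d.sort_values(["patient", "year"]).groupby("patient")[factor].first()
    if first.nunique() < 5:
        raise ValueError("need >= 5 distinct first observed values")
    cuts = np.quantile(first.to_numpy(), [0.2, 0.4, 0.6, 0.8])
    stratum = pd.Series(np.searchsorted(cuts, first.to_numpy(), side="left"),
                        index=first.index)
    out = {}
    for q in range(5):
        pids = set(stratum[stratum == q].index)
        sub = PanelDataset(
            data=panel.data[panel.data["patient"].isin(pids)].copy(),
            events=panel.events[panel.events["patient"].isin(pids)].copy())
        out[q] = timepath_agreement(sub, bundle, factor, lag_source=lag_source)
    return out


def km_vs_simulated(panel: PanelDataset, bundle: CoefficientBundle,
                    outcome: str, min_at_risk: int = 25) -> pd.DataFrame:
    """Kaplan–Meier observed vs model-implied cumulative incidence.

    The observed curve is 1 minus the delayed-entry product-limit estimator
    (Greenwood 95% CI). The model curve accumulates pooled model hazards
    period-style: for each integer duration bin, the mean annual probability
    over the patient-years at risk in that bin, chained as 1 - prod(1 - h).
    Both curves are conditioned on being event-free at the first duration bin
    with at least ``min_at_risk`` patient-years.
    """
    coef = bundle.survival[outcome]
    ev = panel.events[panel.events["outcome"] == outcome]
    if not ev["event"].any():
        warnings.warn(f"{outcome}: no events observed; degenerate comparison")
    iv = build_ph_intervals(panel, outcome, coef.covariate_spec)
    X = np.column_stack([np.ones(len(iv))]
                        + [iv[c].to_numpy(float) for c in coef.betas if c != "constant"])
    beta = np.array([coef.betas["constant"]]
                    + [coef.betas[c] for c in coef.betas if c != "constant"])
    eta = X @ beta
    p_year = annual_probability(eta, coef.ln_gamma, iv["t0"].to_numpy(float))
    bins = np.floor(iv["t0"].to_numpy()).astype(int)
    pooled = (pd.DataFrame({"bin": bins, "p": p_year})
              .groupby("bin").agg(h=("p", "mean"), n_at_risk=("p", "size")))
    pooled = pooled[pooled["n_at_risk"] >= min_at_risk]
    if pooled.empty:
        raise ValueError("no duration bin reaches min_at_risk")
    # condition both curves on the first well-populated bin that has seen an
    # observed event: before that the Greenwood interval is a point mass at
    # zero and the comparison is vacuous
    ev_times = ev.loc[ev["event"], "time"]
    if len(ev_times):
        first_event_bin = int(np.floor(ev_times.min()))
        pooled = pooled[pooled.index >= first_event_bin]
    if pooled.empty:
        raise ValueError("no populated duration bin at or after the first event")
    # keep the contiguous run of well-populated bins from the first one
    idx = pooled.index.to_numpy()
    run = [int(idx[0])]
    for b in idx[1:]:
        if b != run[-1] + 1:
            break
        run.append(int(b))
    pooled = pooled.loc[run]
    start = run[0]
    sim_cuminc = 1.0 - np.cumprod(1.0 - pooled["h"].to_numpy())

    km = KaplanMeierFitter()
    km.fit(ev["time"], event_observed=ev["event"], entry=ev["entry"])
    grid = pooled.index.to_numpy() + 1.0  # bin ends
    s = km.survival_function_at_times(grid).to_numpy()
    s0 = km.survival_function_at_times(float(start)).to_numpy()[0]
    ci = km.confidence_interval_survival_function_
    lo_col, hi_col = ci.columns[0], ci.columns[1]

    def at(col, t):
        idx = ci.index.to_numpy()
        pos = np.searchsorted(idx, t, side="right") - 1
        return ci[col].to_numpy()[np.clip(pos, 0, len(idx) - 1)]

    s_lo = at(lo_col, grid)
    s_hi = at(hi_col, grid)
    out = pd.DataFrame({
        "duration": grid, "n_at_risk": pooled["n_at_risk"].to_numpy(),
        "km_cuminc": np.clip(1.0 - s / s0, 0.0, 1.0),
        "km_lo": np.clip(1.0 - s_hi / s0, 0.0, 1.0),
        "km_hi": np.clip(1.0 - s_lo / s0, 0.0, 1.0),
        "sim_cuminc": sim_cuminc})
    out["covered"] = (out["sim_cuminc"] >= out["km_lo"]) & \
                     (out["sim_cuminc"] <= out["km_hi"])
    return out


# ---------------------------------------------------------------------------
# thin chart writers (matplotlib optional)
# ---------------------------------------------------------------------------

def plot_timepath(comparison: pd.DataFrame, factor: str = "", ax=None):
    """Observed mean ± CI band with the predicted mean path overlaid."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    x = comparison["bin"] + 0.5
    ax.fill_between(x, comparison["obs_lo"], comparison["obs_hi"],
                    color="0.8", label="observed 95% CI")
    ax.plot(x, comparison["obs_mean"], color="0.3", label="observed mean")
    ax.plot(x, comparison["pred_mean"], color="crimson", label="predicted")
    ax.set_xlabel("diabetes duration (years)")
    ax.set_ylabel(factor)
    ax.legend()
    return ax


def plot_incidence(comparison: pd.DataFrame, outcome: str = "", ax=None):
    """Observed KM cumulative incidence with CI vs model-implied curve."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    x = comparison["duration"]
    ax.fill_between(x, comparison["km_lo"], comparison["km_hi"], color="0.85")
    ax.plot(x, comparison["km_cuminc"], color="steelblue", label="observed (KM)")
    ax.plot(x, comparison["sim_cuminc"], color="crimson", label="model")
    ax.set_xlabel("diabetes duration (years)")
    ax.set_ylabel(f"cumulative incidence {outcome}")
    ax.legend()
    return ax
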