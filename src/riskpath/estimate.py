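"""Refitting the equation families from annualised panel data.

* :func:`fit_dynamic_panel` — Gaussian random-intercept ML for the AR(1)
  dynamic equations (via statsmodels MixedLM). The random-effects estimator
  is retained with its known Nickell-type small-T bias on the lagged
  coefficient, matching how such equations are fitted in practice.
* :func:`fit_tobit` — pooled censored-normal MLE for the regime-specific
  eGFR value equations.
* :func:`fit_parametric_ph` — left-truncated parametric proportional-hazards
  MLE (Weibull / exponential / Gompertz) on counting-process intervals with
  annually-updated covariates; cluster-robust (sandwich) standard errors.
* :func:`backwards_stepwise` — Wald-test backwards selection at p < alpha.
* :func:`cox_snell_residuals` — generalized residuals for PH model checking.

All fitters return a :class:`FitResult` whose parameter names use the
package's covariate vocabulary, so results convert directly into the
coefficient types and round-trip through a bundle file into the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from ._covariates import RISK_FACTORS, OUTCOMES, DURATION_FLOOR
from .coeffs import DynamicCoefficients, SurvivalCoefficients, TobitCoefficients

DISTRIBUTIONS = ("weibull", "exponential", "gompertz")


@dataclass
class PanelDataset:
    """Annualised long-format panel.

    ``data``: one row per patient-year (year 0 = baseline / pre-randomisation,
    years >= 1 post-randomisation), columns: patient, year, duration,
    age_at_rand, female, ethnicity, smoker_baseline, the seven risk factors
    and egfr (NaN where unmeasured).

    ``events``: one row per patient per outcome with delayed-entry survival
    data on the diabetes-duration scale: entry, time (exit), event.
    """

    data: pd.DataFrame
    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        d = self.data
        dup = d.duplicated(subset=["patient", "year"]).any()
        if dup:
            raise ValueError("PanelDataset: duplicate patient-year rows")
        g = d.sort_values(["patient", "year"]).groupby("patient")["duration"]
        if (g.diff().dropna() <= 0).any():
            raise ValueError("PanelDataset: duration must increase within patient")


@dataclass
class FitResult:
    """Coefficients, inference and diagnostics for one fitted equation."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    aic: float
    n_obs: int
    n_patients: int
    converged: bool
    extra: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "p": self.pvalues})

    # -- converters into the simulator's coefficient types ----------------
    def to_dynamic_coefficients(self, risk_factor: str) -> DynamicCoefficients:
        p = self.params
        return DynamicCoefficients(
            risk_factor=risk_factor,
            phi0=p.get("constant", 0.0),
            phi1=p.get(f"lag:{risk_factor}", 0.0),
            phi2=p.get(f"first:{risk_factor}", 0.0),
            phi3=p.get("female", 0.0),
            phi4_white=p.get("eth_white", 0.0),
            phi4_black=p.get("eth_black", 0.0),
            phi4_asian=p.get("eth_asian", 0.0),
            phi5=p.get("age_at_rand", 0.0),
            phi6=p.get("ln_duration", 0.0),
            resid_sd=self.extra.get("resid_sd", 0.0),
            re_sd=self.extra.get("re_sd", 0.0),
            se=dict(self.bse), r2=self.extra.get("r2"),
            n_obs=self.n_obs, n_patients=self.n_patients)

    def to_survival_coefficients(self, outcome: str) -> SurvivalCoefficients:
        betas = {k: float(v) for k, v in self.params.items() if k != "ln_gamma"}
        return SurvivalCoefficients(
            outcome=outcome, betas=betas,
            ln_gamma=float(self.params.get("ln_gamma", 0.0)),
            covariate_spec=[k for k in betas if k != "constant"],
            se=dict(self.bse), n_obs=self.n_obs,
            n_events=self.extra.get("n_events"))

    def to_tobit_coefficients(self, regime: str) -> TobitCoefficients:
        limits = self.extra["limits"]
        return TobitCoefficients(
            regime=regime,
            betas={k: float(v) for k, v in self.params.items()},
            sigma=self.extra["sigma"],
            lower_limit=limits[0], upper_limit=limits[1],
            se=dict(self.bse), n_obs=self.n_obs)


# ---------------------------------------------------------------------------
# frame construction
# ---------------------------------------------------------------------------

def _demographic_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    out["female"] = df["female"].astype(float)
    for eth in ("white", "black", "asian"):
        out[f"eth_{eth}"] = (df["ethnicity"] == eth).astype(float)
    out["age_at_rand"] = df["age_at_rand"].astype(float)
    return out


def build_dynamic_frame(panel: PanelDataset, risk_factor: str) -> pd.DataFrame:
    """Estimation rows for one dynamic equation.

    Uses post-randomisation years only; the anchor ``first:`` value is each
    patient's first observed post-randomisation measurement, and rows require
    a measurement in the immediately preceding year (lag construction).
    """
    col = risk_factor
    d = panel.data[panel.data["year"] >= 1].copy()
    d = d[np.isfinite(d[col])].sort_values(["patient", "year"])
    first = d.groupby("patient").first()
    d["y_first"] = d["patient"].map(first[col])
    d["first_year"] = d["patient"].map(first["year"])
    prev = d.set_index(["patient", "year"])[col]
    idx = pd.MultiIndex.from_arrays([d["patient"], d["year"] - 1])
    d["y_lag"] = prev.reindex(idx).to_numpy()
    d = d[(d["year"] > d["first_year"]) & np.isfinite(d["y_lag"])]
    frame = _demographic_columns(d)
    frame.insert(0, "constant", 1.0)
    frame.insert(1, f"lag:{col}", d["y_lag"].to_numpy())
    frame.insert(2, f"first:{col}", d["y_first"].to_numpy())
    frame["ln_duration"] = np.log(np.maximum(d["duration"].to_numpy(), DURATION_FLOOR))
    frame["_y"] = d[col].to_numpy()
    frame["_patient"] = d["patient"].to_numpy()
    return frame.reset_index(drop=True)


def build_tobit_frame(panel: PanelDataset, regime: str) -> pd.DataFrame:
    """Estimation rows for one eGFR Tobit equation (both regimes see all
    rows; the censoring limits encode the regime)."""
    d = panel.data[panel.data["year"] >= 1].copy()
    d = d[np.isfinite(d["egfr"])].sort_values(["patient", "year"])
    first = d.groupby("patient").first()
    d["e_first"] = d["patient"].map(first["egfr"])
    d["first_year"] = d["patient"].map(first["year"])
    prev = d.set_index(["patient", "year"])[["egfr", "sbp"]]
    idx = pd.MultiIndex.from_arrays([d["patient"], d["year"] - 1])
    d["e_lag"] = prev["egfr"].reindex(idx).to_numpy()
    d["sbp_lag"] = prev["sbp"].reindex(idx).to_numpy()
    d = d[(d["year"] > d["first_year"])
          & np.isfinite(d["e_lag"]) & np.isfinite(d["sbp_lag"])]
    frame = pd.DataFrame({
        "constant": 1.0,
        "age_at_rand": d["age_at_rand"].astype(float).to_numpy(),
        "first:egfr": d["e_first"].to_numpy(),
        "lag:egfr": d["e_lag"].to_numpy(),
        "lag:sbp": d["sbp_lag"].to_numpy(),
        "ln_duration": np.log(np.maximum(d["duration"].to_numpy(), DURATION_FLOOR)),
    })
    frame["_y"] = d["egfr"].to_numpy()
    frame["_patient"] = d["patient"].to_numpy()
    return frame.reset_index(drop=True)


def build_ph_intervals(panel: PanelDataset, outcome: str,
                       covariates) -> pd.DataFrame:
    """Counting-process intervals for one outcome with annually-updated
    covariates (values at interval start, i.e. last year's measurements)."""
    ev = panel.events[panel.events["outcome"] == outcome]
    ev = ev.set_index("patient")
    d = panel.data.sort_values(["patient", "year"]).copy()
    d = d[d["patient"].isin(ev.index)]
    d["entry"] = d["patient"].map(ev["entry"])
    d["exit"] = d["patient"].map(ev["time"])
    d["ev"] = d["patient"].map(ev["event"])
    # interval for the year following each measured row
    d["t0"] = d["duration"]
    nxt = d.groupby("patient")["duration"].shift(-1)
    d["t1"] = np.minimum(nxt.fillna(np.inf), d["exit"])
    d = d[(d["t1"] > d["t0"]) & (d["t0"] < d["exit"])]
    d["t1"] = np.minimum(d["t1"], d["exit"])
    d["event"] = d["ev"] & np.isclose(d["t1"], d["exit"])
    rows = pd.DataFrame({"patient": d["patient"].to_numpy(),
                         "t0": d["t0"].to_numpy(), "t1": d["t1"].to_numpy(),
                         "event": d["event"].to_numpy()})
    demo = _demographic_columns(d).reset_index(drop=True)
    for name in covariates:
        if name in ("female", "eth_white", "eth_black", "eth_asian", "age_at_rand"):
            rows[name] = demo[name].to_numpy()
        elif name == "smoker_baseline":
            rows[name] = d["smoker_baseline"].astype(float).to_numpy()
        elif name.startswith("lag:"):
            rows[name] = d[name[4:]].to_numpy()  # value at interval start
        elif name.startswith("first:"):
            fac = name[6:]
            first = (panel.data[panel.data["year"] >= 1]
                     .dropna(subset=[fac]).sort_values(["patient", "year"])
                     .groupby("patient")[fac].first())
            rows[name] = rows["patient"].map(first).to_numpy()
        else:
            raise ValueError(f"unknown covariate {name!r}")
    rows = rows.dropna().reset_index(drop=True)
    return rows


# ---------------------------------------------------------------------------
# dynamic panel (random-intercept) fitter
# ---------------------------------------------------------------------------

def fit_dynamic_panel(panel: PanelDataset, risk_factor: str,
                      covariates=None) -> FitResult:
    """Random-intercept Gaussian ML fit of one dynamic equation."""
    if risk_factor not in RISK_FACTORS:
        raise ValueError(f"unknown risk factor {risk_factor!r}")
    frame = build_dynamic_frame(panel, risk_factor)
    if covariates is None:
        covariates = [c for c in frame.columns if not c.startswith("_")]
    X = frame[covariates]
    y = frame["_y"]
    groups = frame["_patient"]
    n_pat = groups.nunique()

    ols = sm.OLS(y, X).fit()
    if ols.ssr / max(len(y), 1) < 1e-16:
        # interpolation case: no noise, OLS is exact and the variance
        # components are identically zero
        k = X.shape[1]
        return FitResult(params=ols.params, bse=ols.bse, pvalues=ols.pvalues,
                         loglik=float("inf"), aic=float("-inf"),
                         n_obs=len(y), n_patients=n_pat, converged=True,
                         extra={"resid_sd": 0.0, "re_sd": 0.0, "r2": 1.0,
                                "estimator": "ols"})

    model = sm.MixedLM(y, X, groups=groups)
    with np.errstate(all="ignore"):
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=200)
        except Exception:
            res = model.fit(reml=False)
    # boundary collapse: a random-intercept variance under 1% of the residual
    # variance is numerically indistinguishable from zero at these sample
    # sizes; report the pooled OLS fit instead (documented tie-break)
    if float(res.cov_re.iloc[0, 0]) < 0.01 * float(res.scale):
        return FitResult(params=ols.params, bse=ols.bse, pvalues=ols.pvalues,
                         loglik=float(ols.llf), aic=float(ols.aic),
                         n_obs=len(y), n_patients=n_pat, converged=True,
                         extra={"resid_sd": float(np.sqrt(ols.scale)),
                                "re_sd": 0.0, "r2": float(ols.rsquared),
                                "estimator": "ols"})
    fitted = X.to_numpy() @ res.fe_params.to_numpy()
    r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    k = X.shape[1] + 2  # fixed effects + two variance components
    ll = float(res.llf)
    return FitResult(
        params=pd.Series(res.fe_params, index=covariates),
        bse=pd.Series(res.bse_fe.to_numpy(), index=covariates),
        pvalues=pd.Series(res.pvalues.to_numpy()[:len(covariates)], index=covariates),
        loglik=ll, aic=2 * k - 2 * ll, n_obs=len(y), n_patients=n_pat,
        converged=bool(res.converged),
        extra={"resid_sd": float(np.sqrt(res.scale)),
               "re_sd": float(np.sqrt(res.cov_re.iloc[0, 0])),
               "r2": r2, "estimator": "mixedlm"})


# ---------------------------------------------------------------------------
# Tobit (censored normal) fitter
# ---------------------------------------------------------------------------

def tobit_loglik(theta, y, X, lower, upper):
    """Censored-normal log-likelihood; theta = (beta, log sigma)."""
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    xb = X @ beta
    ll = np.empty_like(y)
    at_lo = y <= lower + 1e-12
    at_hi = y >= upper - 1e-12
    mid = ~(at_lo | at_hi)
    z = (y - xb) / sigma
    ll[mid] = norm.logpdf(z[mid]) - log_sigma
    if np.isfinite(lower):
        ll[at_lo] = norm.logcdf((lower - xb[at_lo]) / sigma)
    if np.isfinite(upper):
        ll[at_hi] = norm.logsf((upper - xb[at_hi]) / sigma)
    return ll


def tobit_mle(y, X, lower, upper, names=None, cluster=None) -> FitResult:
    """Maximize the censored-normal likelihood. ``X`` includes the constant."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    interior = (y > lower + 1e-12) & (y < upper - 1e-12)
    if not interior.any():
        raise ValueError("all observations censored: Tobit not identifiable")
    b0, *_ = np.linalg.lstsq(X[interior], y[interior], rcond=None)
    resid = y[interior] - X[interior] @ b0
    s0 = max(resid.std(), 1e-3)
    theta0 = np.concatenate([b0, [np.log(s0)]])

    def negll(theta):
        return -tobit_loglik(theta, y, X, lower, upper).sum()

    res = minimize(negll, theta0, method="BFGS",
                   options={"maxiter": 500, "gtol": 1e-7})
    theta = res.x
    H = approx_hess(theta, negll)
    cov = np.linalg.inv(H)
    bse_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    params = pd.Series(theta[:-1], index=names)
    bse = pd.Series(bse_all[:-1], index=names)
    z = params / bse.replace(0.0, np.nan)
    pvalues = pd.Series(2 * norm.sf(np.abs(z)), index=names)
    ll = -res.fun
    k = len(theta)
    sigma = float(np.exp(theta[-1]))
    return FitResult(params=params, bse=bse, pvalues=pvalues,
                     loglik=float(ll), aic=2 * k - 2 * ll,
                     n_obs=len(y),
                     n_patients=int(pd.Series(cluster).nunique()) if cluster is not None else len(y),
                     converged=bool(res.success),
                     extra={"sigma": sigma,
                            "sigma_se": float(bse_all[-1] * sigma),
                            "limits": (lower, upper),
                            "frac_censored": float(1 - interior.mean())})


def fit_tobit(panel: PanelDataset, regime: str, covariates=None) -> FitResult:
    """Fit one regime's eGFR value equation on the annualised panel.

    The below-60 model treats values >= 60 as right-censored at 60 (limits
    0–60); the at/above-60 model treats values <= 60 as left-censored at 60.
    """
    if regime not in ("below60", "atabove60"):
        raise ValueError("regime must be below60|atabove60")
    frame = build_tobit_frame(panel, regime)
    if covariates is None:
        covariates = [c for c in frame.columns if not c.startswith("_")]
    y = frame["_y"].to_numpy().copy()
    if regime == "below60":
        lower, upper = 0.0, 60.0
        y = np.minimum(y, upper)
    else:
        lower, upper = 60.0, np.inf
        y = np.maximum(y, lower)
    res = tobit_mle(y, frame[covariates].to_numpy(), lower, upper,
                    names=covariates, cluster=frame["_patient"])
    return res


# ---------------------------------------------------------------------------
# left-truncated parametric PH fitter
# ---------------------------------------------------------------------------

def _ph_parts(distribution, eta, shape, t0, t1, event):
    """Per-interval log-likelihood contributions."""
    if distribution == "weibull":
        gamma = np.exp(shape)
        H0 = np.exp(eta) * t0 ** gamma
        H1 = np.exp(eta) * t1 ** gamma
        lnh = eta + shape + (gamma - 1.0) * np.log(t1)
    elif distribution == "exponential":
        H0 = np.exp(eta) * t0
        H1 = np.exp(eta) * t1
        lnh = eta
    elif distribution == "gompertz":
        lam = shape
        if abs(lam) < 1e-8:
            H0 = np.exp(eta) * t0 * (1 + lam * t0 / 2)
            H1 = np.exp(eta) * t1 * (1 + lam * t1 / 2)
        else:
            H0 = np.exp(eta) * np.expm1(lam * t0) / lam
            H1 = np.exp(eta) * np.expm1(lam * t1) / lam
        lnh = eta + lam * t1
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return np.where(event, lnh, 0.0) + (H0 - H1)


def _ph_unpack(distribution, theta):
    if distribution == "exponential":
        return theta, None
    return theta[:-1], theta[-1]


def fit_parametric_ph(intervals: pd.DataFrame, distribution: str = "weibull",
                      covariates=None, robust: bool = True) -> FitResult:
    """Left-truncated parametric PH MLE on counting-process intervals.

    ``intervals`` columns: patient, t0, t1, event, plus covariates (constant
    added automatically). Left truncation / delayed entry is encoded by t0 of
    each patient's first interval; covariates may change between intervals.
    """
    if distribution not in DISTRIBUTIONS:
        raise ValueError(f"distribution must be one of {DISTRIBUTIONS}")
    iv = intervals
    if not iv["event"].any():
        raise ValueError("no events in the data: PH model not estimable")
    if covariates is None:
        covariates = [c for c in iv.columns
                      if c not in ("patient", "t0", "t1", "event")]
    names = ["constant"] + [c for c in covariates if c != "constant"]
    X = np.column_stack([np.ones(len(iv))]
                        + [iv[c].to_numpy(float) for c in names[1:]])
    t0 = iv["t0"].to_numpy(float)
    t1 = iv["t1"].to_numpy(float)
    event = iv["event"].to_numpy(bool)
    patient = iv["patient"].to_numpy()

    exposure = (t1 - t0).sum()
    theta0 = np.zeros(X.shape[1] + (0 if distribution == "exponential" else 1))
    theta0[0] = np.log(event.sum() / exposure)

    def negll(theta):
        beta, shape = _ph_unpack(distribution, theta)
        eta = X @ beta
        return -_ph_parts(distribution, eta, shape, t0, t1, event).sum()

    res = minimize(negll, theta0, method="BFGS",
                   options={"maxiter": 500, "gtol": 1e-7})
    theta = res.x
    H = approx_hess(theta, negll)
    cov_model = np.linalg.inv(H)
    if robust:
        def patient_ll(theta):
            beta, shape = _ph_unpack(distribution, theta)
            parts = _ph_parts(distribution, X @ beta, shape, t0, t1, event)
            return pd.Series(parts).groupby(pd.Series(patient)).sum().to_numpy()
        S = approx_fprime(theta, patient_ll)  # (n_patients, k) scores
        B = S.T @ S
        cov = cov_model @ B @ cov_model
    else:
        cov = cov_model
    bse_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    pnames = names + ([] if distribution == "exponential" else
                      ["ln_gamma" if distribution == "weibull" else "gompertz_rate"])
    params = pd.Series(theta, index=pnames)
    bse = pd.Series(bse_all, index=pnames)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / bse
    pvalues = pd.Series(2 * norm.sf(np.abs(z)), index=pnames)
    ll = -res.fun
    k = len(theta)
    return FitResult(params=params, bse=bse, pvalues=pvalues,
                     loglik=float(ll), aic=2 * k - 2 * ll,
                     n_obs=len(iv),
                     n_patients=int(pd.Series(patient).nunique()),
                     converged=bool(res.success),
                     extra={"distribution": distribution,
                            "n_events": int(event.sum()),
                            "covariance": cov})


def compare_distributions(intervals: pd.DataFrame, covariates=None) -> dict:
    """Fit all three parametric forms; returns {name: FitResult} plus the
    AIC-best name under key ``'best'``."""
    fits = {d: fit_parametric_ph(intervals, d, covariates=covariates)
            for d in DISTRIBUTIONS}
    best = min(DISTRIBUTIONS, key=lambda d: fits[d].aic)
    fits["best"] = best
    return fits


def cox_snell_residuals(fit: FitResult, intervals: pd.DataFrame) -> pd.DataFrame:
    """Generalized residuals H(exit|x) - H(entry|x), one row per patient.

    Under a correctly specified model the residuals of event patients behave
    as censored unit-exponential samples (Nelson–Aalen slope ~ 1).
    """
    distribution = fit.extra["distribution"]
    names = [n for n in fit.params.index
             if n not in ("ln_gamma", "gompertz_rate")]
    beta = fit.params[names].to_numpy()
    shape = (None if distribution == "exponential"
             else float(fit.params.iloc[-1]))
    X = np.column_stack([np.ones(len(intervals))]
                        + [intervals[c].to_numpy(float) for c in names[1:]])
    eta = X @ beta
    parts = _ph_parts(distribution, eta, shape,
                      intervals["t0"].to_numpy(float),
                      intervals["t1"].to_numpy(float),
                      np.zeros(len(intervals), bool))
    per_interval = -parts  # H(t1) - H(t0) >= 0
    df = pd.DataFrame({"patient": intervals["patient"].to_numpy(),
                       "dH": per_interval,
                       "event": intervals["event"].to_numpy(bool)})
    agg = df.groupby("patient").agg(residual=("dH", "sum"),
                                    event=("event", "any"))
    return agg.reset_index()


# ---------------------------------------------------------------------------
# backwards stepwise selection
# ---------------------------------------------------------------------------

def backwards_stepwise(fitter: Callable, data, candidates, alpha: float = 0.05,
                       forced=("constant",)) -> FitResult:
    """Backwards elimination on Wald p-values at the ``alpha`` threshold.

    ``fitter(data, covariates)`` must return a :class:`FitResult`. At each
    step the removable covariate with the largest p >= alpha is dropped
    (ties broken towards the covariate declared later); shape parameters and
    ``forced`` names are never removed. Deterministic; may end constant-only.
    """
    protected = set(forced) | {"ln_gamma", "gompertz_rate"}
    current = list(candidates)
    fit = fitter(data, current)
    while True:
        removable = [c for c in current if c not in protected]
        if not removable:
            break
        pvals = fit.pvalues[removable]
        worst_p = np.nanmax(pvals.to_numpy())
        if not (worst_p >= alpha) or np.isnan(worst_p):
            break
        # tie-break: drop the later-declared covariate among maxima
        ties = [c for c in removable if pvals[c] == worst_p]
        drop = ties[-1]
        current = [c for c in current if c != drop]
        fit = fitter(data, current)
    fit.extra["selected"] = [c for c in current if c not in forced]
    return fit
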