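"""Two-part annual eGFR engine.

Kidney function is modelled in two parts because downstream diabetes outcome
equations treat eGFR = 60 ml/min/1.73m2 as a spline knot, so the *proportion*
of patients below 60 matters as much as the mean value:

1. a Weibull equation (in :mod:`riskpath.events`) models the absorbing
   crossing into eGFR < 60;
2. two regime-specific Tobit value equations produce the continuous annual
   value — censored at (0, 60) below the threshold and bounded below by 60
   above it.

Stochastic mode draws the value from a truncated normal around the Tobit
latent mean with the published forecast SD; deterministic mode returns the
closed-form truncated-normal mean. Either way the type invariant holds:
the value is on the correct side of 60 for the regime in force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ._covariates import linear_predictor, MissingCovariateError
from .coeffs import CoefficientBundle, TobitCoefficients
from .events import annual_event_probability
from .trajectory import PatientState

#: default physiological cap for the unbounded at/above-60 regime
DEFAULT_EGFR_CAP = 200.0


@dataclass
class EgfrAnnualResult:
    below60: bool
    value: float
    regime_used: str
    draw_mode: str
    crossing_probability: float = float("nan")


def truncated_normal_mean(mu, sigma, lower, upper):
    """Closed-form mean of N(mu, sigma^2) truncated to (lower, upper).

    Vectorised; degenerate cases (sigma ~ 0 or all mass outside the window)
    collapse to the clamped latent mean / nearest boundary.
    """
    mu = np.asarray(mu, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    # evaluate the normalising mass in whichever tail avoids cancellation
    z = np.where(a > 0, norm.sf(a) - norm.sf(b), norm.cdf(b) - norm.cdf(a))
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = mu + sigma * (norm.pdf(a) - norm.pdf(b)) / z
    # window in a far tail: fall back to the nearest boundary
    mean = np.where(z < 1e-12, np.clip(mu, lower, min(upper, np.finfo(float).max)), mean)
    return np.clip(mean, lower, upper)


def truncated_normal_ppf(u, mu, sigma, lower, upper):
    """Inverse-CDF sample of the truncated normal from uniforms ``u``."""
    mu = np.asarray(mu, dtype=float)
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    ca, cb = norm.cdf(a), norm.cdf(b)
    q = ca + np.asarray(u) * (cb - ca)
    x = mu + sigma * norm.ppf(np.clip(q, 1e-15, 1 - 1e-15))
    return np.clip(x, lower, upper)


def tobit_latent_mean(coef: TobitCoefficients, state: PatientState,
                      duration=None) -> float:
    """Linear predictor x'beta on the unbounded latent scale.

    ``duration`` (duration at the predicted year) overrides the state's for
    the ``ln_duration`` term; defaults to ``state.duration + 1``.
    """
    if duration is None:
        duration = state.duration + 1.0
    return float(linear_predictor(coef.betas, state, duration=duration))


def tobit_value(coef: TobitCoefficients, state: PatientState,
                mode: str = "deterministic", rng=None, duration=None) -> float:
    """Annual eGFR value under one regime's Tobit equation."""
    mu = tobit_latent_mean(coef, state, duration=duration)
    if mode == "deterministic":
        return float(truncated_normal_mean(mu, coef.sigma,
                                           coef.lower_limit, coef.upper_limit))
    if mode != "stochastic":
        raise ValueError("mode must be 'deterministic' or 'stochastic'")
    if rng is None:
        raise ValueError("stochastic mode requires an rng")
    return float(truncated_normal_ppf(rng.uniform(), mu, coef.sigma,
                                      coef.lower_limit, coef.upper_limit))


def advance_egfr(bundle: CoefficientBundle, state: PatientState,
                 mode: str = "deterministic", rng=None,
                 egfr_cap: float = DEFAULT_EGFR_CAP,
                 crossing_mode: str = None):
    """One annual eGFR update; returns ``(new_state, EgfrAnnualResult)``.

    If the below-60 flag is already set the patient stays in the below-60
    regime (absorbing). Otherwise the Weibull crossing equation is evaluated
    first (stochastic: Monte-Carlo flip; deterministic/expected: probability
    recorded, no flip), then the regime-matched Tobit value is produced from
    last year's values. ``egfr_cap`` bounds the open-ended at/above-60 regime.
    """
    if not np.isfinite(state.egfr) or not np.isfinite(state.egfr_first):
        raise MissingCovariateError("state.egfr and state.egfr_first are required")
    new = state.copy()
    p_cross = float("nan")
    if not state.flags.get("EGFR_LT60", False):
        res = annual_event_probability(bundle.survival["EGFR_LT60"], state)
        p_cross = res.probability
        stochastic_cross = crossing_mode == "stochastic" or (
            crossing_mode is None and mode == "stochastic")
        if stochastic_cross:
            if rng is None:
                raise ValueError("stochastic crossing requires an rng")
            if rng.uniform() < p_cross:
                new.flags["EGFR_LT60"] = True
    below = new.flags["EGFR_LT60"]
    regime = "below60" if below else "atabove60"
    coef = bundle.tobit[regime]
    if regime == "atabove60" and not np.isfinite(coef.upper_limit):
        coef = TobitCoefficients(regime=coef.regime, betas=coef.betas,
                                 sigma=coef.sigma, lower_limit=coef.lower_limit,
                                 upper_limit=egfr_cap, se=coef.se)
    value = tobit_value(coef, state, mode=mode, rng=rng,
                        duration=state.duration + 1.0)
    new.egfr = value
    return new, EgfrAnnualResult(below60=below, value=value, regime_used=regime,
                                 draw_mode=mode, crossing_probability=p_cross)
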