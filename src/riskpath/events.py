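"""Annual probabilities and absorbing-state updates for the binary conditions.

Each condition (AF, albuminuria, PVD, eGFR<60) follows a Weibull
proportional-hazards model on the diabetes-duration time scale: with shape
``gamma = exp(ln_gamma)`` and linear predictor ``eta`` the cumulative hazard
is ``H(t) = exp(eta) * t**gamma``. The probability of onset during the next
annual cycle, conditional on being event-free at duration ``t``, is

    p = 1 - exp(H(t) - H(t+1))

i.e. one minus the conditional survivor over ``(t, t+1]`` — the standard
conversion of a continuous-time PH equation to a discrete annual cycle.
Covariates named ``lag:<factor>`` are read from the state *before* the same
year's continuous update, so they are genuinely last year's values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._covariates import OUTCOMES, linear_predictor
from .coeffs import CoefficientBundle, SurvivalCoefficients
from .trajectory import PatientState


class AbsorbingStateError(ValueError):
    """An annual probability was requested for an already-absorbed patient."""


@dataclass
class AnnualHazardResult:
    outcome: str
    linear_predictor: float
    cum_hazard_t: float
    cum_hazard_t1: float
    probability: float


def weibull_cumulative_hazard(eta, ln_gamma, t):
    """H(t) = exp(eta) * t**gamma, vectorised; H(0) = 0."""
    gamma = np.exp(ln_gamma)
    t = np.asarray(t, dtype=float)
    return np.exp(eta) * np.power(t, gamma)


def annual_probability(eta, ln_gamma, t):
    """1 - exp(H(t) - H(t+1)) for scalar or array eta / t."""
    h_t = weibull_cumulative_hazard(eta, ln_gamma, t)
    h_t1 = weibull_cumulative_hazard(eta, ln_gamma, np.asarray(t, dtype=float) + 1.0)
    return -np.expm1(h_t - h_t1)


def annual_event_probability(coef: SurvivalCoefficients,
                             state: PatientState) -> AnnualHazardResult:
    """Probability that ``coef.outcome`` occurs during the coming year."""
    if state.flags.get(coef.outcome, False):
        raise AbsorbingStateError(
            f"{coef.outcome} flag already set for patient {state.id}: "
            "absorbing conditions have no further annual probability")
    eta = float(linear_predictor(coef.betas, state))
    t = float(state.duration)
    h_t = float(weibull_cumulative_hazard(eta, coef.ln_gamma, t))
    h_t1 = float(weibull_cumulative_hazard(eta, coef.ln_gamma, t + 1.0))
    p = float(-np.expm1(h_t - h_t1))
    return AnnualHazardResult(outcome=coef.outcome, linear_predictor=eta,
                              cum_hazard_t=h_t, cum_hazard_t1=h_t1,
                              probability=min(max(p, 0.0), 1.0))


def update_flags(bundle: CoefficientBundle, state: PatientState, rng=None,
                 mode: str = "stochastic", outcomes=None):
    """One annual event update; returns ``(new_state, results)``.

    ``results`` maps outcome -> :class:`AnnualHazardResult` for patients still
    at risk. In stochastic mode a uniform draw flips each at-risk flag with
    its annual probability; expected mode records probabilities without
    flipping (used for calibration / cumulative-incidence accumulation).
    Flags never revert. ``outcomes`` restricts the update (the cohort
    simulator handles the eGFR crossing inside its eGFR step).
    """
    if mode not in ("stochastic", "expected"):
        raise ValueError("mode must be 'stochastic' or 'expected'")
    if mode == "stochastic" and rng is None:
        raise ValueError("stochastic mode requires an rng")
    outcomes = tuple(outcomes) if outcomes is not None else OUTCOMES
    new = state.copy()
    results = {}
    for out in outcomes:
        if state.flags.get(out, False):
            continue
        res = annual_event_probability(bundle.survival[out], state)
        results[out] = res
        if mode == "stochastic" and rng.uniform() < res.probability:
            new.flags[out] = True
    return new, results
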