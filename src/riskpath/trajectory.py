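"""One-year-ahead prediction of the continuous risk factors.

Each of the seven continuous risk factors follows a first-order dynamic
equation: next year's value is a linear function of this year's value
(``phi1``), the first recorded post-randomisation value (``phi2``), sex,
ethnicity, age at randomisation and log diabetes duration. Because
``|phi1| < 1``, iterated predictions converge geometrically towards a
patient-specific long-run level; ``phi2`` anchors that level to where the
patient started.

Deterministic mode propagates expected values (the convention used when
these equations feed an outcomes simulation); stochastic mode adds a
patient-level random intercept ``mu_i`` (drawn once per patient) and a fresh
annual innovation ``eps_it``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from ._covariates import (
    RISK_FACTORS, OUTCOMES, ETHNICITIES, MissingCovariateError, ln_duration,
)
from .coeffs import CoefficientBundle, DynamicCoefficients


@dataclass
class PatientState:
    """One patient's covariates, current/lagged risk-factor store and flags.

    ``current`` holds the most recent (lagged, once inside the annual loop)
    value of each risk factor; ``first_recorded`` holds the anchor value
    ``y_0``. Condition flags are absorbing: they only flip false -> true.
    """

    id: str
    age_at_rand: float
    female: bool
    ethnicity: str
    duration: float                      # years since diabetes diagnosis
    current: dict = field(default_factory=dict)
    first_recorded: dict = field(default_factory=dict)
    egfr: float = float("nan")
    egfr_first: float = float("nan")
    smoker_baseline: bool = False
    flags: dict = field(default_factory=lambda: {o: False for o in OUTCOMES})

    def __post_init__(self):
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"ethnicity must be one of {ETHNICITIES}")
        if not self.duration > 0:
            raise ValueError("diabetes duration must be > 0")
        for o in OUTCOMES:
            self.flags.setdefault(o, False)

    def copy(self) -> "PatientState":
        return dataclasses.replace(
            self, current=dict(self.current),
            first_recorded=dict(self.first_recorded), flags=dict(self.flags))


def _eth_effect(coef: DynamicCoefficients, ethnicity):
    """phi4 term; works for scalar ethnicity or an array of ethnicities."""
    if isinstance(ethnicity, str):
        return coef.phi4(ethnicity)
    eth = np.asarray(ethnicity)
    out = np.zeros(eth.shape)
    for name in ("white", "black", "asian"):
        out += np.where(eth == name, getattr(coef, f"phi4_{name}"), 0.0)
    return out


def deterministic_prediction(coef: DynamicCoefficients, y_prev, y_first,
                             female, ethnicity, age_at_rand, duration_next):
    """Expected next-year value; accepts scalars or aligned arrays.

    ``duration_next`` is the diabetes duration at the *predicted* year.
    """
    return (coef.phi0
            + coef.phi1 * y_prev
            + coef.phi2 * y_first
            + coef.phi3 * np.asarray(female, dtype=float)
            + _eth_effect(coef, ethnicity)
            + coef.phi5 * age_at_rand
            + coef.phi6 * ln_duration(duration_next))


def predict_next_value(coef: DynamicCoefficients, state: PatientState,
                       mode: str = "deterministic", rng=None, mu=None):
    """Predict next year's value of ``coef.risk_factor`` for one patient.

    In stochastic mode the innovation is ``mu + eps`` where ``eps`` has SD
    ``resid_sd``. If ``mu`` (the patient's time-invariant random intercept)
    is not supplied, a single combined draw with SD
    ``sqrt(re_sd**2 + resid_sd**2)`` is used instead — appropriate for a
    one-off prediction, while a multi-year path should hold ``mu`` fixed.
    """
    fac = coef.risk_factor
    if fac not in state.current:
        raise MissingCovariateError(f"no lagged value for {fac!r} in state.current")
    if fac not in state.first_recorded:
        raise MissingCovariateError(f"no first-recorded value for {fac!r}")
    pred = deterministic_prediction(
        coef, state.current[fac], state.first_recorded[fac],
        state.female, state.ethnicity, state.age_at_rand, state.duration + 1.0)
    if mode == "deterministic":
        return float(pred)
    if mode != "stochastic":
        raise ValueError("mode must be 'deterministic' or 'stochastic'")
    if rng is None:
        raise ValueError("stochastic mode requires an rng")
    if mu is None:
        sd = coef.draw_sd
        return float(pred + (rng.normal(0.0, sd) if sd > 0 else 0.0))
    eps = rng.normal(0.0, coef.resid_sd) if coef.resid_sd > 0 else 0.0
    return float(pred + mu + eps)


def advance_continuous(bundle: CoefficientBundle, state: PatientState,
                       mode: str = "deterministic", rng=None, mu=None,
                       clamp_ranges=None) -> PatientState:
    """Advance all seven continuous factors one year; returns a new state.

    ``mu`` may map risk factor -> the patient's random intercept. Duration is
    incremented by one; ``first_recorded`` is untouched. ``clamp_ranges``
    optionally maps factor -> (lo, hi) for physiological clamping.
    """
    new = state.copy()
    for fac in RISK_FACTORS:
        coef = bundle.dynamic[fac]
        try:
            val = predict_next_value(coef, state, mode=mode, rng=rng,
                                     mu=None if mu is None else mu.get(fac))
        except MissingCovariateError as exc:
            raise MissingCovariateError(f"factor {fac!r}: {exc}") from exc
        if clamp_ranges and fac in clamp_ranges:
            lo, hi = clamp_ranges[fac]
            val = min(max(val, lo), hi)
        new.current[fac] = val
    new.duration = state.duration + 1.0
    return new


def long_run_mean(coef: DynamicCoefficients, state: PatientState,
                  duration_frozen: float) -> float:
    """Fixed point of the dynamic equation with duration frozen.

    Solves ``y* = phi0 + phi1*y* + phi2*y_first + covariates``, i.e. the level
    iterated predictions converge to at geometric rate ``|phi1|``.
    """
    if abs(coef.phi1) >= 1:
        raise ValueError(f"|phi1| >= 1 ({coef.phi1}): no finite long-run mean")
    fac = coef.risk_factor
    if fac not in state.first_recorded:
        raise MissingCovariateError(f"no first-recorded value for {fac!r}")
    numer = (coef.phi0
             + coef.phi2 * state.first_recorded[fac]
             + coef.phi3 * float(state.female)
             + coef.phi4(state.ethnicity)
             + coef.phi5 * state.age_at_rand
             + coef.phi6 * math.log(max(duration_frozen, 0.5)))
    return numer / (1.0 - coef.phi1)
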