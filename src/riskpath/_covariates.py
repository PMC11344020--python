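"""Controlled covariate vocabulary and resolution against patient state.

Every equation in the package names its covariates from a single vocabulary:

``constant``
    intercept (always 1)
``age_at_rand``
    age at randomisation, years (time-invariant)
``female``, ``smoker_baseline``
    0/1 indicators fixed at baseline
``eth_white``, ``eth_black``, ``eth_asian``
    ethnicity dummies; the reference category is "other"
``ln_duration``
    natural log of diabetes duration (years) at the year being predicted,
    floored at DURATION_FLOOR before logging
``lag:<factor>``
    the previous year's value of a continuous risk factor (or ``lag:egfr``)
``first:<factor>``
    the first recorded post-randomisation value (or ``first:egfr``)

The resolver works identically on a scalar :class:`~riskpath.trajectory.PatientState`
and on the vectorised cohort arrays used by the simulator, so the annual-cycle
maths is written once.
"""

from __future__ import annotations

import numpy as np

#: the seven continuous risk factors modelled by the dynamic equations
RISK_FACTORS = ("hdl", "ldl", "sbp", "hba1c", "haemoglobin", "heart_rate", "bmi")

#: absorbing binary conditions (atrial fibrillation, micro/macro-albuminuria,
#: peripheral vascular disease, eGFR below 60 ml/min/1.73m2)
OUTCOMES = ("AF", "ALB", "PVD", "EGFR_LT60")

ETHNICITIES = ("white", "black", "asian", "other")

#: duration (years) is floored here before taking logs, so newly diagnosed
#: patients do not produce -inf; inert for realistic cohorts (~16 y duration)
DURATION_FLOOR = 0.5


class MissingCovariateError(KeyError):
    """A named covariate could not be resolved from the patient state."""


def ln_duration(duration):
    """log of diabetes duration with the near-diagnosis floor applied."""
    return np.log(np.maximum(duration, DURATION_FLOOR))


def resolve(state, name, duration=None):
    """Resolve a vocabulary name to a value (scalar state) or array (cohort).

    ``duration`` overrides the state's duration for the ``ln_duration`` term
    (the equations use the duration of the year being predicted).
    """
    if name == "constant":
        return 1.0
    if name == "age_at_rand":
        return state.age_at_rand
    if name == "female":
        return np.asarray(state.female, dtype=float) if _is_vec(state) else float(state.female)
    if name == "smoker_baseline":
        return (np.asarray(state.smoker_baseline, dtype=float)
                if _is_vec(state) else float(state.smoker_baseline))
    if name in ("eth_white", "eth_black", "eth_asian"):
        eth = name.split("_", 1)[1]
        if _is_vec(state):
            return (np.asarray(state.ethnicity) == eth).astype(float)
        return 1.0 if state.ethnicity == eth else 0.0
    if name == "ln_duration":
        d = state.duration if duration is None else duration
        return ln_duration(d)
    if name.startswith("lag:"):
        fac = name[4:]
        if fac == "egfr":
            return state.egfr
        try:
            return state.current[fac]
        except KeyError as exc:
            raise MissingCovariateError(
                f"patient state lacks a lagged value for risk factor {fac!r}") from exc
    if name.startswith("first:"):
        fac = name[6:]
        if fac == "egfr":
            return state.egfr_first
        try:
            return state.first_recorded[fac]
        except KeyError as exc:
            raise MissingCovariateError(
                f"patient state lacks a first-recorded value for risk factor {fac!r}") from exc
    raise MissingCovariateError(f"unknown covariate name {name!r}")


def linear_predictor(betas, state, duration=None):
    """Dot product of a named coefficient map with resolved covariates."""
    total = 0.0
    for name, beta in betas.items():
        total = total + beta * resolve(state, name, duration=duration)
    return total


def _is_vec(state):
    return getattr(state, "is_vectorized", False)
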