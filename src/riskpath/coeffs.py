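"""Coefficient data model and (de)serialisation.

Three equation families drive the annual cycle:

* :class:`DynamicCoefficients` — a first-order autoregressive linear equation
  for one continuous risk factor (lagged value, first-recorded value, sex,
  ethnicity, age at randomisation, log diabetes duration).
* :class:`SurvivalCoefficients` — a Weibull proportional-hazards equation for
  one absorbing condition, on the diabetes-duration time scale.
* :class:`TobitCoefficients` — a censored-normal value equation for eGFR in
  one regime (below / at-or-above 60 ml/min/1.73m2).

A :class:`CoefficientBundle` groups one equation per risk factor / outcome /
regime and round-trips losslessly through a human-editable JSON schema.
The bundled default file transcribes the published pooled-trial coefficient
tables at their printed 3-decimal precision (full-precision values were never
published); the unpublished residual and random-effect SDs of the dynamic
equations default to 0, which makes simulation deterministic unless the user
supplies them or refits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Optional

from ._covariates import RISK_FACTORS, OUTCOMES


class SchemaError(ValueError):
    """A coefficient file violates the documented schema or an invariant."""


_ETH_FIELDS = ("phi4_white", "phi4_black", "phi4_asian")

#: covariate names legal in survival / Tobit coefficient maps
_VOCAB_FIXED = {
    "constant", "age_at_rand", "female", "smoker_baseline",
    "eth_white", "eth_black", "eth_asian", "ln_duration",
}
_VOCAB_PREFIXES = ("lag:", "first:")


def _check_vocab(name: str, where: str) -> None:
    if name in _VOCAB_FIXED:
        return
    for p in _VOCAB_PREFIXES:
        if name.startswith(p) and (name[len(p):] in RISK_FACTORS or name[len(p):] == "egfr"):
            return
    raise SchemaError(f"{where}: unknown covariate name {name!r}")


def _check_finite(value, where: str) -> float:
    v = float(value)
    if not math.isfinite(v):
        raise SchemaError(f"{where}: non-finite value {value!r}")
    return v


@dataclass
class DynamicCoefficients:
    """AR(1) dynamic-equation coefficients for one continuous risk factor.

    The one-year-ahead expected value is

    ``phi0 + phi1*y_prev + phi2*y_first + phi3*female + phi4_<eth>
    + phi5*age_at_rand + phi6*ln(duration)``.

    ``resid_sd`` (year-to-year error SD) and ``re_sd`` (patient random-intercept
    SD) are optional; both default to 0 because they were never published for
    the bundled equations. They are populated when equations are refit.
    """

    risk_factor: str
    phi0: float
    phi1: float
    phi2: float
    phi3: float
    phi4_white: float
    phi4_black: float
    phi4_asian: float
    phi5: float
    phi6: float
    resid_sd: float = 0.0
    re_sd: float = 0.0
    unit: str = ""
    se: dict = field(default_factory=dict)
    r2: Optional[float] = None
    n_obs: Optional[int] = None
    n_patients: Optional[int] = None

    def __post_init__(self):
        where = f"dynamic[{self.risk_factor}]"
        if self.risk_factor not in RISK_FACTORS:
            raise SchemaError(f"{where}: unknown risk factor")
        for name in ("phi0", "phi1", "phi2", "phi3", "phi5", "phi6", *_ETH_FIELDS):
            setattr(self, name, _check_finite(getattr(self, name), f"{where}.{name}"))
        # |phi1| < 1 gives a stable time path; exactly 1 is allowed only for
        # the last-observation-carried-forward comparator bundle
        if abs(self.phi1) > 1:
            raise SchemaError(
                f"{where}.phi1: |phi1| must be <= 1 for a stable time path "
                f"(got {self.phi1})")
        for name in ("resid_sd", "re_sd"):
            v = _check_finite(getattr(self, name), f"{where}.{name}")
            if v < 0:
                raise SchemaError(f"{where}.{name}: must be >= 0")
            setattr(self, name, v)

    def phi4(self, ethnicity: str) -> float:
        """Ethnicity effect relative to the 'other' reference category."""
        if ethnicity == "other":
            return 0.0
        try:
            return getattr(self, f"phi4_{ethnicity}")
        except AttributeError:
            raise SchemaError(f"unknown ethnicity {ethnicity!r}") from None

    @property
    def draw_sd(self) -> float:
        """Total SD of a single stochastic innovation (mu_i plus eps_it)."""
        return math.hypot(self.re_sd, self.resid_sd)


@dataclass
class SurvivalCoefficients:
    """Weibull proportional-hazards coefficients for one absorbing condition.

    With shape ``gamma = exp(ln_gamma)`` and linear predictor ``eta`` (the
    named ``betas`` dotted with the resolved covariates, constant included),
    the cumulative hazard on the diabetes-duration scale is
    ``H(t) = exp(eta) * t**gamma``.
    """

    outcome: str
    betas: dict
    ln_gamma: float
    covariate_spec: list
    se: dict = field(default_factory=dict)
    n_obs: Optional[int] = None
    n_events: Optional[int] = None

    def __post_init__(self):
        where = f"survival[{self.outcome}]"
        if self.outcome not in OUTCOMES:
            raise SchemaError(f"{where}: unknown outcome")
        self.ln_gamma = _check_finite(self.ln_gamma, f"{where}.ln_gamma")
        self.betas = {k: _check_finite(v, f"{where}.betas[{k}]")
                      for k, v in self.betas.items()}
        if "constant" not in self.betas:
            raise SchemaError(f"{where}: betas must include 'constant'")
        allowed = set(self.covariate_spec) | {"constant"}
        for name in self.betas:
            _check_vocab(name, where)
            if name not in allowed:
                raise SchemaError(f"{where}: beta {name!r} not in covariate_spec")

    @property
    def gamma(self) -> float:
        return math.exp(self.ln_gamma)


@dataclass
class TobitCoefficients:
    """Censored-normal (Tobit) value equation for eGFR in one regime.

    ``sigma`` is the SD used for the stochastic draw (the published 'standard
    error of the forecast'); draws and deterministic means are truncated to
    ``(lower_limit, upper_limit)``.
    """

    regime: str
    betas: dict
    sigma: float
    lower_limit: float
    upper_limit: float  # may be +inf
    se: dict = field(default_factory=dict)
    n_obs: Optional[int] = None

    def __post_init__(self):
        where = f"tobit[{self.regime}]"
        if self.regime not in ("below60", "atabove60"):
            raise SchemaError(f"{where}: regime must be below60|atabove60")
        self.sigma = _check_finite(self.sigma, f"{where}.sigma")
        if self.sigma <= 0:
            raise SchemaError(f"{where}.sigma: must be > 0")
        self.betas = {k: _check_finite(v, f"{where}.betas[{k}]")
                      for k, v in self.betas.items()}
        if "constant" not in self.betas:
            raise SchemaError(f"{where}: betas must include 'constant'")
        for name in self.betas:
            _check_vocab(name, where)
        self.lower_limit = float(self.lower_limit)
        self.upper_limit = float("inf") if self.upper_limit is None else float(self.upper_limit)
        if not self.lower_limit < self.upper_limit:
            raise SchemaError(f"{where}: lower_limit must be < upper_limit")


@dataclass
class CoefficientBundle:
    """All equations needed to run the annual cycle."""

    dynamic: dict      # risk factor -> DynamicCoefficients
    survival: dict     # outcome -> SurvivalCoefficients
    tobit: dict        # regime -> TobitCoefficients
    provenance: str = ""

    def __post_init__(self):
        for fac, coef in self.dynamic.items():
            if coef.risk_factor != fac:
                raise SchemaError(f"dynamic key {fac!r} != coef.risk_factor")
        for out, coef in self.survival.items():
            if coef.outcome != out:
                raise SchemaError(f"survival key {out!r} != coef.outcome")
        for reg, coef in self.tobit.items():
            if coef.regime != reg:
                raise SchemaError(f"tobit key {reg!r} != coef.regime")

    @property
    def is_complete(self) -> bool:
        return (set(self.dynamic) == set(RISK_FACTORS)
                and set(self.survival) == set(OUTCOMES)
                and set(self.tobit) == {"below60", "atabove60"})

    def require_complete(self) -> None:
        if not self.is_complete:
            missing = (sorted(set(RISK_FACTORS) - set(self.dynamic))
                       + sorted(set(OUTCOMES) - set(self.survival))
                       + sorted({"below60", "atabove60"} - set(self.tobit)))
            raise SchemaError(f"bundle is partial; missing equations: {missing}")


def _bundle_from_dict(doc: dict) -> CoefficientBundle:
    try:
        dyn_doc = doc["dynamic"]
        sur_doc = doc["survival"]
        tob_doc = doc["tobit"]
    except KeyError as exc:
        raise SchemaError(f"missing top-level section {exc.args[0]!r}") from None
    dynamic = {fac: DynamicCoefficients(risk_factor=fac, **d)
               for fac, d in dyn_doc.items()}
    survival = {out: SurvivalCoefficients(outcome=out, **d)
                for out, d in sur_doc.items()}
    tobit = {reg: TobitCoefficients(regime=reg, **d)
             for reg, d in tob_doc.items()}
    return CoefficientBundle(dynamic=dynamic, survival=survival, tobit=tobit,
                             provenance=doc.get("provenance", ""))


def _bundle_to_dict(bundle: CoefficientBundle) -> dict:
    def strip(d, key):
        d = dict(d)
        d.pop(key)
        for k in list(d):
            if d[k] is None or (k == "se" and not d[k]):
                del d[k]
        return d

    doc = {
        "provenance": bundle.provenance,
        "dynamic": {fac: strip(asdict(c), "risk_factor")
                    for fac, c in bundle.dynamic.items()},
        "survival": {out: strip(asdict(c), "outcome")
                     for out, c in bundle.survival.items()},
        "tobit": {reg: strip(asdict(c), "regime")
                  for reg, c in bundle.tobit.items()},
    }
    for reg in doc["tobit"]:
        if math.isinf(doc["tobit"][reg]["upper_limit"]):
            doc["tobit"][reg]["upper_limit"] = None
    if not bundle.is_complete:
        doc["partial"] = True
    return doc


def load_bundle(path=None) -> CoefficientBundle:
    """Load a coefficient bundle from a JSON file (default: bundled tables)."""
    if path is None:
        return default_bundle()
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    return _bundle_from_dict(doc)


def save_bundle(bundle: CoefficientBundle, path) -> str:
    """Write a bundle to JSON. ``load_bundle(save_bundle(b))`` is bit-exact
    (floats serialised via repr round-trip). Partial bundles are flagged with
    a ``"partial": true`` key."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_bundle_to_dict(bundle), fh, indent=1)
        fh.write("\n")
    return str(path)


def default_bundle() -> CoefficientBundle:
    """The bundled published coefficient tables (printed 3-dp precision)."""
    text = resources.files("riskpath").joinpath("data/default_bundle.json").read_text()
    bundle = _bundle_from_dict(json.loads(text))
    bundle.require_complete()
    return bundle
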