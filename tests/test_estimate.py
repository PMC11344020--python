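"""Estimation: oracles, recovery behaviour, stepwise, residual diagnostics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.integrate import quad

import riskpath as rp
from riskpath.estimate import (FitResult, backwards_stepwise,
                               build_dynamic_frame, cox_snell_residuals,
                               fit_dynamic_panel, fit_parametric_ph, fit_tobit,
                               tobit_loglik, tobit_mle, _ph_parts)
from riskpath.simulate import _patient_key, _STREAMS
from riskpath.synthdata import CohortSpec, PanelSpec, generate_panel


def noisy_bundle(factor="hba1c", resid_sd=0.5, re_sd=0.3):
    b = rp.default_bundle()
    b.dynamic[factor] = dataclasses.replace(b.dynamic[factor],
                                            resid_sd=resid_sd, re_sd=re_sd)
    return b


def test_noiseless_panel_is_interpolated_exactly(bundle):
    panel = generate_panel(PanelSpec(cohort=CohortSpec(n_patients=300, seed=4),
                                     follow_up=5, dropout=0.0, bundle=bundle))
    fit = fit_dynamic_panel(panel, "hba1c")
    truth = bundle.dynamic["hba1c"]
    assert fit.extra["r2"] == 1.0
    assert fit.params["lag:hba1c"] == pytest.approx(truth.phi1, abs=1e-7)
    assert fit.params["first:hba1c"] == pytest.approx(truth.phi2, abs=1e-7)
    assert fit.params["constant"] == pytest.approx(truth.phi0, abs=1e-5)
    assert fit.extra["resid_sd"] == 0.0 and fit.extra["re_sd"] == 0.0


def test_no_random_effect_matches_ols_oracle():
    """re_sd = 0: the mixed-model fixed effects collapse to OLS."""
    panel = generate_panel(PanelSpec(
        cohort=CohortSpec(n_patients=1200, seed=2), follow_up=5, dropout=0.0,
        bundle=noisy_bundle(resid_sd=0.5, re_sd=0.0)))
    fit = fit_dynamic_panel(panel, "hba1c")
    frame = build_dynamic_frame(panel, "hba1c")
    cols = [c for c in frame.columns if not c.startswith("_")]
    ols = sm.OLS(frame["_y"], frame[cols]).fit()
    assert np.abs(fit.params - ols.params).max() < 1e-6
    assert fit.extra["re_sd"] < 1e-3


def _reconstruct_random_effects(cohort, seed, factor, re_sd):
    """Rebuild the generator's patient random intercepts from the simulator's
    named substreams (independent oracle input)."""
    j = list(rp.RISK_FACTORS).index(factor)
    out = {}
    for p in cohort:
        ss = np.random.SeedSequence([int(seed), _patient_key(p.id)])
        child = ss.spawn(len(_STREAMS))[j]
        out[p.id] = np.random.default_rng(child).standard_normal(1)[0] * re_sd
    return out


def test_random_effect_fit_converges_to_conditional_law():
    """With the random intercept feeding the first post-randomisation value,
    the RE quasi-ML is consistent for the lag coefficient, demographics and
    variance components, while the first-value coefficient absorbs the
    initial-condition projection a1 = cov(mu, y1 | x)/var(y1 | x). The shift
    is verified against a projection oracle using the generator's own mu_i."""
    seed = 3
    bundle = noisy_bundle()
    spec = PanelSpec(cohort=CohortSpec(n_patients=5000, seed=seed),
                     follow_up=6, dropout=0.0, bundle=bundle)
    panel = generate_panel(spec)
    fit = fit_dynamic_panel(panel, "hba1c")
    truth = bundle.dynamic["hba1c"]

    # structural parameters: consistent
    assert abs(fit.params["lag:hba1c"] - truth.phi1) < 3 * fit.bse["lag:hba1c"]
    for name, val in [("female", truth.phi3), ("eth_white", truth.phi4_white),
                      ("eth_black", truth.phi4_black),
                      ("eth_asian", truth.phi4_asian),
                      ("age_at_rand", truth.phi5),
                      ("ln_duration", truth.phi6)]:
        assert abs(fit.params[name] - val) < 3 * fit.bse[name]
    assert abs(fit.extra["resid_sd"] - 0.5) < 0.02
    assert abs(fit.extra["re_sd"] - 0.3) < 0.03

    # initial-condition composite: first-value coefficient = phi2 + a1
    from riskpath.synthdata import generate_cohort
    cohort = generate_cohort(CohortSpec(n_patients=5000, seed=seed))
    mu = _reconstruct_random_effects(cohort, seed, "hba1c", truth.re_sd)
    d = panel.data[panel.data.year == 1][["patient", "age_at_rand", "female",
                                          "ethnicity", "hba1c"]].copy()
    d["mu"] = d["patient"].map(mu)
    Z = np.column_stack([
        np.ones(len(d)), d["hba1c"], d["female"].astype(float),
        (d["ethnicity"] == "white").astype(float),
        (d["ethnicity"] == "black").astype(float),
        (d["ethnicity"] == "asian").astype(float), d["age_at_rand"]])
    proj, *_ = np.linalg.lstsq(Z, d["mu"].to_numpy(), rcond=None)
    a1 = proj[1]
    assert a1 > 0.05  # the endogeneity is material at this noise level
    assert abs(fit.params["first:hba1c"] - (truth.phi2 + a1)) < \
        4 * fit.bse["first:hba1c"]


def test_tobit_without_censoring_matches_ols(rng):
    n = 4000
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ np.array([10.0, 2.0]) + rng.normal(0, 1.5, n)
    fit = tobit_mle(y, X, -np.inf, np.inf, names=["constant", "x"])
    ols = sm.OLS(y, X).fit()
    assert np.abs(fit.params.to_numpy() - np.asarray(ols.params)).max() < 1e-4


def test_tobit_sign_flip_invariance(rng):
    n = 500
    X = rng.normal(size=(n, 2))
    y = np.minimum(X @ np.array([1.0, -0.5]) + rng.normal(0, 1, n), 1.0)
    theta = np.array([1.0, -0.5, 0.1])
    ll = tobit_loglik(theta, y, X, -np.inf, 1.0).sum()
    ll_flipped = tobit_loglik(np.array([-1.0, 0.5, 0.1]), y, -X,
                              -np.inf, 1.0).sum()
    assert ll == pytest.approx(ll_flipped, abs=1e-10)


def test_tobit_recovery_under_censoring(rng):
    """~30% right-censored at 60: MLE recovers beta and sigma within 3 SE."""
    n = 12000
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    beta, sigma = np.array([55.0, 4.0, -3.0]), 8.0
    y = np.minimum(X @ beta + rng.normal(0, sigma, n), 60.0)
    fit = tobit_mle(y, X, 0.0, 60.0, names=["constant", "x1", "x2"])
    for name, tr in zip(fit.params.index, beta):
        assert abs(fit.params[name] - tr) < 3 * fit.bse[name]
    assert abs(fit.extra["sigma"] - sigma) < 3 * fit.extra["sigma_se"]


def test_tobit_all_censored_raises(rng):
    y = np.full(100, 60.0)
    X = np.ones((100, 1))
    with pytest.raises(ValueError, match="censored"):
        tobit_mle(y, X, 0.0, 60.0)


def weibull_intervals(rng, n=8000, lng=np.log(1.21), beta=(-3.2, 0.4),
                      trunc_frac=0.4, window=(4.0, 10.0)):
    x1 = rng.normal(size=n)
    gamma = np.exp(lng)
    eta = beta[0] + beta[1] * x1
    trunc = rng.uniform(size=n) < trunc_frac
    entry = np.where(trunc, rng.lognormal(np.log(12) - 0.125, 0.5, n), 0.01)
    u = rng.uniform(size=n)
    T = (entry ** gamma - np.log(u) / np.exp(eta)) ** (1 / gamma)
    cens = entry + rng.uniform(*window, n)
    return pd.DataFrame({"patient": np.arange(n), "t0": entry,
                         "t1": np.minimum(T, cens), "event": T <= cens,
                         "x1": x1})


def test_exponential_data_fit_with_weibull_gives_unit_shape(rng):
    iv = weibull_intervals(rng, n=10000, lng=0.0)
    fit = fit_parametric_ph(iv, "weibull")
    assert abs(fit.params["ln_gamma"]) < 3 * fit.bse["ln_gamma"]


def test_weibull_recovery_with_truncation_and_censoring(rng):
    iv = weibull_intervals(rng, n=15000)
    fit = fit_parametric_ph(iv, "weibull")
    for name, tr in [("constant", -3.2), ("x1", 0.4),
                     ("ln_gamma", np.log(1.21))]:
        assert abs(fit.params[name] - tr) < 3 * fit.bse[name]
    assert fit.extra["n_events"] == iv["event"].sum()


def test_ph_loglik_matches_quadrature_oracle(rng):
    """Interval log-likelihood terms agree with numeric cumulative-hazard
    integration at the generating parameters."""
    iv = weibull_intervals(rng, n=40)
    eta = -3.2 + 0.4 * iv["x1"].to_numpy()
    lng = np.log(1.21)
    gamma = np.exp(lng)
    ours = _ph_parts("weibull", eta, lng, iv["t0"].to_numpy(),
                     iv["t1"].to_numpy(), iv["event"].to_numpy())
    for i in range(len(iv)):
        H, _ = quad(lambda u: gamma * u ** (gamma - 1) * np.exp(eta[i]),
                    iv["t0"].iloc[i], iv["t1"].iloc[i],
                    epsabs=1e-12, epsrel=1e-12)
        lnh = (eta[i] + lng + (gamma - 1) * np.log(iv["t1"].iloc[i])
               if iv["event"].iloc[i] else 0.0)
        assert ours[i] == pytest.approx(lnh - H, abs=1e-6)


def test_loglik_at_optimum_beats_truth(rng):
    """Optimizer sanity: fitted log-likelihood >= log-likelihood at the
    generating parameters on the same data."""
    iv = weibull_intervals(rng, n=5000)
    fit = fit_parametric_ph(iv, "weibull")
    eta = -3.2 + 0.4 * iv["x1"].to_numpy()
    ll_truth = _ph_parts("weibull", eta, np.log(1.21), iv["t0"].to_numpy(),
                         iv["t1"].to_numpy(), iv["event"].to_numpy()).sum()
    assert fit.loglik >= ll_truth - 1e-8


def test_no_events_raises(rng):
    iv = weibull_intervals(rng, n=50)
    iv["event"] = False
    with pytest.raises(ValueError, match="events"):
        fit_parametric_ph(iv, "weibull")


def test_cox_snell_residuals_behave_like_unit_exponential(rng):
    """Nelson–Aalen slope of the residuals within [0.9, 1.1] when the model
    is correct; residuals are non-negative; zero exposure gives zero."""
    from lifelines import NelsonAalenFitter

    iv = weibull_intervals(rng, n=20000)
    fit = fit_parametric_ph(iv, "weibull")
    res = cox_snell_residuals(fit, iv)
    assert (res["residual"] >= 0).all()
    naf = NelsonAalenFitter()
    naf.fit(res["residual"], event_observed=res["event"])
    na = naf.cumulative_hazard_
    x = na.index.to_numpy()
    y = na.iloc[:, 0].to_numpy()
    keep = (x > 0) & (x < np.quantile(res["residual"][res["event"]], 0.95))
    slope = np.sum(x[keep] * y[keep]) / np.sum(x[keep] ** 2)
    assert 0.9 < slope < 1.1

    zero = iv.iloc[:5].copy()
    zero["t1"] = zero["t0"]
    zero["event"] = False
    r0 = cox_snell_residuals(fit, zero)
    assert np.allclose(r0["residual"], 0.0)


# ---------------------------------------------------------------------------
# stepwise
# ---------------------------------------------------------------------------

def ols_fitter(df, covariates):
    X = df[covariates]
    res = sm.OLS(df["_y"], X).fit()
    return FitResult(params=res.params, bse=res.bse, pvalues=res.pvalues,
                     loglik=res.llf, aic=res.aic, n_obs=len(df),
                     n_patients=len(df), converged=True)


def test_stepwise_keeps_model_when_all_significant(rng):
    n = 2000
    df = pd.DataFrame({"constant": 1.0, "x1": rng.normal(size=n),
                       "x2": rng.normal(size=n)})
    df["_y"] = 1.0 + 0.5 * df.x1 - 0.5 * df.x2 + rng.normal(0, 0.5, n)
    fit = backwards_stepwise(ols_fitter, df, ["constant", "x1", "x2"])
    assert fit.extra["selected"] == ["x1", "x2"]


def test_stepwise_always_keeps_strong_covariate(rng):
    """A 10-SE effect survives selection in every replicate."""
    for rep in range(25):
        n = 400
        df = pd.DataFrame({"constant": np.ones(n)})
        df["strong"] = rng.normal(size=n)
        for j in range(5):
            df[f"noise{j}"] = rng.normal(size=n)
        beta_strong = 10.0 / np.sqrt(n)  # ~10 SE at unit noise
        df["_y"] = beta_strong * df["strong"] + rng.normal(0, 1.0, n)
        fit = backwards_stepwise(
            ols_fitter, df, ["constant", "strong"] + [f"noise{j}" for j in range(5)])
        assert "strong" in fit.extra["selected"]


def test_stepwise_can_return_constant_only(rng):
    n = 3000
    df = pd.DataFrame({"constant": 1.0, "x1": rng.normal(size=n)})
    df["_y"] = rng.normal(size=n)
    fit = backwards_stepwise(ols_fitter, df, ["constant", "x1"],
                             alpha=1e-6)
    assert fit.extra["selected"] == []
    assert list(fit.params.index) == ["constant"]


def test_fit_save_load_simulate_roundtrip(tmp_path):
    """Refit from a synthetic panel, write a bundle file, reload it, and
    check the simulated mean trajectory matches the generating bundle."""
    bundle = rp.default_bundle()
    spec = PanelSpec(cohort=CohortSpec(n_patients=800, seed=9), follow_up=6,
                     dropout=0.0, bundle=bundle)
    panel = generate_panel(spec)
    refit_dyn = {}
    for fac in rp.RISK_FACTORS:
        refit_dyn[fac] = fit_dynamic_panel(panel, fac).to_dynamic_coefficients(fac)
    refit = rp.CoefficientBundle(dynamic=refit_dyn, survival=bundle.survival,
                                 tobit=bundle.tobit, provenance="refit")
    path = tmp_path / "refit.json"
    rp.save_bundle(refit, path)
    reloaded = rp.load_bundle(path)

    from riskpath.synthdata import generate_cohort
    cohort = generate_cohort(CohortSpec(n_patients=300, seed=10))
    cfg = rp.SimulationConfig(horizon=8, mode="deterministic")
    a = rp.simulate_cohort(bundle, cohort, cfg).data
    b = rp.simulate_cohort(reloaded, cohort, cfg).data
    for fac in rp.RISK_FACTORS:
        diff = (a.groupby("year")[fac].mean() - b.groupby("year")[fac].mean())
        scale = a[fac].abs().mean()
        assert (diff.abs() / scale).max() < 0.02
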