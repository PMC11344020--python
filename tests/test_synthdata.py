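"""Synthetic cohorts, panels and preprocessing rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import riskpath as rp
from riskpath.simulate import locf_bundle
from riskpath.synthdata import (CohortSpec, PanelSpec, assemble_panel,
                                generate_cohort, generate_panel,
                                nearest_positive_definite, preprocess_panel)


def test_cohort_reproducible_from_seed():
    a = generate_cohort(CohortSpec(n_patients=50, seed=7))
    b = generate_cohort(CohortSpec(n_patients=50, seed=7))
    assert all(pa.current == pb.current and pa.duration == pb.duration
               for pa, pb in zip(a, b))
    c = generate_cohort(CohortSpec(n_patients=50, seed=8))
    assert any(pa.current != pc.current for pa, pc in zip(a, c))


def test_cohort_hits_population_anchors():
    """Trial-population anchors: mean age ~64, mean diabetes duration ~16."""
    cohort = generate_cohort(CohortSpec(n_patients=20000, seed=1))
    age = np.array([p.age_at_rand for p in cohort])
    dur = np.array([p.duration for p in cohort])
    assert abs(age.mean() - 64.0) < 3 * age.std() / np.sqrt(len(age))
    assert abs(dur.mean() - 16.0) < 3 * dur.std() / np.sqrt(len(dur))
    eth = pd.Series([p.ethnicity for p in cohort]).value_counts(normalize=True)
    assert abs(eth["white"] - 0.75) < 0.02
    fem = np.mean([p.female for p in cohort])
    assert abs(fem - 0.30) < 0.02
    for p in cohort[:100]:
        assert p.current == p.first_recorded
        assert not any(p.flags.values())


def test_zero_variance_spec_gives_identical_patients():
    spec = CohortSpec(n_patients=10, seed=0, age_sd=0.0, duration_sdlog=0.0,
                      female_prop=0.0, smoking_prev=0.0,
                      ethnicity_props={"white": 1.0, "black": 0.0,
                                       "asian": 0.0, "other": 0.0},
                      factor_sds={f: 0.0 for f in
                                  list(rp.RISK_FACTORS) + ["egfr"]})
    cohort = generate_cohort(spec)
    ref = cohort[0]
    assert all(p.current == ref.current and p.duration == ref.duration
               and p.age_at_rand == ref.age_at_rand for p in cohort)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        CohortSpec(ethnicity_props={"white": 0.9, "black": 0.9,
                                    "asian": 0.0, "other": 0.0})
    with pytest.raises(ValueError, match="follow_up"):
        PanelSpec(follow_up=1)
    with pytest.raises(ValueError, match="dropout"):
        PanelSpec(dropout=1.0)


def test_infeasible_correlation_repaired_with_warning():
    bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    fixed = nearest_positive_definite(bad)
    assert np.linalg.eigvalsh(fixed).min() > 0
    assert np.allclose(np.diag(fixed), 1.0)
    k = len(rp.RISK_FACTORS) + 1
    corr = np.full((k, k), 0.99)
    np.fill_diagonal(corr, 1.0)
    corr[0, 1] = corr[1, 0] = -0.99  # jointly infeasible
    with pytest.warns(UserWarning, match="nearest-PD"):
        generate_cohort(CohortSpec(n_patients=10, seed=0, corr=corr))


def test_clean_panel_equals_deterministic_trajectory(bundle):
    """No noise, dropout or missingness, and no published dynamic error
    terms: the measured factor paths equal the deterministic simulation
    (eGFR keeps its forecast-SD draw by construction)."""
    spec = PanelSpec(cohort=CohortSpec(n_patients=150, seed=6), follow_up=4,
                     dropout=0.0, bundle=bundle)
    panel = generate_panel(spec)
    cohort = generate_cohort(CohortSpec(n_patients=150, seed=6))
    det = rp.simulate_cohort(bundle, cohort,
                             rp.SimulationConfig(horizon=4,
                                                 mode="deterministic",
                                                 y_first_source="first_simulated"))
    obs = panel.data[panel.data.year >= 1].sort_values(["patient", "year"])
    sim = det.data.sort_values(["patient", "year"])
    for fac in rp.RISK_FACTORS:
        assert np.allclose(obs[fac].to_numpy(), sim[fac].to_numpy(), atol=1e-9)


def test_dropout_retention_matches_binomial(bundle):
    spec = PanelSpec(cohort=CohortSpec(n_patients=8000, seed=12), follow_up=6,
                     dropout=0.1, bundle=bundle)
    panel = generate_panel(spec)
    n6 = panel.data[panel.data.year == 6]["patient"].nunique()
    expected = 0.9 ** 5
    se = np.sqrt(expected * (1 - expected) / 8000)
    assert abs(n6 / 8000 - expected) < 3 * se


def test_event_times_respect_generating_survivor_function(bundle):
    """Fixed covariates (identity dynamics, zero-variance cohort): recorded
    onset times follow the analytic conditional Weibull law (KS, alpha=0.01)."""
    surv = bundle.survival["ALB"]
    frozen = rp.CoefficientBundle(dynamic=locf_bundle().dynamic,
                                  survival=bundle.survival,
                                  tobit=locf_bundle().tobit)
    spec = CohortSpec(n_patients=10000, seed=5, age_sd=0.0, duration_sdlog=0.0,
                      female_prop=0.0, smoking_prev=0.0,
                      ethnicity_props={"white": 1.0, "black": 0.0,
                                       "asian": 0.0, "other": 0.0},
                      factor_sds={f: 0.0 for f in
                                  list(rp.RISK_FACTORS) + ["egfr"]})
    cohort = generate_cohort(spec)
    horizon = 40
    traj = rp.simulate_cohort(frozen, cohort,
                              rp.SimulationConfig(horizon=horizon,
                                                  mode="stochastic", seed=5))
    ev = traj.event_times
    alb = ev[(ev.outcome == "ALB") & ev.event]
    t0 = cohort[0].duration
    state = cohort[0]
    eta = sum(surv.betas[k] * (1.0 if k == "constant"
                               else {"age_at_rand": state.age_at_rand,
                                     "female": 0.0, "eth_white": 1.0,
                                     "lag:bmi": state.current["bmi"],
                                     "lag:sbp": state.current["sbp"],
                                     "lag:hba1c": state.current["hba1c"]}[k])
              for k in surv.betas)
    gamma = np.exp(surv.ln_gamma)
    H = lambda t: np.exp(eta) * t ** gamma
    denom = 1 - np.exp(H(t0) - H(t0 + horizon))

    def cdf(t):
        return (1 - np.exp(H(t0) - H(np.asarray(t)))) / denom

    assert len(alb) > 500
    stat, p = stats.kstest(alb["time"].to_numpy(), cdf)
    assert p > 0.01


def raw_visits():
    rows = [
        # patient A: baseline + in-range yearly values, one early measurement
        ("A", 0, "hba1c", 7.0), ("A", 3, "hba1c", 6.0),   # month 3: excluded
        ("A", 9, "hba1c", 7.0), ("A", 11, "hba1c", 7.4),  # year 1 -> 7.2
        ("A", 20, "hba1c", 7.6), ("A", 22, "hba1c", 99.0),  # out of range
        # patient B: hba1c at baseline only -> excluded from the hba1c panel
        # (keeps a follow-up sbp so B did not withdraw outright)
        ("B", 0, "hba1c", 8.0), ("B", 0, "sbp", 140.0), ("B", 14, "sbp", 138.0),
        # patient C: no baseline -> excluded
        ("C", 14, "hba1c", 7.1),
        # patient D: withdrew on randomisation day
        ("D", 0, "hba1c", 7.7), ("D", 0, "sbp", 130.0),
    ]
    return pd.DataFrame(rows, columns=["patient", "month", "variable", "value"])


def test_preprocess_rules_and_logging():
    annual, log = preprocess_panel(raw_visits(), ranges={"hba1c": (3, 20),
                                                         "sbp": (60, 250)})
    a = annual[annual.patient == "A"].set_index("year")["value"]
    assert a[1] == pytest.approx(7.2)      # mean of 7.0 and 7.4
    assert a[2] == pytest.approx(7.6)      # 99.0 filtered as out of range
    assert log["early_measurements_dropped"] == 1
    assert log["out_of_range_dropped"] == 1
    assert log["withdrew_at_randomisation"] == 1
    assert "B" not in set(annual[annual.variable == "hba1c"].patient)
    assert "C" not in set(annual.patient)  # no baseline
    assert "D" not in set(annual.patient)


def test_preprocess_missing_ethnicity_exclusion():
    demo = pd.DataFrame({"patient": ["A", "B", "C", "D"],
                         "ethnicity": ["white", None, "asian", "white"]})
    annual, log = preprocess_panel(raw_visits(), ranges={"hba1c": (3, 20)},
                                   demographics=demo)
    assert log["missing_ethnicity"] == 1
    assert "B" not in set(annual.patient)


def test_preprocess_is_idempotent():
    annual, _ = preprocess_panel(raw_visits(), ranges={"hba1c": (3, 20)})
    again, _ = preprocess_panel(annual[["patient", "month", "variable",
                                        "value"]],
                                ranges={"hba1c": (3, 20)})
    pd.testing.assert_frame_equal(
        annual.reset_index(drop=True), again.reset_index(drop=True))


def test_assemble_panel_roundtrip():
    annual, _ = preprocess_panel(raw_visits(), ranges={"hba1c": (3, 20)})
    demo = pd.DataFrame({"patient": ["A"], "age_at_rand": [64.0],
                         "female": [True], "ethnicity": ["white"],
                         "smoker_baseline": [False], "duration": [16.0]})
    panel = assemble_panel(annual, demo)
    assert set(panel.data["patient"]) == {"A"}
    row = panel.data[panel.data.year == 1].iloc[0]
    assert row["hba1c"] == pytest.approx(7.2)
    assert row["duration"] == pytest.approx(17.0)
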