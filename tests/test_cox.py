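import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import lifegain as lg
from lifegain.cox import (
    WeightedCoxModel,
    rcs_basis,
    sandwich_covariance,
    spline_dose_response,
    stratified_and_interaction,
)

COVS = ("age", "sex", "smoking")  # the covariates with true effects in the simulator


def minimal_cohort(groups, times, events, weights=None):
    n = len(groups)
    return pd.DataFrame(
        {
            "group": groups,
            "followup_years": np.asarray(times, float),
            "event": ["other" if e else "censored" for e in events],
            "weight": np.ones(n) if weights is None else np.asarray(weights, float),
        }
    )


class TestPartialLikelihoodOracle:
    def test_two_group_toy_matches_brute_force(self):
        """On 4 subjects with distinct event times the Cox estimate must equal
        the argmax of the exact partial likelihood found by 1-D search."""
        x = np.array([0, 1, 0, 1], float)  # none, moderate, none, moderate

        def neg_log_pl(beta):
            # event order is t = 1, 2, 3, 4; risk sets shrink from the left
            ll = 0.0
            for i in range(4):
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[i:])))
            return -ll

        oracle = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded").x
        cohort = minimal_cohort(
            ["none", "moderate", "none", "moderate"], [1, 2, 3, 4], [1, 1, 1, 1]
        )
        res = WeightedCoxModel(cohort, covariates=(), robust=False).fit()
        beta = res.hazard_estimates.set_index("group").loc["moderate", "beta"]
        assert beta == pytest.approx(oracle, abs=1e-4)

    def test_weight_scale_invariance(self, small_cohort):
        res1 = WeightedCoxModel(small_cohort, covariates=COVS).fit()
        scaled = small_cohort.assign(weight=small_cohort["weight"] * 7.3)
        res2 = WeightedCoxModel(scaled, covariates=COVS).fit()
        assert np.allclose(res1.params, res2.params, atol=1e-8)

    def test_duplicate_records_halved_weights(self):
        rng = np.random.default_rng(0)
        n = 200
        cohort = minimal_cohort(
            rng.choice(["none", "low", "moderate"], n),
            rng.exponential(5, n) + 0.1,
            rng.random(n) < 0.5,
        )
        doubled = pd.concat([cohort, cohort], ignore_index=True)
        doubled["weight"] = 0.5
        b1 = WeightedCoxModel(cohort, covariates=(), robust=False).fit().params
        b2 = WeightedCoxModel(doubled, covariates=(), robust=False).fit().params
        # Efron's sequential treatment of the ties created by duplication is
        # not exactly invariant to splitting a subject into half-weight
        # copies (Breslow would be); the identity holds to first order.
        assert np.allclose(b1, b2, atol=0.01)


class TestRobustVariance:
    def test_sandwich_matches_lifelines(self):
        """The vectorized sandwich must reproduce lifelines' delta-beta
        robust standard errors (independent implementation route)."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 2000
        df = pd.DataFrame(
            {
                "__t": rng.exponential(10, n) + 0.01,
                "__e": (rng.random(n) < 0.2).astype(int),
                "__w": rng.lognormal(0, 0.5, n),
                "x0": rng.normal(size=n),
                "x1": rng.normal(size=n),
            }
        )
        ref = CoxPHFitter()
        ref.fit(df, "__t", "__e", weights_col="__w", robust=True)
        V = sandwich_covariance(ref, df, ["x0", "x1"])
        assert np.allclose(np.sqrt(np.diag(V)), ref.standard_errors_, rtol=1e-6)

    def test_robust_se_larger_than_naive_under_weighting(self, small_cohort):
        robust = WeightedCoxModel(small_cohort, covariates=COVS).fit()
        naive = WeightedCoxModel(small_cohort, covariates=COVS, robust=False).fit()
        he_r = robust.hazard_estimates.set_index("group")["se"]
        he_n = naive.hazard_estimates.set_index("group")["se"]
        # heterogeneous weights inflate sampling variance vs the naive SE
        assert (he_r.drop("none") > he_n.drop("none") * 0.95).all()
        assert he_r.drop("none").mean() > he_n.drop("none").mean()


class TestEstimation:
    def test_null_effects_give_null_betas(self):
        cfg = lg.SimulationConfig(
            n_participants=10_000,
            true_loghr_by_cause={c: (0.0,) * 5 for c in lg.CAUSES},
        )
        n_total, n_within = 0, 0
        for seed in range(4):
            cohort = lg.derive_exposure(
                lg.generate_cohort(cfg.replace(seed=300 + seed)), source="true"
            )
            he = WeightedCoxModel(cohort, covariates=COVS).fit().hazard_estimates
            he = he[he["group"] != "none"]
            n_total += len(he)
            n_within += (he["beta"].abs() < 3 * he["se"]).sum()
            assert (he["beta"].abs() < 4.5 * he["se"]).all()
        assert n_within / n_total >= 0.9

    def test_no_leakage_between_causes(self):
        """An effect planted on CVD mortality only must appear in the CVD fit
        and stay null in the cancer fit."""
        cfg = lg.SimulationConfig(
            n_participants=20_000,
            true_loghr_by_cause={
                "cvd": (0.0, 0.0, -0.5, 0.0, 0.0),
                "cancer": (0.0,) * 5,
                "other": (0.0,) * 5,
            },
        )
        cohort = lg.derive_exposure(lg.generate_cohort(cfg.replace(seed=77)), source="true")
        cvd = WeightedCoxModel(cohort, cause="cvd", covariates=COVS).fit()
        can = WeightedCoxModel(cohort, cause="cancer", covariates=COVS).fit()
        b_cvd = cvd.hazard_estimates.set_index("group").loc["moderate"]
        b_can = can.hazard_estimates.set_index("group").loc["moderate"]
        assert abs(b_cvd["beta"] - (-0.5)) < 3 * b_cvd["se"]
        assert abs(b_can["beta"]) < 3 * b_can["se"]
        assert b_cvd["beta"] < -0.25

    def test_zero_event_group_flagged_not_dropped(self):
        cohort = minimal_cohort(
            ["none"] * 30 + ["moderate"] * 30 + ["high"] * 20,
            np.r_[np.linspace(1, 10, 60), np.linspace(1, 10, 20)],
            [1] * 60 + [0] * 20,
        )
        he = WeightedCoxModel(cohort, covariates=()).fit().hazard_estimates
        he = he.set_index("group")
        assert not he.loc["high", "identifiable"]
        assert np.isnan(he.loc["high", "beta"])
        assert he.loc["moderate", "identifiable"]

    def test_events_counted_per_cause(self, small_cohort):
        he = WeightedCoxModel(small_cohort, cause="cvd", covariates=COVS).fit()
        est = he.hazard_estimates
        assert est["n_events"].sum() == (small_cohort["event"] == "cvd").sum()

    def test_summary_mentions_groups(self, small_cohort):
        res = WeightedCoxModel(small_cohort, covariates=COVS).fit()
        text = res.summary()
        for g in lg.GROUP_LABELS:
            assert g in text


class TestTrendTests:
    def test_planted_linear_trend(self):
        cfg = lg.SimulationConfig(
            n_participants=15_000,
            true_loghr_by_cause={c: tuple(-0.12 * k for k in range(5)) for c in lg.CAUSES},
        )
        cohort = lg.derive_exposure(lg.generate_cohort(cfg.replace(seed=2)), source="true")
        tr = WeightedCoxModel(cohort, covariates=COVS).fit().trend_tests()
        assert tr.p_linear < 1e-6
        assert tr.p_nonlinear > 0.05

    def test_planted_u_shape_flags_nonlinearity(self):
        cfg = lg.SimulationConfig(
            n_participants=15_000,
            true_loghr_by_cause={c: (0.0, -0.3, -0.42, -0.3, 0.0) for c in lg.CAUSES},
        )
        cohort = lg.derive_exposure(lg.generate_cohort(cfg.replace(seed=3)), source="true")
        tr = WeightedCoxModel(cohort, covariates=COVS).fit().trend_tests()
        assert tr.p_nonlinear < 0.01

    def test_null_trend_pvalues_not_extreme(self):
        cfg = lg.SimulationConfig(
            n_participants=10_000,
            true_loghr_by_cause={c: (0.0,) * 5 for c in lg.CAUSES},
        )
        cohort = lg.derive_exposure(lg.generate_cohort(cfg.replace(seed=31)), source="true")
        tr = WeightedCoxModel(cohort, covariates=COVS).fit().trend_tests()
        assert 0.001 < tr.p_linear <= 1.0
        assert 0.001 < tr.p_nonlinear <= 1.0


def simulate_continuous_dose(n, seed, effect):
    """Exposure-only simulation with a log hazard that is an arbitrary
    function of continuous cups (independent of the cohort generator)."""
    rng = np.random.default_rng(seed)
    cups = np.where(rng.random(n) < 0.4, 0.0, rng.gamma(2.0, 1.2, n))
    loghr = effect(cups)
    t = rng.exponential(1.0 / (0.05 * np.exp(loghr)), n)
    c = rng.uniform(2, 15, n)
    return pd.DataFrame(
        {
            "cups": cups,
            "followup_years": np.minimum(t, c),
            "event": np.where(t <= c, "other", "censored"),
            "weight": np.ones(n),
        }
    )


class TestSplineDoseResponse:
    def test_u_shape_minimum_near_two_cups(self):
        df = simulate_continuous_dose(30_000, 5, lambda c: 0.12 * (c - 2.0) ** 2)
        curve, p_nl = spline_dose_response(df, covariates=(), robust=False)
        argmin = curve.loc[curve["hr"].idxmin(), "cups"]
        assert 1.5 <= argmin <= 2.5
        assert p_nl < 0.01

    def test_curve_anchored_at_zero_cups(self):
        df = simulate_continuous_dose(5_000, 6, lambda c: -0.1 * c)
        curve, _ = spline_dose_response(df, covariates=(), robust=False)
        assert curve["hr"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_null_effect_ci_covers_one(self):
        df = simulate_continuous_dose(20_000, 7, lambda c: 0.0 * c)
        curve, _ = spline_dose_response(df, covariates=(), robust=False)
        covered = (curve["ci_lo"] <= 1.0) & (1.0 <= curve["ci_hi"])
        assert covered.mean() > 0.9

    def test_knots_outside_range_rejected(self):
        df = simulate_continuous_dose(500, 8, lambda c: 0.0 * c)
        with pytest.raises(ValueError):
            spline_dose_response(df, covariates=(), knots=[0, 2, 99])

    def test_rcs_basis_linear_outside_boundary_knots(self):
        knots = [1.0, 2.0, 3.0]
        x = np.array([4.0, 5.0, 6.0])
        B = rcs_basis(x, knots)
        # beyond the last knot every basis column is linear in x
        slopes1 = np.diff(B[:, 1])
        assert np.allclose(slopes1, slopes1[0])


def simulate_crossing_hazards(n, seed):
    """Two groups whose hazards cross at t = 5 (strong PH violation)."""
    rng = np.random.default_rng(seed)
    grp = rng.random(n) < 0.5
    h_early = np.where(grp, 0.02, 0.10)
    h_late = np.where(grp, 0.30, 0.10)
    t1 = rng.exponential(1.0 / h_early)
    t2 = 5.0 + rng.exponential(1.0 / h_late)
    t = np.where(t1 < 5.0, t1, t2)
    c = rng.uniform(2, 15, n)
    return pd.DataFrame(
        {
            "group": np.where(grp, "moderate", "none"),
            "followup_years": np.minimum(t, c),
            "event": np.where(t <= c, "other", "censored"),
            "weight": np.ones(n),
        }
    )


class TestPHDiagnostics:
    def test_proportional_data_passes(self, small_cohort):
        res = WeightedCoxModel(small_cohort, covariates=COVS).fit()
        diag = res.ph_diagnostics()
        assert diag.loc["GLOBAL", "p"] > 0.01

    def test_crossing_hazards_detected(self):
        df = simulate_crossing_hazards(4000, 9)
        res = WeightedCoxModel(df, covariates=()).fit()
        diag = res.ph_diagnostics()
        assert diag.loc["GLOBAL", "p"] < 0.01
        assert diag.loc["exposure[moderate]", "p"] < 0.01

    def test_single_group_model_has_empty_exposure_entry(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "group": ["none"] * 500,
                "age": rng.uniform(30, 80, 500),
                "followup_years": rng.exponential(8, 500) + 0.01,
                "event": np.where(rng.random(500) < 0.3, "other", "censored"),
                "weight": np.ones(500),
            }
        )
        res = WeightedCoxModel(df, covariates=("age",)).fit()
        assert len(res.exposure_ph_pvalues()) == 0


def simulate_sex_specific_effect(n, seed, beta_male, beta_female):
    rng = np.random.default_rng(seed)
    male = rng.random(n) < 0.5
    grp = rng.random(n) < 0.4
    beta = np.where(male, beta_male, beta_female) * grp
    t = rng.exponential(1.0 / (0.06 * np.exp(beta)))
    c = rng.uniform(2, 15, n)
    return pd.DataFrame(
        {
            "group": np.where(grp, "moderate", "none"),
            "sex": np.where(male, "male", "female"),
            "followup_years": np.minimum(t, c),
            "event": np.where(t <= c, "other", "censored"),
            "weight": np.ones(n),
        }
    )


class TestStratifiedAndInteraction:
    def test_homogeneous_effect_interaction_null(self):
        df = simulate_sex_specific_effect(8000, 11, -0.3, -0.3)
        per, p_int = stratified_and_interaction(df, "sex", covariates=())
        assert set(per) == {"female", "male"}
        assert p_int > 0.01

    def test_opposite_effects_detected(self):
        df = simulate_sex_specific_effect(8000, 12, -0.5, 0.5)
        per, p_int = stratified_and_interaction(df, "sex", covariates=())
        assert p_int < 0.001
        b_m = per["male"].set_index("group").loc["moderate", "beta"]
        b_f = per["female"].set_index("group").loc["moderate", "beta"]
        assert b_m < 0 < b_f

    def test_single_level_stratum_equals_pooled(self):
        df = simulate_sex_specific_effect(3000, 13, -0.3, -0.3)
        df["sex"] = "female"
        per, p_int = stratified_and_interaction(df, "sex", covariates=())
        pooled = WeightedCoxModel(df, covariates=()).fit().hazard_estimates
        got = per["female"].set_index("group")["beta"]
        want = pooled.set_index("group")["beta"]
        assert np.allclose(got, want, atol=1e-10)
        assert p_int is None

    def test_race_other_excluded(self, small_cohort):
        per, _ = stratified_and_interaction(
            small_cohort, "race", covariates=("age", "sex")
        )
        assert "other" not in per

    def test_subtype_strata_share_nondrinker_reference(self, small_cohort):
        per, p_int = stratified_and_interaction(
            small_cohort, "caffeinated", covariates=("age", "sex")
        )
        assert set(per) == {"caffeinated=True", "caffeinated=False"}
        assert p_int is None
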