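"""Model suite: standardization, candidate set, OLS fits, AICc, contrasts."""

import numpy as np
import pandas as pd
import pytest

from plungedee import models as M
from plungedee.models import (Design, activity_rates, aicc, aicc_rank,
                              candidate_models, fit_dee_model,
                              group_difference, predictive_r,
                              standardize_daily, time_budget)
from plungedee.simulate import SimScenario, simulate_budget_summaries


class TestStandardize:
    def test_arithmetic(self):
        assert standardize_daily(120.0, 48.0) == pytest.approx(60.0)

    def test_24h_identity(self):
        assert standardize_daily(37.5, 24.0) == pytest.approx(37.5)

    def test_linearity_over_activities(self, rng):
        parts = rng.random(4) * 10
        h = 37.0
        assert standardize_daily(parts, h).sum() == pytest.approx(
            float(standardize_daily(parts.sum(), h)))

    def test_short_deployment_warns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            standardize_daily(10.0, 12.0)


class TestTimeBudget:
    def test_all_colony(self):
        tb = time_budget(np.zeros(600, dtype=int))
        assert np.allclose(tb, [24.0, 0, 0, 0])

    def test_equal_quarters(self):
        states = np.repeat([0, 1, 2, 3], 360)
        assert np.allclose(time_budget(states), [6.0, 6, 6, 6])

    def test_sums_to_24(self, rng):
        states = rng.integers(0, 4, 3000)
        assert time_budget(states).sum() == pytest.approx(24.0)


class TestCandidateSet:
    def test_twelve_designs(self):
        designs = candidate_models()
        assert len(designs) == 12
        kinds = [d.kind for d in designs]
        assert kinds.count("time") == 5 and kinds.count("dba") == 5
        assert kinds.count("intercept") == 1 and kinds.count("dba_total") == 1

    def test_groups_partition_activities(self):
        for d in candidate_models():
            if d.kind in ("time", "dba"):
                flat = sorted(a for g in d.groups for a in g)
                assert flat == sorted(M.ACTIVITIES)

    def test_reported_leading_designs_present(self):
        names = {d.name for d in candidate_models()}
        # colony+resting vs commuting+foraging; colony vs everything away
        assert "DBA: col+rest | com+for" in names
        assert "DBA: col | com+for+rest" in names

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            Design(name="bad", kind="time", groups=(("col",), ("com", "for")))


def _summaries(n=12, seed=0, msdee=None):
    rng = np.random.default_rng(seed)
    t = rng.dirichlet(np.ones(4), size=n) * 24.0
    s = pd.DataFrame(t, columns=[f"T_{a}" for a in M.ACTIVITIES])
    for j, a in enumerate(M.ACTIVITIES):
        s[f"DBA_{a}"] = t[:, j] * (j + 1) * 10
    s["DBA_total"] = s[[f"DBA_{a}" for a in M.ACTIVITIES]].sum(axis=1)
    s["bird"] = [f"B{i}" for i in range(n)]
    s["msDEE"] = msdee if msdee is not None else rng.uniform(0.8, 1.4, n)
    return s


class TestFit:
    def test_noise_free_two_group_recovery(self):
        s = _summaries(n=10, seed=3)
        y = 2.0 * (s["T_col"] + s["T_rest"]) + 5.0 * (s["T_com"] + s["T_for"])
        s["msDEE"] = y
        d = Design(name="T: col+rest | com+for", kind="time",
                   groups=(("col", "rest"), ("com", "for")))
        fit = fit_dee_model(d, s)
        assert fit.coef["T_col+rest"] == pytest.approx(2.0, rel=1e-9)
        assert fit.coef["T_com+for"] == pytest.approx(5.0, rel=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_single_activity_collapse(self):
        """All birds in one activity: the pooled coefficient is mean(msDEE)/24."""
        s = _summaries(n=8, seed=4)
        for a in M.ACTIVITIES:
            s[f"T_{a}"] = 0.0
        s["T_col"] = 24.0
        d = Design(name="T: all", kind="time",
                   groups=(("col", "com", "for", "rest"),))
        fit = fit_dee_model(d, s)
        assert fit.coef["T_col+com+for+rest"] == pytest.approx(
            s["msDEE"].mean() / 24.0, rel=1e-9)

    def test_collinear_groups_reported(self):
        s = _summaries(n=10, seed=5)
        s["DBA_col"] = 0.0
        s["DBA_rest"] = 0.0  # two all-zero groups are collinear
        d = Design(name="DBA: full", kind="dba",
                   groups=(("col",), ("com",), ("for",), ("rest",)))
        with pytest.raises(ValueError, match="collinear"):
            fit_dee_model(d, s)

    def test_too_few_birds_rejected(self):
        s = _summaries(n=4, seed=6)
        d = candidate_models()[0]  # 4 predictors
        with pytest.raises(ValueError, match="need at least"):
            fit_dee_model(d, s)


class TestAicc:
    def test_hand_oracle_gaussian(self):
        """AICc from n, RSS and k matches the closed-form Gaussian expression."""
        n, rss, k = 20, 5.0, 4
        loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
        expected = (n * np.log(rss / n) + n * np.log(2 * np.pi) + n
                    + 2 * k + 2 * k * (k + 1) / (n - k - 1))
        assert aicc(loglik, k, n) == pytest.approx(expected, rel=1e-12)

    def test_duplicated_fit_ties_at_zero(self):
        s = _summaries(n=15, seed=7)
        d = Design(name="T: col | rest of day", kind="time",
                   groups=(("col",), ("com", "for", "rest")))
        f1, f2 = fit_dee_model(d, s), fit_dee_model(d, s)
        rank = aicc_rank([f1, f2])
        assert np.allclose(rank["dAICc"], 0.0)

    def test_undefined_correction_excluded(self):
        s = _summaries(n=8, seed=8)
        small = Design(name="T: col | away", kind="time",
                       groups=(("col",), ("com", "for", "rest")))
        big = Design(name="T: full", kind="time",
                     groups=(("col",), ("com",), ("for",), ("rest",)))
        f_small, f_big = fit_dee_model(small, s), fit_dee_model(big, s)
        f_big.n = 6  # n - k - 1 = 0 for k = 5
        f_small.n = 6
        with pytest.warns(UserWarning, match="excluded"):
            rank = aicc_rank([f_small, f_big])
        assert len(rank) == 1

    def test_mismatched_responses_rejected(self):
        f1 = fit_dee_model(candidate_models()[1], _summaries(n=12))
        f2 = fit_dee_model(candidate_models()[1], _summaries(n=13))
        with pytest.raises(ValueError, match="response"):
            aicc_rank([f1, f2])


class TestPredictiveR:
    def test_perfect_fit(self):
        s = _summaries(n=10, seed=9)
        s["msDEE"] = 3.0 * (s["T_col"] + s["T_rest"]) + 7.0 * (s["T_com"] + s["T_for"])
        d = Design(name="t", kind="time", groups=(("col", "rest"), ("com", "for")))
        fit = fit_dee_model(d, s)
        assert predictive_r(fit, s) == pytest.approx(1.0)

    def test_intercept_only_undefined(self):
        s = _summaries(n=10, seed=10)
        fit = fit_dee_model(Design(name="null", kind="intercept"), s)
        assert np.isnan(predictive_r(fit, s))

    def test_r_squared_identity_free_intercept(self):
        """For an OLS fit with intercept, r^2 equals the regression R^2."""
        s = _summaries(n=25, seed=11)
        fit = fit_dee_model(Design(name="null: total DBA", kind="dba_total"), s)
        r = predictive_r(fit, s)
        y = s["msDEE"].to_numpy()
        r2 = 1.0 - fit.rss / ((y - y.mean()) ** 2).sum()
        assert r ** 2 == pytest.approx(r2, abs=1e-10)


class TestActivityRates:
    def test_recovers_ratio_and_bmr_scaling(self):
        s = _summaries(n=15, seed=12)
        rates = {"col": 0.03, "com": 0.09, "for": 0.15, "rest": 0.08}
        s["msDEE"] = sum(r * s[f"T_{a}"] for a, r in rates.items())
        d = candidate_models()[0]
        fit = fit_dee_model(d, s)
        tab = activity_rates(fit, reference_mass_g=1500.0, bmr_w=4.39)
        row = tab.set_index("activity")
        assert row.loc["for", "ratio_vs_colony"] == pytest.approx(5.0, rel=1e-6)
        # watts = MR * mass / 3.6; x_bmr = watts / bmr
        assert row.loc["com", "watts"] == pytest.approx(0.09 * 1500 / 3.6, rel=1e-6)
        # a BMR equal to the activity's own wattage gives a multiple of 1
        tab2 = activity_rates(fit, 1500.0, bmr_w=row.loc["col", "watts"])
        assert tab2.set_index("activity").loc["col", "x_bmr"] == pytest.approx(1.0)

    def test_watts_linear_in_mass(self):
        s = _summaries(n=15, seed=13)
        s["msDEE"] = 0.05 * 24.0
        fit = fit_dee_model(Design(name="T: all", kind="time",
                                   groups=(("col", "com", "for", "rest"),)), s)
        t1 = activity_rates(fit, 1000.0, 4.39)
        t2 = activity_rates(fit, 2000.0, 4.39)
        assert np.allclose(2 * t1["watts"], t2["watts"])

    def test_requires_time_design(self):
        s = _summaries(n=15, seed=14)
        fit = fit_dee_model(Design(name="null: total DBA", kind="dba_total"), s)
        with pytest.raises(ValueError, match="time-budget"):
            activity_rates(fit, 1500.0, 4.39)


class TestGroupDifference:
    def test_identical_groups_zero(self):
        v = np.tile([1.0, 2.0, 3.0], 2)
        g = ["a"] * 3 + ["b"] * 3
        assert group_difference(v, g)["estimate"] == pytest.approx(0.0)

    def test_pure_offset_detected(self):
        v = np.r_[np.full(6, 1.0), np.full(6, 1.5)]
        g = ["F"] * 6 + ["M"] * 6
        out = group_difference(v, g)
        assert out["estimate"] == pytest.approx(0.5)
        assert out["p"] < 1e-10

    def test_type_i_error_calibrated(self, rng):
        """Null rejections at alpha = 0.05 over 2000 replicates: 0.05 +/- 0.02."""
        rejections = 0
        n_rep = 2000
        g = ["a"] * 10 + ["b"] * 10
        for _ in range(n_rep):
            v = rng.normal(0, 1, 20)
            rejections += group_difference(v, g)["p"] < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_difference([1.0, 2.0, 3.0], ["a", "a", "a"])


class TestRecoveryExperiments:
    def test_generating_design_beats_refinements(self):
        """Parsimony: AICc keeps the generating partition against designs that
        split its groups (pure-noise parameters) in >= 70% of replicates."""
        sc = SimScenario(seed=0)
        gen = Design(name="T: col+rest | com+for", kind="time",
                     groups=(("col", "rest"), ("com", "for")))
        out = M.aicc_recovery_experiment(sc, gen, seed=17, n_reps=100)
        assert out["selection_fraction"] >= 0.70
        assert len(out["refinements"]) == 3

    def test_mr_recovery_within_15_percent(self):
        sc = SimScenario(seed=0)
        out = M.mr_recovery_experiment(sc, seed=23, n_reps=300)
        assert out["ratio_for_col"] == pytest.approx(out["true_ratio_for_col"],
                                                     rel=0.15)
        assert (out["coverage_2se"] >= 0.90).all()

    def test_predictive_r_exceeds_080(self):
        sc = SimScenario(seed=0)
        out = M.predictive_r_experiment(sc, seed=29, n_reps=15)
        assert out["median_r"] > 0.8
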