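"""Doubly-labelled-water energetics: hand oracles, invariants, round trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plungedee import dlw
from plungedee.dlw import (DlwConstants, IsotopePanel, dee_kj_per_day,
                           dilution_space, estimate_initial_enrichment,
                           final_dilution_space, fit_equilibrium_relation,
                           isotope_turnover, mass_specific_dee, process_cohort,
                           rco2_single_pool)
from plungedee.simulate import SimScenario, simulate_cohort, simulate_isotopes


class TestTurnover:
    def test_hand_oracle(self, example_panel):
        # ln(1850/350) / 47
        k = isotope_turnover(example_panel)
        assert k["d"] == pytest.approx(0.035426, rel=1e-4)
        assert k["d"] == pytest.approx(np.log(1850.0 / 350.0) / 47.0, rel=1e-12)

    def test_no_washout_gives_zero(self, example_panel):
        p = dataclasses.replace(example_panel, I_final_d=2000.0, I_final_o=2000.0)
        k = isotope_turnover(p)
        assert k["d"] == 0.0 and k["o"] == 0.0

    def test_inverse_in_effective_time(self, example_panel):
        doubled = dataclasses.replace(example_panel, t_total_h=95.0)  # T_eff 47 -> 94
        k1 = isotope_turnover(example_panel)
        k2 = isotope_turnover(doubled)
        assert k2["d"] == pytest.approx(k1["d"] / 2, rel=1e-12)

    def test_final_below_background_raises_with_isotope_named(self, example_panel):
        p = dataclasses.replace(example_panel, I_final_o=100.0)
        with pytest.raises(ValueError, match="'o'"):
            isotope_turnover(p)

    def test_offset_invariance_of_k_only(self, example_panel):
        """Enrichments enter k as ratios of differences: a constant ppm offset
        on one isotope leaves k unchanged but shifts its dilution space."""
        off = dataclasses.replace(example_panel, I_bg_d=150 + 37.0,
                                  I_init_d=2000 + 37.0, I_final_d=500 + 37.0)
        assert isotope_turnover(off)["d"] == pytest.approx(
            isotope_turnover(example_panel)["d"], rel=1e-12)
        assert dilution_space(off)["d"] != pytest.approx(
            dilution_space(example_panel)["d"], rel=1e-6)


class TestDilutionSpace:
    def test_hand_oracle(self, example_panel):
        # 0.05 * 88000 / 1850
        n = dilution_space(example_panel)
        assert n["d"] == pytest.approx(2.3784, rel=1e-4)

    def test_no_dilution(self, example_panel):
        p = dataclasses.replace(example_panel, I_inj_d=2000.0 + 1e-9)
        assert dilution_space(p)["d"] == pytest.approx(0.0, abs=1e-10)

    def test_scale_invariance(self, example_panel):
        """Scaling all enrichment differences by one factor leaves N fixed."""
        c = 3.7
        bg = example_panel.I_bg_d
        p = dataclasses.replace(
            example_panel,
            I_init_d=bg + c * (example_panel.I_init_d - bg),
            I_final_d=bg + c * (example_panel.I_final_d - bg),
            I_inj_d=bg + c * (example_panel.I_inj_d - bg))
        assert dilution_space(p)["d"] == pytest.approx(
            dilution_space(example_panel)["d"], rel=1e-12)


class TestFinalDilutionSpace:
    def test_percentage_mass_scaling(self):
        n_f, n = final_dilution_space(2.0, 1500.0, 1425.0)
        assert n_f == pytest.approx(1.9)
        assert n == pytest.approx(1.95)

    def test_mass_unchanged_is_identity(self):
        n_f, n = final_dilution_space(2.0, 1500.0, 1500.0)
        assert n_f == n == 2.0

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            final_dilution_space(2.0, 1500.0, 0.0)


class TestRco2:
    def test_hand_oracle(self):
        rco2, valid = rco2_single_pool(2.0, 0.040, 0.030)
        assert rco2 == pytest.approx(9.2526, rel=1e-4)
        assert valid

    def test_equal_turnovers_invalid(self):
        rco2, valid = rco2_single_pool(2.0, 0.030, 0.030)
        assert rco2 < 0 and not valid

    def test_linear_in_pool_size(self):
        r1, _ = rco2_single_pool(1.3, 0.040, 0.030)
        r2, _ = rco2_single_pool(2.6, 0.040, 0.030)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    @given(st.floats(0.031, 0.2), st.floats(0.031, 0.2))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_k_o(self, ko1, ko2):
        lo, hi = sorted((ko1, ko2))
        r_lo, _ = rco2_single_pool(2.0, lo, 0.030)
        r_hi, _ = rco2_single_pool(2.0, hi, 0.030)
        assert r_hi >= r_lo
        assert dee_kj_per_day(r_hi) >= dee_kj_per_day(r_lo)


class TestEnergyConversion:
    def test_hand_oracle(self):
        assert dee_kj_per_day(9.2526) == pytest.approx(135.80, rel=1e-4)

    def test_zero(self):
        assert dee_kj_per_day(0.0) == 0.0

    def test_linear_in_caloric_equivalent(self):
        base = dee_kj_per_day(5.0)
        doubled = dee_kj_per_day(5.0, DlwConstants(joule_per_ml_co2=2 * 27.3))
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            DlwConstants(ml_per_mmol=-1.0)

    def test_mass_specific(self):
        assert mass_specific_dee(135.80, 1400.0) == pytest.approx(0.09700, rel=1e-4)
        assert mass_specific_dee(0.0, 1400.0) == 0.0
        assert mass_specific_dee(135.80, 700.0) == pytest.approx(
            2 * mass_specific_dee(135.80, 1400.0))


class TestEquilibriumRelation:
    def _table(self, mass, enr_d, enr_o):
        return pd.DataFrame({"mass_g": mass, "I_init_d": enr_d, "I_init_o": enr_o})

    def test_exact_linear_recovery(self):
        mass = np.array([1200.0, 1350, 1500, 1650, 1800])
        tab = self._table(mass, 400 - 0.1 * mass, 2300 - 0.08 * mass)
        rel = fit_equilibrium_relation(tab)
        assert rel.slope["d"] == pytest.approx(-0.1, rel=1e-9)
        assert rel.intercept["o"] == pytest.approx(2300.0, rel=1e-9)
        assert abs(rel.pearson_r["d"]) == pytest.approx(1.0)
        assert rel.valid  # |r| > 0.7 gate

    def test_zero_mass_variance_rejected(self):
        tab = self._table([1500.0] * 4, [250] * 4, [2100] * 4)
        with pytest.raises(ValueError, match="singular"):
            fit_equilibrium_relation(tab)

    def test_null_noise_rarely_exceeds_gate(self, rng):
        """|r| under independence at n = 50 stays below 0.35 almost surely."""
        below = 0
        n_rep = 200
        for _ in range(n_rep):
            tab = self._table(rng.uniform(1200, 1800, 50),
                              rng.normal(250, 20, 50), rng.normal(2100, 20, 50))
            rel = fit_equilibrium_relation(tab)
            below += abs(rel.pearson_r["d"]) < 0.35
        assert below >= 190  # P(|r| < 0.35) ~ 0.987 per draw

    def test_prediction_interpolates_data(self):
        mass = np.array([1200.0, 1500, 1800])
        tab = self._table(mass, 400 - 0.1 * mass, 2300 - 0.08 * mass)
        rel = fit_equilibrium_relation(tab)
        pred = estimate_initial_enrichment(1500.0, rel)
        assert pred["d"] == pytest.approx(400 - 0.1 * 1500, rel=1e-9)

    def test_flat_relation_predicts_intercept(self):
        import warnings as _w
        tab = self._table([1200.0, 1500, 1800], [250.0] * 3, [2100.0] * 3)
        rel = fit_equilibrium_relation(tab)
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # extrapolation warnings irrelevant here
            for m in (900.0, 1500.0, 2500.0):
                assert estimate_initial_enrichment(m, rel)["d"] == pytest.approx(250.0)

    def test_extrapolation_warns(self):
        mass = np.array([1200.0, 1500, 1800])
        rel = fit_equilibrium_relation(self._table(mass, 400 - 0.1 * mass,
                                                   2300 - 0.08 * mass))
        with pytest.warns(UserWarning, match="extrapolating"):
            estimate_initial_enrichment(2500.0, rel)


class TestRoundTrip:
    def test_isotope_panel_inverts_exactly(self, clean_scenario, rng):
        """dlw(simulate_isotopes(DEE)) == DEE over random parameter draws."""
        for _ in range(100):
            mass = rng.uniform(1200, 1800)
            mass_f = mass * rng.uniform(0.97, 1.0)
            dee = rng.uniform(900, 2300)
            hours = rng.uniform(46, 61)
            row = simulate_isotopes(dee, mass, mass_f, hours, clean_scenario)
            panel = IsotopePanel(
                I_bg_d=row["I_bg_d"], I_bg_o=row["I_bg_o"],
                I_init_d=row["I_init_d"], I_init_o=row["I_init_o"],
                I_final_d=row["I_final_d"], I_final_o=row["I_final_o"],
                I_inj_d=row["I_inj_d"], I_inj_o=row["I_inj_o"],
                mol_inj=row["mol_inj"], t_total_h=hours)
            res = dlw.process_panel(panel, mass, mass_f)
            assert res.dee_kj_day == pytest.approx(dee, rel=1e-6)
            assert res.k_o > res.k_d > 0

    def test_washout_monotone_in_deployment_time(self, clean_scenario):
        a = simulate_isotopes(1500.0, 1500.0, 1500.0, 48.0, clean_scenario)
        b = simulate_isotopes(1500.0, 1500.0, 1500.0, 96.0, clean_scenario)
        assert b["I_final_d"] < a["I_final_d"]
        assert b["I_final_o"] < a["I_final_o"]

    def test_single_sample_cohort_recovers_truth(self, clean_scenario):
        """Full single-sample chain (equilibrium regression included)."""
        cohort = simulate_cohort(clean_scenario)
        res = process_cohort(cohort.dlw).set_index("bird")
        truth = cohort.truth.energetics.set_index("bird")
        for bird in truth.index:
            assert res.loc[bird, "msDEE"] == pytest.approx(
                truth.loc[bird, "msDEE"], rel=1e-6)

    def test_equilibrium_scatter_zero_gives_perfect_r(self, clean_scenario):
        cohort = simulate_cohort(clean_scenario)
        res = process_cohort(cohort.dlw)
        rel = res.attrs["equilibrium_relation"]
        assert abs(rel.pearson_r["d"]) == pytest.approx(1.0, abs=1e-9)
        assert abs(rel.pearson_r["o"]) == pytest.approx(1.0, abs=1e-9)


class TestPanelValidation:
    def test_ordering_enforced(self, example_panel):
        bad = dataclasses.replace(example_panel, I_init_d=100.0)  # below background
        with pytest.raises(ValueError):
            bad.validate()

    def test_time_ordering_enforced(self, example_panel):
        bad = dataclasses.replace(example_panel, t_total_h=0.5)
        with pytest.raises(ValueError):
            bad.validate()
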