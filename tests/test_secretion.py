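"""Kinetics estimators, sampling contracts, PCA, and sensitivity."""

import numpy as np
import pandas as pd
import pytest

from mecell import (
    activity_to_concentration,
    composition_vs_sensitivity,
    estimate_growth_rate,
    estimate_secretion_rate,
    molar_fractions,
    pca_fluxes,
    sample_overexpression,
    sample_solution_space,
    sensitivity,
    simulate_batch_timecourse,
)
from mecell.errors import ContractError, SolveError
from mecell.secretion import SampleSet, TimeCourse


class TestGrowthFit:
    def test_noiseless_exponential_recovered_exactly(self):
        tc = simulate_batch_timecourse(0.2, 0.0, 0.05, np.arange(6))
        fit = estimate_growth_rate(tc)
        assert fit.mu == pytest.approx(0.2, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(np.log(0.05))

    def test_constant_biomass_gives_zero_mu(self):
        tc = TimeCourse(np.arange(5), np.full(5, 0.3))
        assert estimate_growth_rate(tc).mu == pytest.approx(0.0)

    def test_noisy_recovery_within_five_percent(self):
        errs = []
        for seed in range(20):
            tc = simulate_batch_timecourse(0.3, 0.0, 0.05, np.linspace(0, 8, 12),
                                           noise_cv=0.01, seed=seed)
            errs.append(abs(estimate_growth_rate(tc).mu - 0.3) / 0.3)
        assert max(errs) < 0.05

    def test_window_must_cover_three_points(self):
        tc = TimeCourse(np.arange(5), np.exp(np.arange(5)))
        with pytest.raises(ContractError):
            estimate_growth_rate(tc, window=(0, 2))

    def test_non_positive_biomass_rejected(self):
        tc = TimeCourse(np.arange(4), np.array([0.1, 0.0, 0.2, 0.4]))
        with pytest.raises(ContractError):
            estimate_growth_rate(tc)


class TestSecretionRate:
    def test_constant_biomass_closed_form(self):
        # X = 1 g/L on [0, 10] h, C rising 0 -> 5: nu = 5/10
        t = np.linspace(0, 10, 11)
        tc = TimeCourse(t, np.ones_like(t), 0.5 * t)
        fit = estimate_secretion_rate(tc, tc)
        assert fit.nu == pytest.approx(0.5, abs=1e-12)

    def test_exponential_biomass_within_quadrature_error(self):
        t = np.linspace(0, 5, 50)
        tc = simulate_batch_timecourse(0.2, 0.5, 1.0, t)
        fit = estimate_secretion_rate(tc, tc)
        assert fit.nu == pytest.approx(0.5, rel=1e-3)

    def test_constant_product_gives_zero(self):
        t = np.linspace(0, 5, 10)
        tc = TimeCourse(t, np.exp(0.2 * t), np.full_like(t, 2.0))
        assert estimate_secretion_rate(tc, tc).nu == 0.0

    def test_zero_integral_rejected(self):
        t = np.arange(3.0)
        x = TimeCourse(t, np.array([1e-12, 0.0, 0.0]) + 1e-15,
                       np.array([0.0, 1.0, 2.0]))
        x.biomass = np.zeros(3)
        with pytest.raises(ContractError):
            estimate_secretion_rate(x, x)

    def test_misaligned_grids_rejected(self):
        a = TimeCourse(np.arange(4.0), np.ones(4), np.ones(4))
        b = TimeCourse(np.arange(4.0) + 0.5, np.ones(4), np.ones(4))
        with pytest.raises(ContractError):
            estimate_secretion_rate(a, b)


class TestActivityConversion:
    def test_direct_division(self):
        conv = activity_to_concentration(245000.0, (245.0, 245.0))
        assert conv["mg_per_mL"][0] == pytest.approx(1.0)

    def test_hand_division_at_low_end(self):
        conv = activity_to_concentration(1537.0, (153.7, 153.7))
        assert conv["mg_per_mL"][1] == pytest.approx(0.01)

    def test_specific_activity_range_orders_interval(self):
        conv = activity_to_concentration(10_000.0, (153.7, 245.0))
        lo, hi = conv["mg_per_mL"]
        assert lo < hi

    def test_molar_conversion_uses_molecular_weight(self, spec):
        protein = spec.gene(spec.ground_truth.reporter_gene).protein_sequence()
        conv = activity_to_concentration(1000.0, (153.7, 245.0),
                                         protein_sequence=protein)
        assert conv["molecular_weight"] > 0
        assert conv["mmol_per_L"][0] == pytest.approx(
            conv["mg_per_mL"][0] * 1e6 / conv["molecular_weight"])

    def test_zero_specific_activity_rejected(self):
        with pytest.raises(ContractError):
            activity_to_concentration(100.0, (0.0, 245.0))


@pytest.fixture(scope="module")
def near_optimal(model):
    return sample_solution_space(model, growth_frac=0.9, n=15, seed=5)


class TestSampling:
    def test_every_sample_meets_the_growth_constraint(self, near_optimal):
        mu_opt = near_optimal.condition["mu_opt"]
        growth = near_optimal.fluxes["biomass_dilution"]
        assert (growth >= 0.9 * mu_opt - 1e-9).all()
        assert (growth <= mu_opt + 1e-9).all()

    def test_same_seed_reproduces_the_sample_set(self, model, near_optimal):
        again = sample_solution_space(model, growth_frac=0.9, n=15, seed=5)
        pd.testing.assert_frame_equal(again.fluxes, near_optimal.fluxes)

    def test_secretion_spans_lie_inside_endpoint_solutions(self, model,
                                                           near_optimal):
        sec = near_optimal.fluxes["translocation_g_amy"]
        assert sec.between(-1e-9, sec.max() + 1e-9).all()

    def test_bad_growth_fraction_rejected(self, model):
        with pytest.raises(ContractError):
            sample_solution_space(model, growth_frac=1.5, n=2)


@pytest.fixture(scope="module")
def overexpression_pair(model, growth):
    mu_fix = round(0.9 * growth.mu_star, 3)
    lo = sample_overexpression(model, mu_fix, 0.001, 0.002, n=40, seed=21)
    hi = sample_overexpression(model, mu_fix, 0.010, 0.020, n=40, seed=22)
    return lo, hi


class TestOverexpression:
    def test_secretion_forced_within_range(self, overexpression_pair):
        lo, hi = overexpression_pair
        sec = lo.fluxes["translocation_g_amy"]
        assert sec.between(0.001 - 1e-9, 0.002 + 1e-9).all()
        sec = hi.fluxes["translocation_g_amy"]
        assert sec.between(0.010 - 1e-9, 0.020 + 1e-9).all()

    def test_same_seed_reproducible(self, model, growth, overexpression_pair):
        lo, _ = overexpression_pair
        mu_fix = round(0.9 * growth.mu_star, 3)
        again = sample_overexpression(model, mu_fix, 0.001, 0.002,
                                      n=40, seed=21)
        pd.testing.assert_frame_equal(again.fluxes, lo.fluxes)

    def test_reporter_amino_acids_rise_with_secretion(self, spec,
                                                      overexpression_pair):
        lo, hi = overexpression_pair
        for aa, rxn in spec.motifs["aa_synthesis"].items():
            slope = np.polyfit(
                pd.concat([lo.fluxes["translocation_g_amy"],
                           hi.fluxes["translocation_g_amy"]]),
                pd.concat([lo.fluxes[rxn], hi.fluxes[rxn]]), 1)[0]
            expected = spec.ground_truth.expected_sensitivity[aa]
            assert np.sign(slope) == np.sign(expected)

    def test_infeasible_secretion_reports_bracket(self, model, growth):
        mu_fix = round(0.9 * growth.mu_star, 3)
        with pytest.raises(SolveError, match="maximum feasible secretion"):
            sample_overexpression(model, mu_fix, 0.001, 1e6, n=100, seed=0)


class TestPCA:
    def test_two_separated_clusters_dominate_pc1(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.01, size=(20, 5))
        b = rng.normal(5.0, 0.01, size=(20, 5))
        fluxes = pd.DataFrame(np.vstack([a, b]),
                              columns=[f"r{i}" for i in range(5)])
        res = pca_fluxes(SampleSet(fluxes, {}, 0))
        assert res.variance_fractions[0] > 0.9
        # PC1 separates the clusters
        assert (res.scores.iloc[:20, 0] * res.scores.iloc[20:, 0].mean() > 0).mean() < 0.5

    def test_loadings_are_orthonormal(self, near_optimal, model):
        res = pca_fluxes(near_optimal, model)
        gram = res.loadings.T.values @ res.loadings.values
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_variance_fractions_bounded(self, near_optimal):
        res = pca_fluxes(near_optimal)
        assert (res.variance_fractions >= 0).all()
        assert res.variance_fractions.sum() <= 1 + 1e-9

    def test_reaction_reordering_leaves_results_unchanged(self, near_optimal):
        res = pca_fluxes(near_optimal)
        shuffled = SampleSet(
            near_optimal.fluxes[list(reversed(near_optimal.fluxes.columns))],
            near_optimal.condition, near_optimal.seed)
        res2 = pca_fluxes(shuffled)
        assert np.allclose(res.variance_fractions, res2.variance_fractions)
        common = res.loadings.index
        assert np.allclose(np.abs(res.loadings.loc[common]).values,
                           np.abs(res2.loadings.loc[common]).values, atol=1e-9)

    def test_constant_samples_rejected(self):
        fluxes = pd.DataFrame(np.ones((5, 4)),
                              columns=["a", "b", "c", "d"])
        with pytest.raises(ContractError):
            pca_fluxes(SampleSet(fluxes, {}, 0))


class TestSensitivity:
    def _set(self, values):
        return SampleSet(pd.DataFrame({"syn": values}), {}, 0)

    def test_direct_evaluation(self):
        res = sensitivity(self._set([1.0] * 5), self._set([2.0] * 5),
                          "syn", r_low=1.0, r_high=3.0)
        assert res.sensitivity == pytest.approx(0.5)

    def test_identical_distributions_give_zero_and_p_near_one(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(1.0, 0.1, 50)
        res = sensitivity(self._set(vals), self._set(vals), "syn", 1.0, 2.0)
        assert res.sensitivity == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_equal_rates_rejected(self):
        with pytest.raises(ContractError):
            sensitivity(self._set([1.0] * 3), self._set([2.0] * 3),
                        "syn", 1.0, 1.0)

    def test_outlier_trimming_removes_planted_spike(self):
        vals = np.concatenate([np.random.default_rng(2).normal(1, 0.01, 49),
                               [100.0]])
        res = sensitivity(self._set(vals), self._set(vals + 1), "syn",
                          0.0, 1.0)
        assert res.n_low == 49  # the spike is outside 1.96 SD


class TestCompositionRegression:
    def test_proportional_sensitivities_give_unit_r_squared(self):
        seq = "MAAAAGGWWC"
        frac = molar_fractions(seq)
        sens = {aa: 3.0 * frac[aa] for aa in "AGWC"}
        report = composition_vs_sensitivity(seq, sens)
        assert report["r_squared"] == pytest.approx(1.0)
        assert report["slope"] == pytest.approx(3.0)

    def test_molar_fractions_sum_to_one(self):
        frac = molar_fractions("MAGWCAGWCA")
        assert frac.sum() == pytest.approx(1.0)
        assert frac["A"] == pytest.approx(0.3)

    def test_planted_outlier_is_flagged_and_excluded(self):
        seq = "M" + "A" * 10 + "G" * 8 + "W" * 6 + "C" * 4 + "S" * 2
        frac = molar_fractions(seq)
        sens = {aa: 2.0 * frac[aa] for aa in "AGWCS"}
        sens["M"] = 5.0  # far off the line
        report = composition_vs_sensitivity(seq, sens)
        assert "M" in report["outliers"]
        assert report["without_outliers"]["r_squared"] == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ContractError):
            composition_vs_sensitivity("MAG", {"A": 1.0, "G": 2.0})
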