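"""Stress conventions: uncoupled uptake, sweeps, attribution, DE calls."""

import numpy as np
import pandas as pd
import pytest

from mecell import (
    attribute_amino_acid_demand,
    differential_expression_calls,
    extract_expression,
    normalize_profiles,
    score_de,
    simulate_folate_damage,
    simulate_uncoupled_uptake,
    sweep_stressor,
)
from mecell.errors import ContractError, SolveError
from mecell.stress import ExpressionProfile, StressSweep


ETOH_RATES = [0.0, 0.1, 0.3, 0.5]


@pytest.fixture(scope="module")
def ethanol_sweep(model):
    return sweep_stressor(model, "etoh_e", ETOH_RATES,
                          tracked_reactions=["AASYN_trp", "ADH", "ACET"])


@pytest.fixture(scope="module")
def decoupled_ethanol_sweep(decoupled):
    return sweep_stressor(decoupled, "etoh_e", ETOH_RATES,
                          tracked_reactions=["AASYN_trp"])


class TestUncoupledUptake:
    def test_zero_rate_reproduces_baseline(self, model, growth):
        res = simulate_uncoupled_uptake(model, "etoh_e", 0.0)
        assert res.mu_star == pytest.approx(growth.mu_star, abs=2e-6)

    def test_forced_influx_is_fully_degraded_and_exported(self, model):
        rate = 0.4
        res = simulate_uncoupled_uptake(model, "etoh_e", rate)
        sol = res.solution
        # steady state: dehydrogenase pair and acetate export all carry
        # exactly the influx (no other sink exists)
        assert sol["ADH"] == pytest.approx(rate, abs=1e-6)
        assert sol["ALD"] == pytest.approx(rate, abs=1e-6)
        assert sol["ACET"] == pytest.approx(rate, abs=1e-6)
        assert sol["EX_ace_e"] == pytest.approx(rate, abs=1e-6)

    def test_sodium_influx_forces_equal_coupled_export(self, model):
        rate = 1.5
        res = simulate_uncoupled_uptake(model, "na_c", rate)
        base = simulate_uncoupled_uptake(model, "na_c", 0.0)
        assert res.solution["NAEXP"] == pytest.approx(rate, abs=1e-6)
        # export is enzyme-coupled, so exporter translation rises
        assert res.solution["translation_g_na_exp"] > \
            base.solution["translation_g_na_exp"]

    def test_negative_rate_rejected(self, model):
        with pytest.raises(ContractError):
            simulate_uncoupled_uptake(model, "etoh_e", -1.0)

    def test_unexchanged_metabolite_rejected(self, model):
        with pytest.raises(ContractError):
            simulate_uncoupled_uptake(model, "prec_c", 0.1)


class TestSweeps:
    def test_tryptophan_synthesis_monotone_in_ethanol(self, ethanol_sweep):
        trp = ethanol_sweep.tracked["AASYN_trp"].to_numpy()
        assert (np.diff(trp) > 0).all()

    def test_decoupled_model_shows_no_tryptophan_response(
            self, decoupled_ethanol_sweep):
        trp = decoupled_ethanol_sweep.tracked["AASYN_trp"].to_numpy()
        assert np.allclose(trp, trp[0], atol=1e-6)

    def test_exporter_expression_rises_with_stress(self, ethanol_sweep):
        series = [p.table.loc["g_ace_exp", "translation"]
                  for p in ethanol_sweep.profiles]
        assert (np.diff(series) > 0).all()

    def test_amino_acid_synthesis_non_increasing_under_salt(self, model, spec):
        sweep = sweep_stressor(
            model, "na_c", [0.0, 1.0, 2.0],
            tracked_reactions=list(spec.motifs["aa_synthesis"].values()))
        totals = sweep.tracked.sum(axis=1).to_numpy()
        assert (np.diff(totals) < 0).all()

    def test_empty_rate_list_gives_empty_sweep(self, model):
        sweep = sweep_stressor(model, "etoh_e", [])
        assert sweep.rates == [] and sweep.profiles == []

    def test_unsorted_rates_rejected(self, model):
        with pytest.raises(ContractError):
            sweep_stressor(model, "etoh_e", [0.3, 0.1])


class TestFolateDamage:
    def test_zero_damage_is_baseline(self, model, growth):
        res = simulate_folate_damage(model, 0.0)
        assert res.mu_star == pytest.approx(growth.mu_star, abs=2e-6)

    def test_synthesis_rises_by_exactly_the_damage_rate(self, model):
        base = simulate_folate_damage(model, 0.0)
        hurt = simulate_folate_damage(model, 0.15)
        assert hurt.solution["FOLSYN"] - base.solution["FOLSYN"] == \
            pytest.approx(0.15, abs=1e-6)

    def test_branch_gene_expression_increases_with_damage(self, model):
        rates = [0.0, 0.1, 0.2]
        transl = [simulate_folate_damage(model, r).solution["translation_g_fol"]
                  for r in rates]
        assert transl[0] < transl[1] < transl[2]

    def test_unsustainable_damage_reports_bracket(self, model):
        with pytest.raises(SolveError, match="not sustainable"):
            simulate_folate_damage(model, 1e6)


class TestNormalization:
    def _sweep_of(self, series_by_rate):
        profiles = []
        for rate, val in series_by_rate.items():
            table = pd.DataFrame({"transcription": [val], "translation": [val]},
                                 index=["g1"])
            profiles.append(ExpressionProfile(f"r={rate}", rate, table))
        return StressSweep("x", list(series_by_rate), profiles,
                           pd.DataFrame(index=list(series_by_rate)),
                           pd.Series(dtype=float))

    def test_series_scaled_by_maximum(self):
        sweep = self._sweep_of({0.0: 2.0, 0.5: 4.0, 1.0: 8.0})
        normed = normalize_profiles(sweep)
        values = [p.table.loc["g1", "translation"] for p in normed.profiles]
        assert values == [0.25, 0.5, 1.0]

    def test_constant_series_maps_to_ones(self):
        sweep = self._sweep_of({0.0: 3.0, 1.0: 3.0})
        normed = normalize_profiles(sweep)
        assert all(p.table.loc["g1", "translation"] == 1.0
                   for p in normed.profiles)

    def test_all_zero_series_maps_to_zero(self):
        sweep = self._sweep_of({0.0: 0.0, 1.0: 0.0})
        normed = normalize_profiles(sweep)
        assert all(p.table.loc["g1", "translation"] == 0.0
                   for p in normed.profiles)


class TestAttribution:
    def test_fractions_sum_to_one(self, model, spec, growth):
        stressed = simulate_uncoupled_uptake(model, "etoh_e", 0.5)
        att = attribute_amino_acid_demand(model, spec, growth.solution,
                                          stressed.solution, "W")
        assert att.defined
        assert att.table["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_exporter_dominates_tryptophan_increment(self, model, spec,
                                                     growth):
        stressed = simulate_uncoupled_uptake(model, "etoh_e", 0.5)
        att = attribute_amino_acid_demand(model, spec, growth.solution,
                                          stressed.solution, "W")
        assert att.table["fraction"].idxmax() == \
            spec.motifs["acetate_exporter_gene"]
        assert att.table.loc["g_ace_exp", "fraction"] > 0.5

    def test_machinery_proteins_appear_as_rows(self, model, spec, growth):
        stressed = simulate_uncoupled_uptake(model, "etoh_e", 0.5)
        att = attribute_amino_acid_demand(model, spec, growth.solution,
                                          stressed.solution, "W")
        assert {"g_rnap", "g_rpsA", "g_aars"} <= set(att.table.index)

    def test_identical_solutions_are_undefined(self, model, spec, growth):
        att = attribute_amino_acid_demand(model, spec, growth.solution,
                                          growth.solution, "W")
        assert not att.defined


class TestDifferentialExpression:
    def _profile(self, values, condition="c", rate=0.0):
        table = pd.DataFrame({"transcription": values, "translation": values})
        return ExpressionProfile(condition, rate, table)

    def test_self_reference_scores_perfectly(self, model, growth):
        base = extract_expression(model, growth.solution)
        stressed = simulate_uncoupled_uptake(model, "na_c", 2.0)
        prof = extract_expression(model, stressed.solution)
        calls = differential_expression_calls(base, prof)
        reference = pd.DataFrame({"direction": calls["call"]})
        report = score_de(calls, reference)
        assert report["accuracy"] == 1.0
        for acc in report["accuracy_by_direction"].values():
            assert acc == 1.0

    def test_sodium_exporter_called_up_under_salt(self, model, growth):
        base = extract_expression(model, growth.solution)
        stressed = simulate_uncoupled_uptake(model, "na_c", 2.0)
        prof = extract_expression(model, stressed.solution)
        calls = differential_expression_calls(base, prof)
        assert calls.loc["g_na_exp", "call"] == "up"

    def test_half_agreeing_reference_scores_half(self):
        base = self._profile(pd.Series({"g1": 1.0, "g2": 1.0, "g3": 1.0,
                                        "g4": 1.0}))
        stress = self._profile(pd.Series({"g1": 2.0, "g2": 2.0, "g3": 0.5,
                                          "g4": 0.5}))
        calls = differential_expression_calls(base, stress)
        reference = pd.DataFrame({
            "direction": {"g1": "up", "g2": "down", "g3": "down", "g4": "up"}})
        report = score_de(calls, reference)
        assert report["accuracy"] == pytest.approx(0.5)

    def test_large_epsilon_silences_all_calls(self):
        base = self._profile(pd.Series({"g1": 1.0, "g2": 1.0}))
        stress = self._profile(pd.Series({"g1": 1.5, "g2": 0.7}))
        calls = differential_expression_calls(base, stress, epsilon=10.0)
        assert (calls["call"] == "unchanged").all()
        reference = pd.DataFrame({"direction": {"g1": "up", "g2": "down"}})
        report = score_de(calls, reference)
        # accuracy is evaluated over reference-changed genes only
        assert report["n_reference_changed"] == 2
        assert report["accuracy"] == 0.0

    def test_subsystem_breakdown_present(self):
        base = self._profile(pd.Series({"g1": 1.0, "g2": 1.0}))
        stress = self._profile(pd.Series({"g1": 2.0, "g2": 0.5}))
        calls = differential_expression_calls(base, stress)
        reference = pd.DataFrame({
            "direction": {"g1": "up", "g2": "down"},
            "subsystem": {"g1": "transport", "g2": "synthesis"}})
        report = score_de(calls, reference)
        assert report["accuracy_by_subsystem"] == {"transport": 1.0,
                                                   "synthesis": 1.0}
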