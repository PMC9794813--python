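"""ME-model assembly: coefficients, census, and structural invariants."""

import pytest

from mecell import (
    MuCoefficient,
    assemble_me_model,
    couple_enzyme,
    decouple_model,
    write_me_json,
)
from mecell.build import (
    build_complex_formation,
    build_transcription_reaction,
    build_translation_reaction,
    build_trna_charging,
    consumed_aa_counts,
)
from mecell.errors import BuildError, ContractError
from mecell.memodel import MEReaction
from mecell.organism import (
    EnzymeAssignment,
    Gene,
    ProteinComplex,
    TranscriptionUnit,
)


class TestMuCoefficient:
    def test_forms_reduce_to_affine(self):
        assert MuCoefficient.const(2.0).value(0.7) == 2.0
        assert MuCoefficient.linear(1.0, 3.0).value(0.5) == 2.5
        assert MuCoefficient.ratio(8.0, 1.0, 1000.0).value(0.2) == \
            pytest.approx((8.0 + 0.2) / 1000.0)

    def test_finite_at_mu_zero(self):
        assert MuCoefficient.ratio(8.0, 1.0, 1000.0).value(0.0) == 0.008

    def test_json_round_trip(self):
        c = MuCoefficient.linear(1.5, -2.5)
        assert MuCoefficient.from_json(c.to_json()) == c


class TestTranscription:
    def test_ntp_counts_follow_unit_sequence(self, spec, toy_tu):
        rxn = build_transcription_reaction(toy_tu, spec)
        assert rxn.stoichiometry["ntp_a_c"].constant == -1
        assert rxn.stoichiometry["ntp_c_c"].constant == -1
        assert rxn.stoichiometry["ntp_g_c"].constant == -1
        assert rxn.stoichiometry["ntp_u_c"].constant == -1

    def test_polymerase_consumption_vanishes_at_mu_zero(self, spec, toy_tu):
        rxn = build_transcription_reaction(toy_tu, spec)
        rnap = f"cplx_{spec.machinery_roles['rna_polymerase']}"
        assert rxn.stoichiometry[rnap].value(0.0) == 0.0
        assert rxn.stoichiometry[rnap].value(0.5) < 0

    def test_unknown_sigma_factor_is_a_build_error(self, spec):
        tu = TranscriptionUnit("tuX", ("g_glcT",), "ACGT", sigma_factor="sigZ")
        with pytest.raises(BuildError, match="sigma"):
            build_transcription_reaction(tu, spec)

    def test_census_transcription_and_degradation(self, spec, model):
        census = model.census()
        assert census["transcription"] == len(spec.transcription_units)
        n_mrna = sum(1 for s in model.species.values() if s.kind == "mrna")
        degradations = [r for r in model.reactions.values()
                        if r.id.startswith("mrna_degradation_")]
        assert len(degradations) == n_mrna


class TestTranslation:
    def test_charged_trna_consumption_matches_codons(self, spec, toy_gene):
        rxn = build_translation_reaction(toy_gene, spec)
        assert rxn.stoichiometry["charged_trna_met"].constant == -1
        assert rxn.stoichiometry["charged_trna_gly"].constant == -1
        assert rxn.stoichiometry["charged_trna_lys"].constant == -1
        # equal uncharged return
        for aa in ("met", "gly", "lys"):
            assert rxn.stoichiometry[f"generic_trna_{aa}"].constant == 1

    def test_methionine_excision_trims_product(self, spec):
        gene = Gene("gB", "ATGGGTAAATAA", cleaved_start_residue=True)
        rxn = build_translation_reaction(gene, spec)
        # excised Met returns to the free pool; product is two residues
        assert rxn.stoichiometry["aa_met_c"].constant == 1
        assert rxn.stoichiometry["protein_biomass"].constant == 2
        assert consumed_aa_counts(gene) == {"G": 1, "K": 1}

    def test_mrna_coefficient_increases_with_mu(self, spec, toy_gene):
        rxn = build_translation_reaction(toy_gene, spec)
        coeff = rxn.stoichiometry["mrna_gA"]
        assert abs(coeff.value(0.5)) > abs(coeff.value(0.1))
        assert coeff.value(0.0) < 0  # degradation loss persists at mu=0

    def test_census_translation_equals_protein_genes(self, spec, model):
        assert model.census()["translation"] == len(spec.protein_genes())


class TestChargingAndComplexes:
    def test_charging_exists_per_amino_acid(self, spec, model):
        assert model.census()["trna_charging"] == len(spec.trna_genes)

    def test_synthetase_coupling_zero_at_mu_zero_and_scales_with_keff(self, spec):
        rxn = build_trna_charging("A", spec)
        synth = f"cplx_{spec.machinery_roles['trna_synthetase:A']}"
        assert rxn.stoichiometry[synth].value(0.0) == 0.0
        base = rxn.stoichiometry[synth].value(0.4)
        doubled = dict(spec.global_rates)
        doubled["synthetase_keff"] *= 2
        fast = type(spec)(**{**spec.__dict__, "global_rates": doubled})
        rxn2 = build_trna_charging("A", fast)
        assert rxn2.stoichiometry[synth].value(0.4) == pytest.approx(base / 2)

    def test_dimer_consumes_two_subunits(self, spec):
        cplx = ProteinComplex("CPLX_dimer", {"g_glyc": 2})
        rxn = build_complex_formation(cplx, spec)
        assert rxn.stoichiometry["protein_g_glyc"].constant == -2
        assert rxn.stoichiometry["cplx_CPLX_dimer"].constant == 1

    def test_cofactor_modification_consumed(self, spec):
        rxn = build_complex_formation(spec.complex("CPLX_glyc"), spec)
        assert rxn.stoichiometry["fol_c"].constant == -1

    def test_census_complex_formation(self, spec, model):
        assert model.census()["complex_formation"] == len(spec.complexes)


class TestCoupling:
    def test_hand_evaluated_coupling_coefficient(self):
        rxn = MEReaction("R1", "metabolic")
        couple_enzyme(rxn, EnzymeAssignment("R1", "E", keff=234000.0))
        assert rxn.stoichiometry["cplx_E"].value(0.45) == \
            pytest.approx(-1.923e-6, rel=1e-3)
        assert rxn.stoichiometry["cplx_E"].value(0.0) == 0.0

    def test_coupling_refuses_exchange_and_demand(self):
        for rtype in ("exchange", "demand"):
            rxn = MEReaction("RX", rtype)
            with pytest.raises(ContractError):
                couple_enzyme(rxn, EnzymeAssignment("RX", "E", keff=1.0))

    def test_all_enzyme_couplings_vanish_at_mu_zero(self, model):
        for rxn in model.reactions.values():
            for sp in rxn.coupling_species:
                coeff = rxn.stoichiometry[sp]
                assert coeff.value(0.0) == 0.0
                assert coeff.value(0.5) <= coeff.value(0.1) <= 0.0

    def test_shared_complex_formation_covers_total_usage(self, model, growth):
        # complex production must cover sum(mu/keff_i * v_i) over clients
        sol = growth.solution
        mu = growth.mu_star
        for cplx in [s.id for s in model.species.values() if s.kind == "complex"]:
            produced = consumed = 0.0
            for rxn in model.reactions.values():
                coeff = rxn.stoichiometry.get(cplx)
                if coeff is None:
                    continue
                flow = coeff.value(mu) * sol[rxn.id]
                if flow > 0:
                    produced += flow
                else:
                    consumed -= flow
            assert produced >= consumed - 1e-6


class TestTranslocation:
    def test_reporter_only_active_after_translocation(self, spec, model):
        # the reporter complex forms from the extracellular species only
        formation = model.reactions["formation_CPLX_amy"]
        assert "protein_g_amy_ext" in formation.stoichiometry
        assert "protein_g_amy" not in formation.stoichiometry

    def test_translocation_flux_feeds_complex_formation(self, model, growth):
        sol = growth.solution
        assert sol["translocation_g_amy"] == pytest.approx(
            sol["formation_CPLX_amy"], abs=1e-8)

    def test_energy_cost_scales_with_length(self, spec):
        from mecell.build import add_translocation
        t = spec.translocation_for("g_amy")
        rxn = add_translocation(spec.gene("g_amy"), t, spec)
        length = sum(spec.gene("g_amy").codon_counts().values())
        per_res = spec.global_rates["atp_per_residue_translocation"]
        assert rxn.stoichiometry["atp_c"].constant == -per_res * length


class TestAssemblyAndDecoupling:
    def test_assembly_is_deterministic(self, spec, model, tmp_path):
        again = assemble_me_model(spec)
        write_me_json(model, tmp_path / "a.json")
        write_me_json(again, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == \
            (tmp_path / "b.json").read_bytes()

    def test_split_reversible_pairs_have_non_negative_bounds(self, model):
        fwd = {r[:-4] for r in model.reactions if r.endswith("_FWD")}
        assert fwd  # the salvage reactions are reversible
        for stem in fwd:
            for suffix in ("_FWD", "_REV"):
                rxn = model.reactions[stem + suffix]
                assert rxn.lower_bound.value(0.7) == 0.0
                assert rxn.upper_bound.value(0.7) > 0.0

    def test_decoupling_is_idempotent(self, model, decoupled):
        twice = decouple_model(decoupled)
        assert {rid: dict(rx.stoichiometry)
                for rid, rx in twice.reactions.items()} == \
               {rid: dict(rx.stoichiometry)
                for rid, rx in decoupled.reactions.items()}
        assert all(not r.coupling_species
                   for r in decoupled.reactions.values())

    def test_decoupling_relaxes_growth(self, growth, decoupled_growth):
        assert decoupled_growth.mu_star >= growth.mu_star - 1e-9

    def test_provenance_hash_recorded(self, spec, model):
        from mecell.organism import spec_hash
        assert model.spec_hash == spec_hash(spec)
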