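"""Assembly of a metabolism-and-expression model from an organism spec.

The builder expands the metabolic core with transcription, translation,
tRNA charging, complex formation and translocation reactions and
installs growth-rate-dependent coupling: every unit of catalyzed flux
consumes ``mu/keff`` of the catalyzing complex, every unit of
translation flux consumes ribosome capacity ``mu*L/k_ribo`` and mRNA
``(mu + k_deg)/kappa``, and a biomass-dilution objective forces the
macromolecular composition to be produced at the growth rate. Reversible
core reactions are split into non-negative forward/reverse members.
"""

from __future__ import annotations

import copy

from .errors import BuildError, ContractError
from .memodel import MEModel, MEReaction, MuCoefficient, Species
from .organism import (
    AA_NAMES,
    Gene,
    OrganismSpec,
    ProteinComplex,
    TranscriptionUnit,
    spec_hash,
    validate_spec,
)

KNOWN_SIGMA_FACTORS = ("sigA", "sigB")

_NT_SPECIES = {"A": "ntp_a_c", "C": "ntp_c_c", "G": "ntp_g_c", "T": "ntp_u_c"}
_NMP_SPECIES = {"A": "nmp_a_c", "C": "nmp_c_c", "G": "nmp_g_c", "T": "nmp_u_c"}


def _nt_counts(sequence: str) -> dict[str, int]:
    return {nt: sequence.count(nt) for nt in "ACGT" if sequence.count(nt)}


def mrna_species(gene_id: str) -> str:
    return f"mrna_{gene_id}"


def protein_species(gene_id: str, compartment: str = "cytosol") -> str:
    if compartment == "cytosol":
        return f"protein_{gene_id}"
    return f"protein_{gene_id}_{'mem' if compartment == 'membrane' else 'ext'}"


def trna_species(aa: str, charged: bool = False) -> str:
    prefix = "charged_trna" if charged else "generic_trna"
    return f"{prefix}_{AA_NAMES[aa]}"


def consumed_aa_counts(gene: Gene) -> dict[str, int]:
    """Net amino acids drawn from the free pools by one translation.

    Codon counts, minus the start methionine when it is excised and
    returned to the pool.
    """
    counts = dict(gene.codon_counts())
    if gene.cleaved_start_residue:
        counts["M"] = counts.get("M", 0) - 1
        if counts["M"] == 0:
            del counts["M"]
    return counts


# ---------------------------------------------------------------------------
# single-reaction builders


def build_transcription_reaction(
    tu: TranscriptionUnit, spec: OrganismSpec,
    known_sigma=KNOWN_SIGMA_FACTORS,
) -> MEReaction:
    """Transcription of one unit: NTPs in, one transcript per member gene.

    RNA polymerase is consumed at ``mu * L_nt / k_txn`` per unit flux;
    stable RNA (tRNA, rRNA) credits the RNA biomass component.
    """
    if tu.sigma_factor not in known_sigma:
        raise BuildError(f"{tu.id}: unknown sigma factor {tu.sigma_factor!r}")
    rnap = spec.machinery_roles.get("rna_polymerase")
    if rnap is None:
        raise BuildError("no RNA polymerase machinery role assigned")
    rates = spec.global_rates
    rxn = MEReaction(f"transcription_{tu.id}", "transcription",
                     subsystem="transcription", tu_id=tu.id)
    for nt, n in sorted(_nt_counts(tu.sequence).items()):
        rxn.add(_NT_SPECIES[nt], MuCoefficient.const(-n))
    rxn.add(f"cplx_{rnap}",
            MuCoefficient.linear(0.0, -len(tu.sequence)
                                 / rates["transcription_rate_per_nt"]),
            coupling=True)
    trna_aa = {gid: aa for aa, gid in spec.trna_genes.items()}
    rna_biomass = 0.0
    for gid in tu.gene_ids:
        gene = spec.gene(gid)
        if gene.product_kind == "protein":
            rxn.add(mrna_species(gid), MuCoefficient.const(1.0))
        else:
            if gene.product_kind == "tRNA" and gid in trna_aa:
                rxn.add(trna_species(trna_aa[gid]), MuCoefficient.const(1.0))
            else:
                rxn.add(f"rna_{gid}", MuCoefficient.const(1.0))
            rna_biomass += len(gene.nucleotide_sequence)
    if rna_biomass:
        rxn.add("rna_biomass", MuCoefficient.const(rna_biomass))
    return rxn


def build_mrna_degradation(gene: Gene, spec: OrganismSpec) -> MEReaction:
    """Demand reaction routing one degraded mRNA back to NMP monomers,
    consuming degradosome capacity."""
    deg = spec.machinery_roles.get("degradosome")
    if deg is None:
        raise BuildError("no degradosome machinery role assigned")
    rxn = MEReaction(f"mrna_degradation_{gene.id}", "demand",
                     subsystem="mRNA degradation", gene_id=gene.id)
    rxn.add(mrna_species(gene.id), MuCoefficient.const(-1.0))
    for nt, n in sorted(_nt_counts(gene.nucleotide_sequence).items()):
        rxn.add(_NMP_SPECIES[nt], MuCoefficient.const(n))
    rxn.add(f"cplx_{deg}",
            MuCoefficient.linear(0.0, -len(gene.nucleotide_sequence)
                                 / spec.global_rates["degradosome_rate_per_nt"]),
            coupling=True)
    return rxn


def build_translation_reaction(gene: Gene, spec: OrganismSpec) -> MEReaction:
    """Translation of one protein-coding gene.

    Consumes one charged tRNA per codon (returning the uncharged tRNA),
    ATP per residue, ribosome capacity ``mu*L/k_ribo`` and mRNA at
    ``(mu + k_deg)/kappa`` — the mRNA requirement grows with both the
    growth rate (dilution) and the degradation rate. Produces the
    translated protein plus its protein-biomass credit; start-Met
    excision returns the methionine to the free pool.
    """
    if gene.product_kind != "protein":
        raise BuildError(f"{gene.id} is not protein-coding")
    try:
        counts = gene.codon_counts()
    except Exception as exc:
        raise BuildError(f"{gene.id}: invalid coding sequence: {exc}") from exc
    rates = spec.global_rates
    ribo = spec.machinery_roles.get("ribosome")
    if ribo is None:
        raise BuildError("no ribosome machinery role assigned")
    length = sum(counts.values())
    rxn = MEReaction(f"translation_{gene.id}", "translation",
                     subsystem="translation", gene_id=gene.id)
    for aa, n in sorted(counts.items()):
        rxn.add(trna_species(aa, charged=True), MuCoefficient.const(-n))
        rxn.add(trna_species(aa, charged=False), MuCoefficient.const(n))
    atp = rates["atp_per_residue_translation"] * length
    rxn.add("atp_c", MuCoefficient.const(-atp))
    rxn.add("adp_c", MuCoefficient.const(atp))
    rxn.add(mrna_species(gene.id),
            -MuCoefficient.ratio(rates["mrna_degradation_rate"], 1.0,
                                 rates["mrna_translation_capacity"]))
    rxn.add(f"cplx_{ribo}",
            MuCoefficient.linear(0.0, -length
                                 / rates["translation_rate_per_residue"]),
            coupling=True)
    product_residues = length
    if gene.cleaved_start_residue:
        rxn.add("aa_met_c", MuCoefficient.const(1.0))
        product_residues -= 1
    rxn.add(protein_species(gene.id), MuCoefficient.const(1.0))
    rxn.add("protein_biomass", MuCoefficient.const(float(product_residues)))
    return rxn


def build_trna_charging(amino_acid: str, spec: OrganismSpec) -> MEReaction:
    """Charge the generic tRNA of one amino acid.

    The uncharged tRNA carries a dilution surcharge ``mu/k_dil`` per
    charging event, so the tRNA pool must be transcribed at a rate
    proportional to its usage; the synthetase complex is consumed at
    ``mu/keff``.
    """
    role = f"trna_synthetase:{amino_acid}"
    synth = spec.machinery_roles.get(role)
    if synth is None:
        raise BuildError(f"no synthetase machinery role for {amino_acid!r}")
    rates = spec.global_rates
    rxn = MEReaction(f"charging_{AA_NAMES[amino_acid]}", "trna_charging",
                     subsystem="tRNA charging")
    rxn.add(f"aa_{AA_NAMES[amino_acid]}_c", MuCoefficient.const(-1.0))
    rxn.add(trna_species(amino_acid),
            -MuCoefficient.linear(1.0, 1.0 / rates["trna_dilution_rate"]))
    atp = rates["atp_per_aa_charging"]
    rxn.add("atp_c", MuCoefficient.const(-atp))
    rxn.add("adp_c", MuCoefficient.const(atp))
    rxn.add(f"cplx_{synth}",
            MuCoefficient.linear(0.0, -1.0 / rates["synthetase_keff"]),
            coupling=True)
    rxn.add(trna_species(amino_acid, charged=True), MuCoefficient.const(1.0))
    return rxn


def build_complex_formation(cplx: ProteinComplex, spec: OrganismSpec) -> MEReaction:
    """Assemble one complex from processed subunits plus cofactors."""
    rxn = MEReaction(f"formation_{cplx.id}", "complex_formation",
                     subsystem="complex formation")
    for gid, n in sorted(cplx.subunit_stoichiometry.items()):
        try:
            gene = spec.gene(gid)
        except KeyError as exc:
            raise BuildError(f"{cplx.id}: missing subunit gene {gid!r}") from exc
        if gene.product_kind != "protein":
            raise BuildError(f"{cplx.id}: subunit {gid} is not protein-coding")
        tloc = spec.translocation_for(gid)
        compartment = tloc.destination if tloc else "cytosol"
        rxn.add(protein_species(gid, compartment), MuCoefficient.const(-float(n)))
    for cofactor, n in cplx.modifications:
        rxn.add(cofactor, MuCoefficient.const(-float(n)))
    rxn.add(f"cplx_{cplx.id}", MuCoefficient.const(1.0))
    return rxn


def add_translocation(gene: Gene, assignment, spec: OrganismSpec) -> MEReaction:
    """Export a translated protein to its destination compartment.

    Consumes translocase capacity at ``mu/keff`` and an ATP cost
    proportional to protein length.
    """
    if assignment.destination == "cytosol":
        raise ContractError(f"{gene.id}: translocation to cytosol is a no-op")
    if assignment.pathway == "none":
        raise BuildError(
            f"{gene.id}: non-cytosolic destination without a pathway")
    if not spec.translocase_complex:
        raise BuildError("spec declares no translocase complex")
    length = sum(gene.codon_counts().values())
    rates = spec.global_rates
    rxn = MEReaction(f"translocation_{gene.id}", "translocation",
                     subsystem=f"translocation ({assignment.pathway})",
                     gene_id=gene.id)
    rxn.add(protein_species(gene.id), MuCoefficient.const(-1.0))
    rxn.add(protein_species(gene.id, assignment.destination),
            MuCoefficient.const(1.0))
    atp = rates["atp_per_residue_translocation"] * length
    rxn.add("atp_c", MuCoefficient.const(-atp))
    rxn.add("adp_c", MuCoefficient.const(atp))
    rxn.add(f"cplx_{spec.translocase_complex}",
            MuCoefficient.linear(0.0, -1.0 / rates["translocase_keff"]),
            coupling=True)
    return rxn


def couple_enzyme(rxn: MEReaction, assignment) -> MEReaction:
    """Install ``mu/keff`` consumption of the catalyzing complex."""
    if rxn.rtype in ("exchange", "demand"):
        raise ContractError(
            f"{rxn.id}: exchange/demand reactions stay uncoupled")
    rxn.add(f"cplx_{assignment.complex_id}",
            MuCoefficient.linear(0.0, -1.0 / assignment.keff), coupling=True)
    return rxn


# ---------------------------------------------------------------------------
# whole-model assembly


def _core_to_me(rxn, spec: OrganismSpec) -> list[MEReaction]:
    rtype = "exchange" if rxn.is_exchange else "metabolic"
    if rxn.reversible and not rxn.is_exchange:
        fwd = MEReaction(f"{rxn.id}_FWD", rtype, subsystem=rxn.subsystem,
                         lower_bound=MuCoefficient.const(0.0),
                         upper_bound=MuCoefficient.const(max(rxn.upper_bound, 0.0)))
        rev = MEReaction(f"{rxn.id}_REV", rtype, subsystem=rxn.subsystem,
                         lower_bound=MuCoefficient.const(0.0),
                         upper_bound=MuCoefficient.const(max(-rxn.lower_bound, 0.0)))
        for mid, coeff in sorted(rxn.stoichiometry.items()):
            fwd.add(mid, MuCoefficient.const(coeff))
            rev.add(mid, MuCoefficient.const(-coeff))
        return [fwd, rev]
    out = MEReaction(rxn.id, rtype, subsystem=rxn.subsystem,
                     lower_bound=MuCoefficient.const(rxn.lower_bound),
                     upper_bound=MuCoefficient.const(rxn.upper_bound))
    for mid, coeff in sorted(rxn.stoichiometry.items()):
        out.add(mid, MuCoefficient.const(coeff))
    return [out]


def assemble_me_model(spec: OrganismSpec,
                      known_sigma=KNOWN_SIGMA_FACTORS) -> MEModel:
    """Build the full ME model from a validated organism spec.

    Pure function of the spec: assembling twice yields identical models,
    and the spec hash is recorded as provenance.
    """
    report = validate_spec(spec)
    if not report.ok:
        raise BuildError(f"spec does not validate:\n{report}")

    model = MEModel(id="me_model", spec_hash=spec_hash(spec),
                    motifs=dict(spec.motifs),
                    ground_truth={
                        "essential_genes": list(spec.ground_truth.essential_genes),
                        "reporter_gene": spec.ground_truth.reporter_gene,
                        "reporter_aa_counts": dict(spec.ground_truth.reporter_aa_counts),
                        "expected_sensitivity": dict(spec.ground_truth.expected_sensitivity),
                    })

    for m in spec.metabolites:
        model.add_species(Species(m.id, m.category, m.compartment, m.formula))

    aas = sorted(spec.trna_genes)
    for aa in aas:
        model.add_species(Species(trna_species(aa), "trna"))
        model.add_species(Species(trna_species(aa, charged=True), "charged_trna"))
    for g in spec.genes:
        if g.product_kind == "protein":
            model.add_species(Species(mrna_species(g.id), "mrna"))
            model.add_species(Species(protein_species(g.id), "protein"))
            tloc = spec.translocation_for(g.id)
            if tloc and tloc.destination != "cytosol":
                model.add_species(Species(
                    protein_species(g.id, tloc.destination),
                    "processed_protein", tloc.destination))
        elif g.product_kind == "rRNA":
            model.add_species(Species(f"rna_{g.id}", "rrna"))
    for c in spec.complexes:
        model.add_species(Species(f"cplx_{c.id}", "complex"))

    # metabolic core, with reversible splitting and enzyme coupling;
    # alternative isozyme assignments each get their own reaction copy so
    # the LP chooses among them
    for core in spec.core_reactions:
        assigns = spec.assignments_for(core.id)
        for rxn in _core_to_me(core, spec):
            if rxn.rtype != "metabolic" or not assigns:
                model.add_reaction(rxn)
            elif len(assigns) == 1:
                model.add_reaction(couple_enzyme(rxn, assigns[0]))
            else:
                for a in assigns:
                    alt = copy.deepcopy(rxn)
                    alt.id = f"{rxn.id}__{a.complex_id}"
                    model.add_reaction(couple_enzyme(alt, a))

    # expression layer
    for tu in spec.transcription_units:
        rxn = build_transcription_reaction(tu, spec, known_sigma)
        model.add_reaction(rxn)
        for gid in tu.gene_ids:
            model.transcription_index.setdefault(gid, []).append(rxn.id)
    for g in spec.genes:
        if g.product_kind == "protein":
            model.add_reaction(build_mrna_degradation(g, spec))
            t = build_translation_reaction(g, spec)
            model.add_reaction(t)
            model.translation_index[g.id] = t.id
    for aa in aas:
        model.add_reaction(build_trna_charging(aa, spec))
    # stable-RNA turnover: degradosome-coupled recycling of tRNA/rRNA to
    # NMPs; lets stable-RNA synthesis run above its dilution-forced floor
    deg = spec.machinery_roles["degradosome"]
    for gid, sp_id in sorted(
            [(spec.trna_genes[aa], trna_species(aa)) for aa in aas]
            + [(g.id, f"rna_{g.id}") for g in spec.genes
               if g.product_kind == "rRNA"]):
        gene = spec.gene(gid)
        turn = MEReaction(f"rna_turnover_{gid}", "demand",
                          subsystem="stable RNA turnover", gene_id=gid)
        turn.add(sp_id, MuCoefficient.const(-1.0))
        for nt, n in sorted(_nt_counts(gene.nucleotide_sequence).items()):
            turn.add(_NMP_SPECIES[nt], MuCoefficient.const(n))
        turn.add(f"cplx_{deg}",
                 MuCoefficient.linear(0.0, -len(gene.nucleotide_sequence)
                                      / spec.global_rates["degradosome_rate_per_nt"]),
                 coupling=True)
        model.add_reaction(turn)
    # surplus stable RNA beyond the accounted composition
    if "rna_biomass" in model.species:
        spill = MEReaction("demand_rna_biomass", "demand",
                           subsystem="biomass slack")
        spill.add("rna_biomass", MuCoefficient.const(-1.0))
        model.add_reaction(spill)
    for t in spec.translocations:
        if t.destination != "cytosol":
            model.add_reaction(add_translocation(spec.gene(t.gene_id), t, spec))
    for c in spec.complexes:
        model.add_reaction(build_complex_formation(c, spec))

    # secreted-enzyme accumulation: extracellular complexes wash out in
    # batch culture, so secretion may run above the catalytic requirement
    secreted_dest = {t.gene_id: t.destination for t in spec.translocations}
    for c in spec.complexes:
        if any(secreted_dest.get(gid) == "extracellular"
               for gid in c.subunit_stoichiometry):
            acc = MEReaction(f"demand_cplx_{c.id}", "demand",
                             subsystem="secreted enzyme accumulation")
            acc.add(f"cplx_{c.id}", MuCoefficient.const(-1.0))
            model.add_reaction(acc)

    # unmodeled-protein sink: lets slack protein fill the biomass quota
    if spec.unmodeled_protein_gene:
        sink = MEReaction(f"demand_protein_{spec.unmodeled_protein_gene}",
                          "demand", subsystem="unmodeled protein")
        sink.add(protein_species(spec.unmodeled_protein_gene),
                 MuCoefficient.const(-1.0))
        model.add_reaction(sink)

    # growth objective: biomass composition diluted at rate mu
    rates = spec.global_rates
    total = rates["biomass_total"]
    dilution = MEReaction("biomass_dilution", "biomass_dilution",
                          subsystem="biomass",
                          lower_bound=MuCoefficient.linear(0.0, 1.0),
                          upper_bound=MuCoefficient.linear(0.0, 1.0))
    for comp, fraction in sorted(spec.biomass_composition.items()):
        dilution.add(comp, MuCoefficient.const(-fraction * total))
    gam = rates.get("gam", 0.0)
    if gam:
        dilution.add("atp_c", MuCoefficient.const(-gam))
        dilution.add("adp_c", MuCoefficient.const(gam))
    model.add_reaction(dilution)
    model.objective = dilution.id
    return model


def decouple_model(model: MEModel) -> MEModel:
    """Strip all enzyme/machinery coupling, yielding an M-like variant.

    Expression reactions are retained but no longer consume the
    machinery that catalyzes them; decoupling is idempotent and can only
    relax the model (maximum growth never decreases).
    """
    out = model.copy()
    out.id = f"{model.id}_decoupled"
    for rxn in out.reactions.values():
        for sp in rxn.coupling_species:
            rxn.stoichiometry.pop(sp, None)
        rxn.coupling_species = set()
    return out
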