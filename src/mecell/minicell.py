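"""Seeded generator for an internally consistent mini-cell organism.

The mini cell is a deliberately small but complete organism description
used as synthetic ground-truth data: a single-substrate metabolic core
(glucose -> precursor -> amino acids, nucleotides, ATP), a full
expression layer (RNA polymerase, ribosome, a shared tRNA synthetase,
an RNA degradosome), and the condition motifs the downstream analyses
assume:

* a secreted reporter enzyme that hydrolyzes an extracellular polymer
  (starch analog) back to the carbon source, with a declared amino-acid
  composition;
* an alcohol-degradation path (ethanol -> acetaldehyde -> acetate) whose
  acetate exporter is tryptophan-rich, so detoxification demands
  tryptophan synthesis;
* sodium import/export, export coupled to an ATP-consuming pump;
* a chorismate/folate branch whose product is an enzyme cofactor;
* an ATP-fabricating futile cycle with deliberately sluggish enzymes;
* a redundant isozyme pair, and a co-transcribed never-translated gene
  that forces mRNA degradation whenever the carbon transporter is
  expressed.

Because every motif is wired by construction, the generator can record
solver-independent ground truth: the essential gene set, the reporter
composition, and the expected amino-acid secretion sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .organism import (
    AA_NAMES,
    CODONS,
    CoreReaction,
    EnzymeAssignment,
    Gene,
    GroundTruth,
    Metabolite,
    OrganismSpec,
    ProteinComplex,
    TranscriptionUnit,
    TranslocationAssignment,
    validate_spec,
)


@dataclass
class MiniCellConfig:
    """Study conditions of the mini cell; defaults are the fixture."""

    amino_acids: tuple[str, ...] = ("M", "A", "G", "W", "C")
    #: reporter (secreted amylase analog) body composition, start Met implicit
    reporter_aa_counts: dict[str, int] = field(
        default_factory=lambda: {"A": 8, "G": 4, "W": 2, "C": 0}
    )
    #: cysteine tail length of the unmodeled-protein (biomass slack) gene
    slack_protein_cys: int = 40
    enzyme_protein_length: int = 30     # residues, incl. start Met
    machinery_protein_length: int = 40
    exporter_trp_count: int = 12        # planted Trp in the acetate exporter
    regulatory_protein_length: int = 20
    trna_length_nt: int = 30
    rrna_length_nt: int = 60
    #: codon weights per amino acid; None -> uniform over the standard code
    codon_usage: Optional[dict[str, dict[str, float]]] = None

    # effective turnover rates, 1/h
    keff_primary: float = 234000.0      # 65 1/s
    keff_secondary: float = 3600.0      # 1 1/s
    keff_futile: float = 50.0           # sluggish by construction

    # medium
    glc_uptake: float = 5.0             # mmol/gDW/h
    starch_uptake: float = 2.0
    starch_glucose_units: int = 4

    # expression kinetics
    mrna_degradation_rate: float = 8.0          # 1/h (~5 min half-life)
    translation_rate_per_residue: float = 43200.0   # residues/h per ribosome
    transcription_rate_per_nt: float = 198000.0     # nt/h per polymerase
    mrna_translation_capacity: float = 1000.0       # translations/h per mRNA
    trna_dilution_rate: float = 50.0                # 1/h
    degradosome_rate_per_nt: float = 198000.0       # nt/h per degradosome
    synthetase_keff: float = 234000.0               # 1/h
    translocase_keff: float = 234000.0              # 1/h

    # energy costs
    atp_per_residue_translation: float = 4.0
    atp_per_aa_charging: float = 2.0
    atp_per_residue_translocation: float = 0.1
    gam: float = 20.0                   # growth-associated ATP, mmol/gDW
    sodium_export_atp: float = 2.0

    # core yields; respiration is the only stoichiometric ATP source
    glyc_prec_yield: float = 2.0
    glyc_atp_yield: float = 0.0
    resp_atp_yield: float = 10.0

    # biomass amounts, mmol-units per gDW
    biomass_protein: float = 5.0        # mmol residues
    biomass_rna: float = 0.3            # mmol stable-RNA nucleotides
    biomass_prec: float = 2.0

    #: extra non-essential filler genes (additional NTP-synthesis isozymes)
    n_extra_proteins: int = 0

    @property
    def gene_count(self) -> int:
        """Total genes the generator will emit for this configuration."""
        n_protein = 28 + self.n_extra_proteins
        return n_protein + 1 + len(self.amino_acids)  # + rRNA + tRNAs


def _check_config(config: MiniCellConfig) -> None:
    if not config.amino_acids:
        raise ConfigurationError("no amino acids configured but protein genes requested")
    if "M" not in config.amino_acids:
        raise ConfigurationError("the start residue M must be a modeled amino acid")
    for aa in config.amino_acids:
        if aa not in AA_NAMES:
            raise ConfigurationError(f"unknown amino acid code {aa!r}")
    for aa, n in config.reporter_aa_counts.items():
        if aa not in config.amino_acids:
            raise ConfigurationError(f"reporter uses unmodeled amino acid {aa!r}")
        if n < 0:
            raise ConfigurationError(f"negative reporter count for {aa!r}")
    if sum(config.reporter_aa_counts.values()) == 0:
        raise ConfigurationError("reporter protein has an empty body")
    for name in ("enzyme_protein_length", "machinery_protein_length",
                 "regulatory_protein_length", "trna_length_nt", "rrna_length_nt"):
        if getattr(config, name) <= 1:
            raise ConfigurationError(f"{name} must exceed 1")


def _reverse_translate(aa_seq: str, rng: np.random.Generator,
                       codon_usage: Optional[dict[str, dict[str, float]]]) -> str:
    codons = []
    for aa in aa_seq:
        if codon_usage and aa in codon_usage:
            table = codon_usage[aa]
            names = sorted(table)
            w = np.array([table[c] for c in names], dtype=float)
            codons.append(names[rng.choice(len(names), p=w / w.sum())])
        else:
            opts = CODONS[aa]
            codons.append(opts[rng.integers(len(opts))])
    codons.append("TAA")
    return "".join(codons)


def _protein_body(rng: np.random.Generator, n: int, alphabet: tuple[str, ...],
                  require_all: bool = False,
                  forced: Optional[dict[str, int]] = None) -> str:
    """Random protein body of n residues; optionally guarantee coverage."""
    body: list[str] = []
    if forced:
        for aa, k in sorted(forced.items()):
            body.extend([aa] * k)
    if require_all:
        body.extend(a for a in alphabet if a != "M")
    fill = n - len(body)
    if fill < 0:
        raise ConfigurationError("protein length too small for its forced residues")
    pool = [a for a in alphabet]
    body.extend(pool[i] for i in rng.integers(len(pool), size=fill))
    order = rng.permutation(len(body))
    return "".join(body[i] for i in order)


def generate_minicell(config: MiniCellConfig | None = None, seed: int = 0) -> OrganismSpec:
    """Build the seeded mini-cell organism spec.

    The same ``(config, seed)`` pair always yields a byte-identical
    serialized spec. The returned spec passes :func:`validate_spec`.
    """
    config = config or MiniCellConfig()
    _check_config(config)
    rng = np.random.default_rng(seed)
    aas = tuple(config.amino_acids)
    cu = config.codon_usage

    def protein_gene(gid: str, length: int, require_all: bool = False,
                     forced: Optional[dict[str, int]] = None,
                     cleaved: bool = False) -> Gene:
        body = _protein_body(rng, length - 1, aas, require_all, forced)
        return Gene(gid, _reverse_translate("M" + body, rng, cu),
                    "protein", cleaved)

    Lenz, Lmach = config.enzyme_protein_length, config.machinery_protein_length

    genes: list[Gene] = []
    # --- metabolic enzymes (machinery-supporting ones cover all residues,
    # so every amino-acid pathway is constructively required)
    genes.append(protein_gene("g_glcT", Lenz, require_all=True))
    genes.append(protein_gene("g_reg", config.regulatory_protein_length))
    genes.append(protein_gene("g_glyc", Lenz, require_all=True))
    genes.append(protein_gene("g_resp", Lenz))
    genes.append(protein_gene("g_ntsA", Lenz))
    genes.append(protein_gene("g_ntsB", Lenz))
    aa_syn_genes = {}
    for aa in aas:
        gid = f"g_{AA_NAMES[aa]}_syn"
        aa_syn_genes[aa] = gid
        genes.append(protein_gene(gid, Lenz, require_all=True))
    genes.append(protein_gene("g_cho", Lenz, require_all=True))
    genes.append(protein_gene("g_fol", Lenz, require_all=True))
    genes.append(protein_gene("g_adh", Lenz, cleaved=True))
    genes.append(protein_gene("g_ald", Lenz))
    genes.append(protein_gene(
        "g_ace_exp", max(Lenz, config.exporter_trp_count + 6),
        forced={"W": config.exporter_trp_count} if "W" in aas else None))
    genes.append(protein_gene("g_na_exp", Lenz))
    genes.append(protein_gene("g_mal_t", Lenz))
    reporter_body = {aa: n for aa, n in config.reporter_aa_counts.items() if n > 0}
    genes.append(protein_gene(
        "g_amy", 1 + sum(reporter_body.values()), forced=reporter_body))
    genes.append(protein_gene("g_sec", Lmach, require_all=True))
    genes.append(protein_gene("g_fc1", Lenz))
    genes.append(protein_gene("g_fc2", Lenz))
    # --- expression machinery
    genes.append(protein_gene("g_rnap", Lmach, require_all=True))
    genes.append(protein_gene("g_rpsA", Lmach, require_all=True))
    genes.append(protein_gene("g_rplB", Lmach, require_all=True))
    genes.append(protein_gene("g_rny", Lmach, require_all=True))
    genes.append(protein_gene("g_aars", Lmach, require_all=True))
    # --- unmodeled-protein slack (cysteine-rich by construction)
    slack_forced = {"C": config.slack_protein_cys} if "C" in aas else {
        aas[1]: config.slack_protein_cys}
    genes.append(Gene("g_dummy", _reverse_translate(
        "M" + "".join(aa * n for aa, n in sorted(slack_forced.items())), rng, cu)))
    extra_ids = []
    for i in range(config.n_extra_proteins):
        gid = f"g_nts_extra{i + 1}"
        extra_ids.append(gid)
        genes.append(protein_gene(gid, Lenz))
    # --- RNA genes
    def rna_seq(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(4, size=n))

    genes.append(Gene("g_rrna", rna_seq(config.rrna_length_nt), "rRNA"))
    trna_genes = {}
    for aa in aas:
        gid = f"g_trna_{AA_NAMES[aa]}"
        trna_genes[aa] = gid
        genes.append(Gene(gid, rna_seq(config.trna_length_nt), "tRNA"))

    # ------------------------------------------------------------------
    # metabolites
    C = lambda n: {"C": n}
    su = config.starch_glucose_units
    mets = [
        Metabolite("glc_e", "glucose", "extracellular", C(6)),
        Metabolite("glc_c", "glucose", "cytosol", C(6)),
        Metabolite("prec_c", "biosynthetic precursor", "cytosol"),
        Metabolite("atp_c", "ATP equivalent", "cytosol"),
        Metabolite("adp_c", "ADP equivalent", "cytosol"),
        Metabolite("co2_c", "CO2", "cytosol", C(1)),
        Metabolite("co2_e", "CO2", "extracellular", C(1)),
        Metabolite("cho_c", "chorismate analog", "cytosol"),
        Metabolite("fol_c", "folate analog", "cytosol"),
        Metabolite("starch_e", "starch analog", "extracellular", C(6 * su)),
        Metabolite("mal_e", "maltose analog", "extracellular", C(12)),
        Metabolite("xyl_e", "orphan pentose", "extracellular", C(5)),
        Metabolite("etoh_e", "ethanol", "extracellular", C(2)),
        Metabolite("etoh_c", "ethanol", "cytosol", C(2)),
        Metabolite("acd_c", "acetaldehyde", "cytosol", C(2)),
        Metabolite("ace_c", "acetate", "cytosol", C(2)),
        Metabolite("ace_e", "acetate", "extracellular", C(2)),
        Metabolite("na_c", "sodium", "cytosol"),
        Metabolite("na_e", "sodium", "extracellular"),
        Metabolite("cyca_c", "cycle carrier A", "cytosol"),
        Metabolite("cycb_c", "cycle carrier B", "cytosol"),
        Metabolite("protein_biomass", "protein biomass component", "cytosol",
                   None, "constraint_component"),
        Metabolite("rna_biomass", "RNA biomass component", "cytosol",
                   None, "constraint_component"),
    ]
    for aa in aas:
        mets.append(Metabolite(f"aa_{AA_NAMES[aa]}_c", f"amino acid {AA_NAMES[aa]}",
                               "cytosol"))
    for nt in "acgu":
        mets.append(Metabolite(f"ntp_{nt}_c", f"NTP {nt.upper()}", "cytosol"))
        mets.append(Metabolite(f"nmp_{nt}_c", f"NMP {nt.upper()}", "cytosol"))

    # ------------------------------------------------------------------
    # core reactions
    ry, ga, gp = config.resp_atp_yield, config.glyc_atp_yield, config.glyc_prec_yield
    rxns = [
        CoreReaction("EX_glc_e", {"glc_e": -1.0}, False, -config.glc_uptake, 0.0,
                     "exchange"),
        CoreReaction("EX_starch_e", {"starch_e": -1.0}, False,
                     -config.starch_uptake, 0.0, "exchange"),
        CoreReaction("EX_mal_e", {"mal_e": -1.0}, False, 0.0, 0.0, "exchange"),
        CoreReaction("EX_xyl_e", {"xyl_e": -1.0}, False, 0.0, 0.0, "exchange"),
        CoreReaction("EX_co2_e", {"co2_e": -1.0}, False, 0.0, 1000.0, "exchange"),
        CoreReaction("EX_ace_e", {"ace_e": -1.0}, False, 0.0, 1000.0, "exchange"),
        CoreReaction("EX_etoh_e", {"etoh_e": -1.0}, False, 0.0, 0.0, "exchange"),
        # artificial salt injection point: an exchange written directly on the
        # cytosolic pool, so a forced influx is uncoupled from any transporter
        CoreReaction("EX_na_c", {"na_c": -1.0}, False, 0.0, 0.0, "exchange"),
        CoreReaction("EX_na_e", {"na_e": -1.0}, False, 0.0, 1000.0, "exchange"),
        CoreReaction("GLCT", {"glc_e": -1.0, "glc_c": 1.0}, False, 0.0, 1000.0,
                     "transport", True),
        CoreReaction("MALT", {"mal_e": -1.0, "glc_c": 2.0}, False, 0.0, 1000.0,
                     "transport", True),
        CoreReaction("GLYC",
                     {"glc_c": -1.0, "prec_c": gp,
                      **({"adp_c": -ga, "atp_c": ga} if ga else {})},
                     False, 0.0, 1000.0, "glycolysis", True),
        CoreReaction("RESP", {"prec_c": -1.0, "adp_c": -ry, "atp_c": ry,
                              "co2_c": 1.0}, False, 0.0, 1000.0, "respiration", True),
        CoreReaction("CO2T", {"co2_c": -1.0, "co2_e": 1.0}, False, 0.0, 1000.0,
                     "transport"),
        CoreReaction("CHOSYN", {"prec_c": -1.0, "atp_c": -1.0, "adp_c": 1.0,
                                "cho_c": 1.0}, False, 0.0, 1000.0,
                     "aromatic precursor synthesis", True),
        CoreReaction("FOLSYN", {"cho_c": -1.0, "atp_c": -1.0, "adp_c": 1.0,
                                "fol_c": 1.0}, False, 0.0, 1000.0,
                     "folate synthesis", True),
        CoreReaction("ETOHT", {"etoh_e": -1.0, "etoh_c": 1.0}, False, 0.0, 1000.0,
                     "transport"),
        CoreReaction("ADH", {"etoh_c": -1.0, "acd_c": 1.0}, False, 0.0, 1000.0,
                     "ethanol degradation", True),
        CoreReaction("ALD", {"acd_c": -1.0, "ace_c": 1.0}, False, 0.0, 1000.0,
                     "ethanol degradation", True),
        CoreReaction("ACET", {"ace_c": -1.0, "ace_e": 1.0}, False, 0.0, 1000.0,
                     "transport", True),
        CoreReaction("NAEXP", {"na_c": -1.0, "atp_c": -config.sodium_export_atp,
                               "adp_c": config.sodium_export_atp, "na_e": 1.0},
                     False, 0.0, 1000.0, "ion transport", True),
        CoreReaction("AMYL", {"starch_e": -1.0, "glc_e": float(su)}, False, 0.0,
                     1000.0, "extracellular hydrolysis", True),
        CoreReaction("FC1", {"cyca_c": -1.0, "adp_c": -1.0, "cycb_c": 1.0,
                             "atp_c": 1.0}, False, 0.0, 1000.0, "futile cycle",
                     True),
        CoreReaction("FC2", {"cycb_c": -1.0, "cyca_c": 1.0}, False, 0.0, 1000.0,
                     "futile cycle", True),
        CoreReaction("ATPM", {"atp_c": -1.0, "adp_c": 1.0}, False, 0.0, 1000.0,
                     "maintenance"),
    ]
    aa_syn_rxns = {}
    for aa in aas:
        if aa == "W":
            stoich = {"cho_c": -1.0, "prec_c": -1.0, "atp_c": -1.0, "adp_c": 1.0,
                      f"aa_{AA_NAMES[aa]}_c": 1.0}
        else:
            stoich = {"prec_c": -1.0, "atp_c": -2.0, "adp_c": 2.0,
                      f"aa_{AA_NAMES[aa]}_c": 1.0}
        rid = f"AASYN_{AA_NAMES[aa]}"
        aa_syn_rxns[aa] = rid
        rxns.append(CoreReaction(rid, stoich, False, 0.0, 1000.0,
                                 "amino acid synthesis", True))
    for nt in "acgu":
        rxns.append(CoreReaction(
            f"NTSYN_{nt}", {"prec_c": -1.0, "atp_c": -2.0, "adp_c": 2.0,
                            f"ntp_{nt}_c": 1.0}, False, 0.0, 1000.0,
            "nucleotide synthesis", True))
        rxns.append(CoreReaction(
            f"NMPK_{nt}", {f"nmp_{nt}_c": -1.0, "atp_c": -1.0,
                           f"ntp_{nt}_c": 1.0, "adp_c": 1.0}, True,
            -1000.0, 1000.0, "nucleotide salvage"))

    # ------------------------------------------------------------------
    # complexes and enzyme assignments
    def monomer(cid: str, gid: str, mods=()) -> ProteinComplex:
        return ProteinComplex(cid, {gid: 1}, tuple(mods))

    cplxs = [
        monomer("CPLX_glcT", "g_glcT"),
        ProteinComplex("CPLX_glyc", {"g_glyc": 1}, (("fol_c", 1),)),
        monomer("CPLX_resp", "g_resp"),
        monomer("CPLX_ntsA", "g_ntsA"),
        monomer("CPLX_ntsB", "g_ntsB"),
        monomer("CPLX_cho", "g_cho"),
        monomer("CPLX_fol", "g_fol"),
        monomer("CPLX_adh", "g_adh"),
        monomer("CPLX_ald", "g_ald"),
        monomer("CPLX_ace_exp", "g_ace_exp"),
        monomer("CPLX_na_exp", "g_na_exp"),
        monomer("CPLX_mal_t", "g_mal_t"),
        monomer("CPLX_amy", "g_amy"),
        monomer("CPLX_sec", "g_sec"),
        monomer("CPLX_fc1", "g_fc1"),
        monomer("CPLX_fc2", "g_fc2"),
        ProteinComplex("CPLX_rnap", {"g_rnap": 2}),
        ProteinComplex("CPLX_ribo", {"g_rpsA": 1, "g_rplB": 1},
                       (("rna_g_rrna", 1),)),
        monomer("CPLX_deg", "g_rny"),
        monomer("CPLX_aars", "g_aars"),
    ]
    for aa in aas:
        cplxs.append(monomer(f"CPLX_{AA_NAMES[aa]}_syn", aa_syn_genes[aa]))
    for gid in extra_ids:
        cplxs.append(monomer(f"CPLX_{gid[2:]}", gid))

    kp, ks, kf = config.keff_primary, config.keff_secondary, config.keff_futile
    assigns = [
        EnzymeAssignment("GLCT", "CPLX_glcT", kp),
        EnzymeAssignment("MALT", "CPLX_mal_t", kp),
        EnzymeAssignment("GLYC", "CPLX_glyc", kp),
        EnzymeAssignment("RESP", "CPLX_resp", kp),
        EnzymeAssignment("CHOSYN", "CPLX_cho", ks, "secondary"),
        EnzymeAssignment("FOLSYN", "CPLX_fol", ks, "secondary"),
        EnzymeAssignment("ADH", "CPLX_adh", ks, "secondary"),
        EnzymeAssignment("ALD", "CPLX_ald", ks, "secondary"),
        EnzymeAssignment("ACET", "CPLX_ace_exp", ks, "secondary"),
        EnzymeAssignment("NAEXP", "CPLX_na_exp", ks, "secondary"),
        EnzymeAssignment("AMYL", "CPLX_amy", kp),
        EnzymeAssignment("FC1", "CPLX_fc1", kf, "secondary"),
        EnzymeAssignment("FC2", "CPLX_fc2", kf, "secondary"),
    ]
    for aa in aas:
        assigns.append(EnzymeAssignment(aa_syn_rxns[aa],
                                        f"CPLX_{AA_NAMES[aa]}_syn", ks, "secondary"))
    for nt in "acgu":
        assigns.append(EnzymeAssignment(f"NTSYN_{nt}", "CPLX_ntsA", kp))
        assigns.append(EnzymeAssignment(f"NTSYN_{nt}", "CPLX_ntsB", kp))
        for gid in extra_ids:
            assigns.append(EnzymeAssignment(f"NTSYN_{nt}", f"CPLX_{gid[2:]}", kp))

    translocations = [
        TranslocationAssignment("g_glcT", "srp", "membrane"),
        TranslocationAssignment("g_mal_t", "srp", "membrane"),
        TranslocationAssignment("g_ace_exp", "sec_srp", "membrane"),
        TranslocationAssignment("g_na_exp", "tat", "membrane"),
        TranslocationAssignment("g_amy", "sec_srp", "extracellular"),
    ]

    # ------------------------------------------------------------------
    # transcription units (operons first, then monocistronic units)
    gene_by_id = {g.id: g for g in genes}

    def tu(tid: str, gids: list[str]) -> TranscriptionUnit:
        return TranscriptionUnit(
            tid, tuple(gids),
            "".join(gene_by_id[g].nucleotide_sequence for g in gids))

    tus = [tu("TU_glcT_operon", ["g_glcT", "g_reg"]),
           tu("TU_etoh_operon", ["g_adh", "g_ald"])]
    in_operon = {"g_glcT", "g_reg", "g_adh", "g_ald"}
    for g in genes:
        if g.id in in_operon:
            continue
        tus.append(tu(f"TU_{g.id[2:]}", [g.id]))

    machinery_roles = {
        "rna_polymerase": "CPLX_rnap",
        "ribosome": "CPLX_ribo",
        "degradosome": "CPLX_deg",
    }
    for aa in aas:
        machinery_roles[f"trna_synthetase:{aa}"] = "CPLX_aars"

    total = config.biomass_protein + config.biomass_rna + config.biomass_prec
    biomass = {
        "protein_biomass": config.biomass_protein / total,
        "rna_biomass": config.biomass_rna / total,
        "prec_c": config.biomass_prec / total,
    }
    global_rates = {
        "mrna_degradation_rate": config.mrna_degradation_rate,
        "translation_rate_per_residue": config.translation_rate_per_residue,
        "transcription_rate_per_nt": config.transcription_rate_per_nt,
        "mrna_translation_capacity": config.mrna_translation_capacity,
        "trna_dilution_rate": config.trna_dilution_rate,
        "degradosome_rate_per_nt": config.degradosome_rate_per_nt,
        "synthetase_keff": config.synthetase_keff,
        "translocase_keff": config.translocase_keff,
        "atp_per_residue_translation": config.atp_per_residue_translation,
        "atp_per_aa_charging": config.atp_per_aa_charging,
        "atp_per_residue_translocation": config.atp_per_residue_translocation,
        "gam": config.gam,
        "biomass_total": total,
    }

    # sole-path carbon uptake and biosynthesis, translocase, and every
    # expression-machinery subunit; the biomass slack gene itself is not
    # essential (overexpressing any enzyme with a flux outlet can fill
    # the protein quota instead)
    # sole-path carbon uptake and biosynthesis, translocase, and every
    # expression-machinery subunit; ATP-only genes are excluded because
    # the diagnostic futile cycle can fabricate ATP at low growth, and
    # the biomass slack gene is replaceable by any enzyme with an outlet
    essential = (
        "g_glcT", "g_glyc", "g_cho", "g_fol", "g_sec",
        *(aa_syn_genes[aa] for aa in aas),
        "g_rnap", "g_rpsA", "g_rplB", "g_rny", "g_aars",
    )

    # planted secretion sensitivities: reporter translation rises 1:1 with
    # secretion while slack protein is displaced mass-for-mass
    rep_counts = dict(config.reporter_aa_counts)
    rep_counts["M"] = rep_counts.get("M", 0) + 1
    w_rep = sum(rep_counts.values())
    slack_counts = dict(slack_forced)
    slack_counts["M"] = slack_counts.get("M", 0) + 1
    w_slack = sum(slack_counts.values())
    expected_sensitivity = {
        aa: rep_counts.get(aa, 0) - (w_rep / w_slack) * slack_counts.get(aa, 0)
        for aa in aas
    }

    spec = OrganismSpec(
        metabolites=mets, core_reactions=rxns, genes=genes,
        transcription_units=tus, complexes=cplxs,
        enzyme_assignments=assigns, translocations=translocations,
        machinery_roles=machinery_roles, biomass_composition=biomass,
        global_rates=global_rates, trna_genes=trna_genes,
        unmodeled_protein_gene="g_dummy", translocase_complex="CPLX_sec",
        ground_truth=GroundTruth(
            essential_genes=essential, reporter_gene="g_amy",
            reporter_aa_counts=rep_counts,
            expected_sensitivity=expected_sensitivity,
        ),
        motifs={
            "glucose_exchange": "EX_glc_e",
            "starch_exchange": "EX_starch_e",
            "carbon_exchanges": ["EX_glc_e", "EX_starch_e", "EX_mal_e",
                                 "EX_xyl_e", "EX_etoh_e"],
            "carbon_substrates": {"glc_e": "EX_glc_e", "mal_e": "EX_mal_e",
                                  "xyl_e": "EX_xyl_e"},
            "ethanol_exchange": "EX_etoh_e",
            "sodium_exchange": "EX_na_c",
            "sodium_exporter_gene": "g_na_exp",
            "folate_species": "fol_c",
            "folate_synthesis": "FOLSYN",
            "chorismate_branch_gene": "g_fol",
            "trp_synthesis": "AASYN_trp" if "W" in aas else "",
            "aa_synthesis": {aa: aa_syn_rxns[aa] for aa in aas},
            "ethanol_path": ["ADH", "ALD", "ACET"],
            "acetate_exporter_gene": "g_ace_exp",
            "futile_cycle": ["FC1", "FC2"],
            "isozyme_pair": ["g_ntsA", "g_ntsB"],
            "isozyme_reaction": "NTSYN_a",
            "reporter_gene": "g_amy",
            "reporter_reaction": "AMYL",
            "secretion_reaction": "translocation_g_amy",
            "never_translated_gene": "g_reg",
        },
    )
    report = validate_spec(spec)
    if not report.ok:  # pragma: no cover - generator self-check
        raise ConfigurationError(f"generated spec is inconsistent:\n{report}")
    return spec
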