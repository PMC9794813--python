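"""Declarative organism descriptions and their validation.

An :class:`OrganismSpec` is a complete, self-contained description of a
(mini) organism: metabolites and core reactions, genes with nucleotide
sequences, transcription units, protein complexes, enzyme->reaction
assignments with effective turnover rates, and translocation assignments.
It is the single input from which a metabolism-and-expression (ME) model
is assembled.

Specs serialize to a directory of delimited text tables (one per record
type) plus one structured JSON file for the nested parts; the round trip
is lossless and byte-stable, which makes spec generation testable for
determinism and gives models a provenance hash.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio.Seq import Seq

COMPARTMENTS = ("cytosol", "membrane", "extracellular")
PRODUCT_KINDS = ("protein", "rRNA", "tRNA")
PATHWAYS = ("sec_srp", "srp", "tat", "none")
TIERS = ("primary", "secondary")

#: three-letter tags used in species ids, keyed by one-letter amino acid code
AA_NAMES = {
    "A": "ala", "C": "cys", "D": "asp", "E": "glu", "F": "phe",
    "G": "gly", "H": "his", "I": "ile", "K": "lys", "L": "leu",
    "M": "met", "N": "asn", "P": "pro", "Q": "gln", "R": "arg",
    "S": "ser", "T": "thr", "V": "val", "W": "trp", "Y": "tyr",
}

#: DNA codons per amino acid (bacterial/standard code), used for
#: reverse translation; forward translation goes through Biopython.
CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str
    formula: Optional[dict[str, int]] = None
    category: str = "metabolite"  # or "constraint_component"


@dataclass(frozen=True)
class CoreReaction:
    id: str
    stoichiometry: dict[str, float]
    reversible: bool
    lower_bound: float
    upper_bound: float
    subsystem: str = ""
    enzymatic: bool = False

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1


@dataclass(frozen=True)
class Gene:
    id: str
    nucleotide_sequence: str
    product_kind: str = "protein"
    cleaved_start_residue: bool = False

    def protein_sequence(self) -> str:
        """Translated amino-acid sequence (stop removed, excision applied)."""
        if self.product_kind != "protein":
            raise ValueError(f"{self.id} is not protein-coding")
        prot = str(Seq(self.nucleotide_sequence).translate(table=11))
        if not prot.endswith("*"):
            raise ValueError(f"{self.id}: sequence does not end with a stop codon")
        prot = prot[:-1]
        if self.cleaved_start_residue:
            prot = prot[1:]
        return prot

    def codon_counts(self) -> dict[str, int]:
        """Amino acids consumed during translation (start Met included)."""
        prot = str(Seq(self.nucleotide_sequence).translate(table=11))[:-1]
        counts: dict[str, int] = {}
        for aa in prot:
            counts[aa] = counts.get(aa, 0) + 1
        return counts


@dataclass(frozen=True)
class TranscriptionUnit:
    id: str
    gene_ids: tuple[str, ...]
    sequence: str
    sigma_factor: str = "sigA"


@dataclass(frozen=True)
class ProteinComplex:
    id: str
    subunit_stoichiometry: dict[str, int]
    modifications: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class EnzymeAssignment:
    reaction_id: str
    complex_id: str
    keff: float
    tier: str = "primary"


@dataclass(frozen=True)
class TranslocationAssignment:
    gene_id: str
    pathway: str
    destination: str


@dataclass
class GroundTruth:
    """Constructive ground truth recorded by the generator.

    Independent of any solver: essentiality follows from single-path
    topology and machinery completeness, sensitivities from the planted
    reporter / slack-protein compositions.
    """

    essential_genes: tuple[str, ...] = ()
    reporter_gene: str = ""
    reporter_aa_counts: dict[str, int] = field(default_factory=dict)
    expected_sensitivity: dict[str, float] = field(default_factory=dict)


@dataclass
class OrganismSpec:
    metabolites: list[Metabolite]
    core_reactions: list[CoreReaction]
    genes: list[Gene]
    transcription_units: list[TranscriptionUnit]
    complexes: list[ProteinComplex]
    enzyme_assignments: list[EnzymeAssignment]
    translocations: list[TranslocationAssignment]
    machinery_roles: dict[str, str]
    biomass_composition: dict[str, float]
    global_rates: dict[str, float]
    trna_genes: dict[str, str] = field(default_factory=dict)
    unmodeled_protein_gene: str = ""
    translocase_complex: str = ""
    ground_truth: GroundTruth = field(default_factory=GroundTruth)
    motifs: dict[str, object] = field(default_factory=dict)

    # -- lookups -------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return self._met_index()[mid]

    def gene(self, gid: str) -> Gene:
        return {g.id: g for g in self.genes}[gid]

    def complex(self, cid: str) -> ProteinComplex:
        return {c.id: c for c in self.complexes}[cid]

    def _met_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def protein_genes(self) -> list[Gene]:
        return [g for g in self.genes if g.product_kind == "protein"]

    def translocation_for(self, gene_id: str) -> Optional[TranslocationAssignment]:
        for t in self.translocations:
            if t.gene_id == gene_id:
                return t
        return None

    def assignments_for(self, reaction_id: str) -> list[EnzymeAssignment]:
        return [a for a in self.enzyme_assignments if a.reaction_id == reaction_id]


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Finding:
    code: str
    subject: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, code: str, subject: str, message: str) -> None:
        self.findings.append(Finding(code, subject, message))

    def __str__(self) -> str:  # pragma: no cover - debug aid
        if self.ok:
            return "spec valid"
        return "\n".join(f"[{f.code}] {f.subject}: {f.message}" for f in self.findings)


def _check_cds(gene: Gene, report: ValidationReport) -> None:
    seq = gene.nucleotide_sequence
    if set(seq) - set("ACGT"):
        report.add("bad_alphabet", gene.id, "sequence contains non-ACGT characters")
        return
    if len(seq) % 3 != 0:
        report.add("bad_cds_length", gene.id, "length not divisible by 3")
        return
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons[0] != "ATG":
        report.add("missing_start", gene.id, "does not begin with ATG")
    if codons[-1] not in STOP_CODONS:
        report.add("missing_stop", gene.id, "does not end with a stop codon")
    if any(c in STOP_CODONS for c in codons[:-1]):
        report.add("internal_stop", gene.id, "internal stop codon")


def validate_spec(spec: OrganismSpec) -> ValidationReport:
    """Check every structural invariant; returns a report, never raises.

    The report is empty exactly when the spec is internally consistent:
    no dangling references, sequences are valid coding sequences, the
    element balance holds wherever formulas are complete, all machinery
    roles are assigned and the biomass composition sums to one.
    """
    rep = ValidationReport()
    met_ids = [m.id for m in spec.metabolites]
    if len(set(met_ids)) != len(met_ids):
        dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
        rep.add("duplicate_metabolite", ",".join(dupes), "metabolite ids not unique")
    mets = spec._met_index()
    for m in spec.metabolites:
        if m.compartment not in COMPARTMENTS:
            rep.add("bad_compartment", m.id, f"unknown compartment {m.compartment!r}")

    gene_ids = {g.id for g in spec.genes}
    rxn_ids = {r.id for r in spec.core_reactions}
    cplx_ids = {c.id for c in spec.complexes}
    rna_species = {
        f"rna_{g.id}" for g in spec.genes if g.product_kind in ("rRNA", "tRNA")
    }

    for r in spec.core_reactions:
        for mid in r.stoichiometry:
            if mid not in mets:
                rep.add("dangling_metabolite", r.id, f"unknown metabolite {mid!r}")
        if r.lower_bound > r.upper_bound:
            rep.add("bad_bounds", r.id, "lower bound above upper bound")
        if not r.is_exchange:
            participants = [mets.get(m) for m in r.stoichiometry]
            if all(p is not None and p.formula is not None for p in participants):
                balance: dict[str, float] = {}
                for mid, coeff in r.stoichiometry.items():
                    for el, n in mets[mid].formula.items():
                        balance[el] = balance.get(el, 0.0) + coeff * n
                for el, tot in balance.items():
                    if abs(tot) > 1e-9:
                        rep.add("mass_imbalance", r.id,
                                f"element {el} off by {tot:+g}")

    for g in spec.genes:
        if g.product_kind not in PRODUCT_KINDS:
            rep.add("bad_product_kind", g.id, f"unknown kind {g.product_kind!r}")
        elif g.product_kind == "protein":
            _check_cds(g, rep)

    for tu in spec.transcription_units:
        if not tu.gene_ids:
            rep.add("empty_tu", tu.id, "transcription unit has no genes")
        for gid in tu.gene_ids:
            if gid not in gene_ids:
                rep.add("dangling_gene", tu.id, f"unknown gene {gid!r}")
            elif spec.gene(gid).nucleotide_sequence not in tu.sequence:
                rep.add("gene_not_in_tu", tu.id,
                        f"gene {gid} sequence is not a substring of the unit")

    genes_by_id = {g.id: g for g in spec.genes}
    for c in spec.complexes:
        for gid, n in c.subunit_stoichiometry.items():
            if gid not in gene_ids:
                rep.add("dangling_subunit", c.id, f"unknown gene {gid!r}")
            elif genes_by_id[gid].product_kind != "protein":
                rep.add("nonprotein_subunit", c.id, f"{gid} is not protein-coding")
            if n < 1:
                rep.add("bad_stoichiometry", c.id, f"subunit count {n} < 1")
        for cofactor, _ in c.modifications:
            if cofactor not in mets and cofactor not in rna_species:
                rep.add("dangling_cofactor", c.id, f"unknown cofactor {cofactor!r}")

    for a in spec.enzyme_assignments:
        if a.reaction_id not in rxn_ids:
            rep.add("dangling_reaction", f"{a.complex_id}->{a.reaction_id}",
                    "assignment references a missing reaction")
        if a.complex_id not in cplx_ids:
            rep.add("dangling_complex", f"{a.complex_id}->{a.reaction_id}",
                    "assignment references a missing complex")
        if not a.keff > 0:
            rep.add("bad_keff", a.reaction_id, f"keff {a.keff} not positive")

    assigned = {a.reaction_id for a in spec.enzyme_assignments}
    for r in spec.core_reactions:
        if r.enzymatic and r.id not in assigned:
            rep.add("unassigned_enzymatic", r.id,
                    "enzymatic reaction without an enzyme assignment")

    for t in spec.translocations:
        if t.gene_id not in gene_ids:
            rep.add("dangling_gene", t.gene_id, "translocation of unknown gene")
        if t.destination not in COMPARTMENTS:
            rep.add("bad_destination", t.gene_id, f"unknown {t.destination!r}")
        if t.pathway not in PATHWAYS:
            rep.add("bad_pathway", t.gene_id, f"unknown {t.pathway!r}")
        if t.destination != "cytosol" and t.pathway == "none":
            rep.add("unrouted_secretion", t.gene_id,
                    "non-cytosolic destination requires a translocation pathway")

    required_roles = ["rna_polymerase", "ribosome", "degradosome"] + [
        f"trna_synthetase:{aa}" for aa in spec.trna_genes
    ]
    for role in required_roles:
        if role not in spec.machinery_roles:
            rep.add("missing_role", role, "machinery role not assigned")
        elif spec.machinery_roles[role] not in cplx_ids:
            rep.add("dangling_role", role,
                    f"role maps to unknown complex {spec.machinery_roles[role]!r}")

    total = sum(spec.biomass_composition.values())
    if abs(total - 1.0) > 1e-9:
        rep.add("biomass_fractions", "biomass_composition",
                f"fractions sum to {total!r}, not 1")
    for comp in spec.biomass_composition:
        if comp not in mets:
            rep.add("dangling_biomass_component", comp, "unknown component")

    for aa, gid in spec.trna_genes.items():
        if gid not in gene_ids or genes_by_id[gid].product_kind != "tRNA":
            rep.add("bad_trna_gene", aa, f"{gid!r} is not a tRNA gene")

    return rep


# ---------------------------------------------------------------------------
# serialization (directory of delimited tables + one JSON file)


def _jdump(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def spec_to_tables(spec: OrganismSpec) -> dict[str, str]:
    """Render the spec as named TSV/JSON text blobs (canonical form)."""

    def tsv(rows: list[dict], columns: list[str]) -> str:
        df = pd.DataFrame(rows, columns=columns)
        buf = _io.StringIO()
        df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
        return buf.getvalue()

    tables = {
        "metabolites.tsv": tsv(
            [
                {
                    "id": m.id, "name": m.name, "compartment": m.compartment,
                    "formula": _jdump(m.formula) if m.formula is not None else "",
                    "category": m.category,
                }
                for m in spec.metabolites
            ],
            ["id", "name", "compartment", "formula", "category"],
        ),
        "reactions.tsv": tsv(
            [
                {
                    "id": r.id, "stoichiometry": _jdump(r.stoichiometry),
                    "reversible": r.reversible, "lower_bound": repr(r.lower_bound),
                    "upper_bound": repr(r.upper_bound), "subsystem": r.subsystem,
                    "enzymatic": r.enzymatic,
                }
                for r in spec.core_reactions
            ],
            ["id", "stoichiometry", "reversible", "lower_bound", "upper_bound",
             "subsystem", "enzymatic"],
        ),
        "genes.tsv": tsv(
            [
                {
                    "id": g.id, "nucleotide_sequence": g.nucleotide_sequence,
                    "product_kind": g.product_kind,
                    "cleaved_start_residue": g.cleaved_start_residue,
                }
                for g in spec.genes
            ],
            ["id", "nucleotide_sequence", "product_kind", "cleaved_start_residue"],
        ),
        "transcription_units.tsv": tsv(
            [
                {
                    "id": tu.id, "gene_ids": ",".join(tu.gene_ids),
                    "sequence": tu.sequence, "sigma_factor": tu.sigma_factor,
                }
                for tu in spec.transcription_units
            ],
            ["id", "gene_ids", "sequence", "sigma_factor"],
        ),
        "complexes.tsv": tsv(
            [
                {
                    "id": c.id,
                    "subunit_stoichiometry": _jdump(c.subunit_stoichiometry),
                    "modifications": _jdump([list(m) for m in c.modifications]),
                }
                for c in spec.complexes
            ],
            ["id", "subunit_stoichiometry", "modifications"],
        ),
        "enzyme_assignments.tsv": tsv(
            [
                {
                    "reaction_id": a.reaction_id, "complex_id": a.complex_id,
                    "keff": repr(a.keff), "tier": a.tier,
                }
                for a in spec.enzyme_assignments
            ],
            ["reaction_id", "complex_id", "keff", "tier"],
        ),
        "translocations.tsv": tsv(
            [
                {"gene_id": t.gene_id, "pathway": t.pathway,
                 "destination": t.destination}
                for t in spec.translocations
            ],
            ["gene_id", "pathway", "destination"],
        ),
        "organism.json": json.dumps(
            {
                "machinery_roles": spec.machinery_roles,
                "biomass_composition": spec.biomass_composition,
                "global_rates": spec.global_rates,
                "trna_genes": spec.trna_genes,
                "unmodeled_protein_gene": spec.unmodeled_protein_gene,
                "translocase_complex": spec.translocase_complex,
                "ground_truth": asdict(spec.ground_truth),
                "motifs": spec.motifs,
            },
            sort_keys=True, indent=1,
        ) + "\n",
    }
    return tables


def spec_to_bytes(spec: OrganismSpec) -> bytes:
    """Canonical byte serialization (used for determinism and hashing)."""
    tables = spec_to_tables(spec)
    chunks = []
    for name in sorted(tables):
        chunks.append(name.encode())
        chunks.append(tables[name].encode())
    return b"\n".join(chunks)


def spec_hash(spec: OrganismSpec) -> str:
    return hashlib.sha256(spec_to_bytes(spec)).hexdigest()


def write_spec(spec: OrganismSpec, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, text in spec_to_tables(spec).items():
        (directory / name).write_text(text)


def read_spec(directory: str | Path) -> OrganismSpec:
    directory = Path(directory)

    def table(name: str) -> pd.DataFrame:
        return pd.read_csv(directory / name, sep="\t", keep_default_na=False,
                           dtype=str)

    mets = [
        Metabolite(
            id=row["id"], name=row["name"], compartment=row["compartment"],
            formula=json.loads(row["formula"]) if row["formula"] else None,
            category=row["category"],
        )
        for _, row in table("metabolites.tsv").iterrows()
    ]
    rxns = [
        CoreReaction(
            id=row["id"], stoichiometry=json.loads(row["stoichiometry"]),
            reversible=row["reversible"] == "True",
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
            subsystem=row["subsystem"], enzymatic=row["enzymatic"] == "True",
        )
        for _, row in table("reactions.tsv").iterrows()
    ]
    genes = [
        Gene(
            id=row["id"], nucleotide_sequence=row["nucleotide_sequence"],
            product_kind=row["product_kind"],
            cleaved_start_residue=row["cleaved_start_residue"] == "True",
        )
        for _, row in table("genes.tsv").iterrows()
    ]
    tus = [
        TranscriptionUnit(
            id=row["id"], gene_ids=tuple(row["gene_ids"].split(",")),
            sequence=row["sequence"], sigma_factor=row["sigma_factor"],
        )
        for _, row in table("transcription_units.tsv").iterrows()
    ]
    cplxs = [
        ProteinComplex(
            id=row["id"],
            subunit_stoichiometry=json.loads(row["subunit_stoichiometry"]),
            modifications=tuple(
                (c, int(n)) for c, n in json.loads(row["modifications"])
            ),
        )
        for _, row in table("complexes.tsv").iterrows()
    ]
    assigns = [
        EnzymeAssignment(
            reaction_id=row["reaction_id"], complex_id=row["complex_id"],
            keff=float(row["keff"]), tier=row["tier"],
        )
        for _, row in table("enzyme_assignments.tsv").iterrows()
    ]
    tlocs = [
        TranslocationAssignment(
            gene_id=row["gene_id"], pathway=row["pathway"],
            destination=row["destination"],
        )
        for _, row in table("translocations.tsv").iterrows()
    ]
    meta = json.loads((directory / "organism.json").read_text())
    gt = GroundTruth(
        essential_genes=tuple(meta["ground_truth"]["essential_genes"]),
        reporter_gene=meta["ground_truth"]["reporter_gene"],
        reporter_aa_counts=meta["ground_truth"]["reporter_aa_counts"],
        expected_sensitivity=meta["ground_truth"]["expected_sensitivity"],
    )
    return OrganismSpec(
        metabolites=mets, core_reactions=rxns, genes=genes,
        transcription_units=tus, complexes=cplxs, enzyme_assignments=assigns,
        translocations=tlocs, machinery_roles=meta["machinery_roles"],
        biomass_composition=meta["biomass_composition"],
        global_rates=meta["global_rates"], trna_genes=meta["trna_genes"],
        unmodeled_protein_gene=meta["unmodeled_protein_gene"],
        translocase_complex=meta["translocase_complex"],
        ground_truth=gt, motifs=meta["motifs"],
    )
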