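"""Readers and writers for models, fluxes, samples and time courses.

The ME-model file format is a JSON dialect in the COBRAme style:
species with kinds, reactions with per-species coefficient expressions
encoded as ``{"constant": a, "mu_linear": b}`` records, growth-rate-
dependent bounds in the same encoding, and provenance (spec hash). Files
are written canonically (sorted keys, fixed indentation) so that a
write/read/write round trip is bit-exact. Constructs outside the dialect
are collected as warnings and loaded as opaque reactions — countable,
but flagged as unsupported for solving — never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


import pandas as pd

from .memodel import MEModel, MEReaction, MuCoefficient, RTYPE, Species
from .secretion import SampleSet, TimeCourse
from .solve import FluxSolution

FORMAT_TAG = "mecell-me-json"
FORMAT_VERSION = 1


@dataclass
class ModelFileRecord:
    genes: int
    reactions: int
    species: int
    dialect: str
    warnings: list[str] = field(default_factory=list)
    unsupported_reactions: list[str] = field(default_factory=list)


def model_to_json_dict(model: MEModel) -> dict:
    return {
        "format": FORMAT_TAG,
        "version": FORMAT_VERSION,
        "id": model.id,
        "objective": model.objective,
        "spec_hash": model.spec_hash,
        "species": [
            {"id": s.id, "kind": s.kind, "compartment": s.compartment,
             "formula": s.formula}
            for s in model.species.values()
        ],
        "reactions": [
            {
                "id": r.id, "rtype": r.rtype, "subsystem": r.subsystem,
                "gene_id": r.gene_id, "tu_id": r.tu_id,
                "lower_bound": r.lower_bound.to_json(),
                "upper_bound": r.upper_bound.to_json(),
                "stoichiometry": {sp: c.to_json()
                                  for sp, c in r.stoichiometry.items()},
                "coupling_species": sorted(r.coupling_species),
            }
            for r in model.reactions.values()
        ],
        "translation_index": model.translation_index,
        "transcription_index": model.transcription_index,
        "motifs": model.motifs,
        "ground_truth": model.ground_truth,
    }


def write_me_json(model: MEModel, path: str | Path) -> None:
    text = json.dumps(model_to_json_dict(model), sort_keys=True, indent=1)
    Path(path).write_text(text + "\n")


def read_cobrame_json(path: str | Path) -> tuple[MEModel, ModelFileRecord]:
    """Load a COBRAme-style JSON model file.

    Returns the model plus a census record (gene, reaction and species
    counts, dialect tag, warnings). Reactions with unknown types or
    coefficient expressions are loaded opaquely and listed as
    unsupported.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON at line {exc.lineno}, "
                         f"column {exc.colno}: {exc.msg}") from exc
    dialect = data.get("format", "unknown")
    warnings: list[str] = []
    unsupported: list[str] = []
    if dialect != FORMAT_TAG:
        warnings.append(f"unknown dialect tag {dialect!r}; attempting best effort")
    model = MEModel(id=data.get("id", path.stem),
                    objective=data.get("objective", ""),
                    spec_hash=data.get("spec_hash", ""),
                    translation_index=data.get("translation_index", {}),
                    transcription_index=data.get("transcription_index", {}),
                    motifs=data.get("motifs", {}),
                    ground_truth=data.get("ground_truth", {}))
    for s in data.get("species", []):
        model.add_species(Species(s["id"], s.get("kind", "metabolite"),
                                  s.get("compartment", "cytosol"),
                                  s.get("formula")))
    for r in data.get("reactions", []):
        rtype = r.get("rtype", "metabolic")
        if rtype not in RTYPE:
            warnings.append(f"reaction {r['id']}: unknown type {rtype!r}, "
                            "loaded as opaque")
            unsupported.append(r["id"])
            rtype = "metabolic"
        stoich = {}
        ok = True
        for sp, c in r.get("stoichiometry", {}).items():
            try:
                stoich[sp] = MuCoefficient.from_json(c)
            except (ValueError, TypeError) as exc:
                warnings.append(f"reaction {r['id']}: unsupported coefficient "
                                f"for {sp}: {exc}")
                unsupported.append(r["id"])
                ok = False
        rxn = MEReaction(
            id=r["id"], rtype=rtype, stoichiometry=stoich if ok else {},
            lower_bound=MuCoefficient.from_json(r.get("lower_bound", 0.0)),
            upper_bound=MuCoefficient.from_json(r.get("upper_bound", 1000.0)),
            subsystem=r.get("subsystem", ""), gene_id=r.get("gene_id", ""),
            tu_id=r.get("tu_id", ""),
            coupling_species=set(r.get("coupling_species", [])),
        )
        for sp in rxn.stoichiometry:
            if sp not in model.species:
                warnings.append(f"reaction {r['id']}: undeclared species {sp}, "
                                "registered as metabolite")
                model.add_species(Species(sp, "metabolite"))
        model.add_reaction(rxn)
    genes = len(model.translation_index) or len(
        {r.gene_id for r in model.reactions.values() if r.gene_id})
    record = ModelFileRecord(
        genes=genes, reactions=len(model.reactions),
        species=len(model.species), dialect=dialect,
        warnings=warnings, unsupported_reactions=sorted(set(unsupported)),
    )
    return model, record


# ---------------------------------------------------------------------------
# flat tables


def write_fluxes(solution: FluxSolution, path: str | Path,
                 provenance: dict | None = None) -> None:
    """Two-column delimited flux table with a provenance header."""
    lines = []
    for key, val in (provenance or {}).items():
        lines.append(f"# {key}={val}")
    lines.append("reaction\tflux")
    for rid, v in solution.fluxes.items():
        lines.append(f"{rid}\t{v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fluxes(path: str | Path) -> FluxSolution:
    df = pd.read_csv(path, sep="\t", comment="#")
    return FluxSolution("feasible",
                        pd.Series(df["flux"].values, index=df["reaction"]))


def write_sample_set(samples: SampleSet, path: str | Path) -> None:
    header = [f"# seed={samples.seed}",
              f"# condition={json.dumps(samples.condition, sort_keys=True)}"]
    body = samples.fluxes.to_csv(sep="\t", index_label="sample",
                                 lineterminator="\n")
    Path(path).write_text("\n".join(header) + "\n" + body)


def read_sample_set(path: str | Path) -> SampleSet:
    path = Path(path)
    seed, condition = 0, {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "seed":
                seed = int(val)
            elif key.strip() == "condition":
                condition = json.loads(val)
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample")
    return SampleSet(df, condition, seed)


def write_timecourse(tc: TimeCourse, path: str | Path) -> None:
    cols = {"t": tc.times, "X": tc.biomass}
    if tc.product is not None:
        cols["C"] = tc.product
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                              lineterminator="\n")


def read_timecourse(path: str | Path) -> TimeCourse:
    df = pd.read_csv(path, sep="\t", comment="#")
    product = df["C"].to_numpy() if "C" in df.columns else (
        df["A"].to_numpy() if "A" in df.columns else None)
    return TimeCourse(df["t"].to_numpy(), df["X"].to_numpy(), product)


def write_truth_set(labels: dict[str, str], path: str | Path) -> None:
    lines = ["id\tlabel"] + [f"{k}\t{v}" for k, v in sorted(labels.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_set(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["id"], df["label"]))


def read_genbank_genes(path: str | Path):
    """Extract gene ids and coding sequences from a GenBank file.

    Supports user-supplied annotation as an alternative gene source;
    only CDS features with a locus tag (or gene name) are returned, as
    :class:`~mecell.organism.Gene` records. Building a full organism
    spec from annotation databases is out of scope.
    """
    from Bio import SeqIO

    from .organism import Gene

    genes = []
    for record in SeqIO.parse(str(path), "genbank"):
        for feature in record.features:
            if feature.type != "CDS":
                continue
            name = (feature.qualifiers.get("locus_tag")
                    or feature.qualifiers.get("gene") or [None])[0]
            if name is None:
                continue
            seq = str(feature.extract(record.seq))
            genes.append(Gene(name, seq))
    return genes
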