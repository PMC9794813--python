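"""Growth-rate-dependent model containers.

A metabolism-and-expression model is a stoichiometric network whose
coefficients may depend on the growth rate mu. Every coefficient here is
affine in mu, ``a + b*mu`` (the constant and ratio forms of the coupling
conventions both reduce to this), so substituting a numeric mu yields an
ordinary linear program.
"""

from __future__ import annotations

import copy
from collections import Counter
from dataclasses import dataclass, field


@dataclass(frozen=True)
class MuCoefficient:
    """Scalar coefficient as an affine function of growth rate mu (1/h)."""

    constant: float = 0.0
    mu_linear: float = 0.0

    def value(self, mu: float) -> float:
        return self.constant + self.mu_linear * mu

    @property
    def is_constant(self) -> bool:
        return self.mu_linear == 0.0

    @classmethod
    def const(cls, c: float) -> "MuCoefficient":
        return cls(float(c), 0.0)

    @classmethod
    def linear(cls, a: float, b: float) -> "MuCoefficient":
        return cls(float(a), float(b))

    @classmethod
    def ratio(cls, a: float, b: float, c: float) -> "MuCoefficient":
        """(a + b*mu) / c."""
        return cls(float(a) / float(c), float(b) / float(c))

    def __add__(self, other: "MuCoefficient") -> "MuCoefficient":
        return MuCoefficient(self.constant + other.constant,
                             self.mu_linear + other.mu_linear)

    def __neg__(self) -> "MuCoefficient":
        return MuCoefficient(-self.constant, -self.mu_linear)

    def to_json(self) -> dict:
        return {"constant": self.constant, "mu_linear": self.mu_linear}

    @classmethod
    def from_json(cls, obj) -> "MuCoefficient":
        if isinstance(obj, (int, float)):
            return cls.const(obj)
        unknown = set(obj) - {"constant", "mu_linear"}
        if unknown:
            raise ValueError(f"unsupported coefficient expression fields {unknown}")
        return cls(float(obj.get("constant", 0.0)), float(obj.get("mu_linear", 0.0)))


RTYPE = (
    "metabolic", "exchange", "demand", "transcription", "translation",
    "complex_formation", "trna_charging", "post_translation",
    "translocation", "biomass_dilution",
)


@dataclass
class MEReaction:
    id: str
    rtype: str
    stoichiometry: dict[str, MuCoefficient] = field(default_factory=dict)
    lower_bound: MuCoefficient = MuCoefficient(0.0, 0.0)
    upper_bound: MuCoefficient = MuCoefficient(1000.0, 0.0)
    subsystem: str = ""
    #: species ids whose entries are enzyme/machinery couplings
    coupling_species: set[str] = field(default_factory=set)
    gene_id: str = ""
    tu_id: str = ""

    def add(self, species: str, coeff: MuCoefficient, coupling: bool = False) -> None:
        if species in self.stoichiometry:
            self.stoichiometry[species] = self.stoichiometry[species] + coeff
        else:
            self.stoichiometry[species] = coeff
        if coupling:
            self.coupling_species.add(species)


@dataclass(frozen=True)
class Species:
    id: str
    kind: str            # metabolite, constraint_component, mrna, trna, ...
    compartment: str = "cytosol"
    formula: dict | None = None


@dataclass
class MEModel:
    """Assembled network; reactions keep symbolic mu-dependence."""

    id: str
    species: dict[str, Species] = field(default_factory=dict)
    reactions: dict[str, MEReaction] = field(default_factory=dict)
    objective: str = ""
    spec_hash: str = ""
    #: gene -> translation reaction id (protein-coding genes)
    translation_index: dict[str, str] = field(default_factory=dict)
    #: gene -> ids of transcription reactions producing its transcript
    transcription_index: dict[str, list[str]] = field(default_factory=dict)
    #: carried over from the organism spec for downstream analyses
    motifs: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def add_species(self, sp: Species) -> None:
        self.species.setdefault(sp.id, sp)

    def add_reaction(self, rxn: MEReaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        missing = [s for s in rxn.stoichiometry if s not in self.species]
        if missing:
            raise ValueError(f"{rxn.id}: unknown species {missing}")
        self.reactions[rxn.id] = rxn

    def census(self) -> dict[str, int]:
        return dict(Counter(r.rtype for r in self.reactions.values()))

    def species_census(self) -> dict[str, int]:
        return dict(Counter(s.kind for s in self.species.values()))

    def copy(self) -> "MEModel":
        out = copy.deepcopy(self)
        # solver-side compilation caches must not survive the copy
        out.__dict__.pop("_compiled", None)
        return out

    def exchanges(self) -> list[MEReaction]:
        return [r for r in self.reactions.values() if r.rtype == "exchange"]
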