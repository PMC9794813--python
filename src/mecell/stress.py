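"""Ethanol, salt, and folate-damage stress simulation.

Stressor influx follows the uncoupled-uptake convention: the stressor's
exchange is forced to a fixed uptake rate with no transporter expression
induced by the influx, while any export route stays coupled to the
synthesis of its transporter. Expression responses are read off the
transcription and translation fluxes of the solved model, normalized to
their maximum across a sweep, and differential-expression calls are
scored against reference labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .build import consumed_aa_counts
from .errors import ContractError, SolveError
from .memodel import MEModel, MEReaction, MuCoefficient
from .organism import OrganismSpec
from .solve import FluxSolution, GrowthResult, maximize_growth


@dataclass
class ExpressionProfile:
    """Per-gene transcription and translation fluxes at one condition."""

    condition: str
    stressor_rate: float
    table: pd.DataFrame  # index gene; columns transcription, translation


@dataclass
class StressSweep:
    stressor: str
    rates: list[float]
    profiles: list[Optional[ExpressionProfile]]  # None where infeasible
    tracked: pd.DataFrame  # index rate; one column per tracked reaction
    growth: pd.Series      # index rate


def _find_exchange(model: MEModel, metabolite_id: str) -> str:
    hits = [r.id for r in model.exchanges()
            if list(r.stoichiometry) == [metabolite_id]]
    if not hits:
        raise ContractError(f"{metabolite_id!r} has no exchange reaction")
    return hits[0]


def extract_expression(model: MEModel, solution: FluxSolution,
                       condition: str = "", rate: float = 0.0
                       ) -> ExpressionProfile:
    """Read per-gene expression fluxes out of a solved flux vector."""
    rows = {}
    for gid, t_rid in model.translation_index.items():
        txn = sum(solution[r] for r in model.transcription_index.get(gid, []))
        rows[gid] = {"transcription": txn, "translation": solution[t_rid]}
    return ExpressionProfile(condition, rate,
                             pd.DataFrame.from_dict(rows, orient="index"))


def simulate_uncoupled_uptake(model: MEModel, metabolite_id: str,
                              rate: float, tol: float = 1e-6) -> GrowthResult:
    """Force stressor influx at ``rate`` and solve to optimal growth.

    The stressor exchange gets lower = upper = -rate; all other
    exchanges are untouched, and no transporter usage is attached to the
    influx (export, if present, keeps its enzyme coupling).
    """
    if rate < 0:
        raise ContractError("uptake rate must be non-negative")
    exch = _find_exchange(model, metabolite_id)
    variant = model.copy()
    rxn = variant.reactions[exch]
    rxn.lower_bound = rxn.upper_bound = MuCoefficient(-rate, 0.0)
    try:
        return maximize_growth(variant, tol=tol)
    except SolveError as exc:
        raise SolveError(
            f"stress-infeasible: no growth sustains {metabolite_id} influx "
            f"of {rate} mmol/gDW/h ({exc})") from exc


def sweep_stressor(model: MEModel, metabolite_id: str,
                   rates: Iterable[float],
                   tracked_reactions: Iterable[str] = (),
                   tol: float = 1e-6) -> StressSweep:
    """One solved expression profile per stressor uptake rate."""
    rates = list(rates)
    if any(b < a for a, b in zip(rates, rates[1:])):
        raise ContractError("stressor rates must be sorted ascending")
    tracked_reactions = list(tracked_reactions)
    profiles, tracked_rows, growth = [], [], []
    for rate in rates:
        try:
            res = simulate_uncoupled_uptake(model, metabolite_id, rate, tol)
        except SolveError:
            profiles.append(None)
            tracked_rows.append({r: np.nan for r in tracked_reactions})
            growth.append(np.nan)
            continue
        profiles.append(extract_expression(model, res.solution,
                                           f"{metabolite_id}={rate}", rate))
        tracked_rows.append({r: res.solution[r] for r in tracked_reactions})
        growth.append(res.mu_star)
    return StressSweep(
        stressor=metabolite_id, rates=rates, profiles=profiles,
        tracked=pd.DataFrame(tracked_rows, index=pd.Index(rates, name="rate")),
        growth=pd.Series(growth, index=pd.Index(rates, name="rate")),
    )


def simulate_folate_damage(model: MEModel, damage_rate: float,
                           folate_species: str = "fol_c",
                           tol: float = 1e-6) -> GrowthResult:
    """Drain the folate pool at a fixed rate (cofactor damage) and solve.

    Adds a demand reaction consuming the folate analog at exactly
    ``damage_rate``; at steady state the folate-synthesis pathway must
    rise by the same amount.
    """
    if folate_species not in model.species:
        raise ContractError(f"no folate-analog species {folate_species!r}")
    variant = model.copy()
    dmg = MEReaction("folate_damage", "demand", subsystem="cofactor damage",
                     lower_bound=MuCoefficient(damage_rate, 0.0),
                     upper_bound=MuCoefficient(damage_rate, 0.0))
    dmg.add(folate_species, MuCoefficient.const(-1.0))
    variant.add_reaction(dmg)
    try:
        return maximize_growth(variant, tol=tol)
    except SolveError as exc:
        raise SolveError(
            f"folate damage rate {damage_rate} is not sustainable "
            f"({exc})") from exc


def normalize_profiles(sweep: StressSweep) -> StressSweep:
    """Scale each gene's expression series by its maximum over the sweep.

    All-zero series map to all-zero (the conventional reading of a
    flux-ratio normalization for silent genes).
    """
    live = [p for p in sweep.profiles if p is not None]
    if not live:
        raise ContractError("sweep contains no feasible profiles")
    stacked = {c: pd.DataFrame({p.stressor_rate: p.table[c] for p in live})
               for c in ("transcription", "translation")}
    norm_profiles: list[Optional[ExpressionProfile]] = []
    for p in sweep.profiles:
        if p is None:
            norm_profiles.append(None)
            continue
        table = p.table.copy()
        for c in ("transcription", "translation"):
            peak = stacked[c].max(axis=1)
            scale = peak.where(peak > 0, 1.0)
            table[c] = (p.table[c] / scale).where(peak > 0, 0.0)
        norm_profiles.append(ExpressionProfile(p.condition, p.stressor_rate,
                                               table))
    return StressSweep(sweep.stressor, sweep.rates, norm_profiles,
                       sweep.tracked.copy(), sweep.growth.copy())


@dataclass
class AttributionTable:
    """Per-protein share of the change in one amino acid's synthesis."""

    amino_acid: str
    total_change: float
    defined: bool
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: delta_consumption, fraction


def attribute_amino_acid_demand(model: MEModel, spec: OrganismSpec,
                                sol_base: FluxSolution,
                                sol_stress: FluxSolution,
                                amino_acid: str) -> AttributionTable:
    """Attribute the change in an amino acid's synthesis to proteins.

    Each protein's contribution is the change in its translation flux
    times its (net) count of the amino acid; machinery proteins appear
    as their own rows. Because charging and translation are the amino
    acid's only sinks, the fractions sum to one whenever the total
    change is nonzero.
    """
    from .organism import AA_NAMES

    if amino_acid not in AA_NAMES:
        raise ContractError(f"unknown amino acid {amino_acid!r}")
    aa_sp = f"aa_{AA_NAMES[amino_acid]}_c"
    synth = [
        r.id for r in model.reactions.values()
        if r.rtype == "metabolic" and r.stoichiometry.get(aa_sp) is not None
        and r.stoichiometry[aa_sp].constant > 0
    ]
    total = sum(
        (sol_stress[r] - sol_base[r]) * model.reactions[r].stoichiometry[aa_sp].constant
        for r in synth
    )
    rows = {}
    for gene in spec.protein_genes():
        count = consumed_aa_counts(gene).get(amino_acid, 0)
        if count == 0:
            continue
        rid = model.translation_index[gene.id]
        delta = (sol_stress[rid] - sol_base[rid]) * count
        rows[gene.id] = {"delta_consumption": delta}
    table = pd.DataFrame.from_dict(rows, orient="index")
    if abs(total) < 1e-15:
        return AttributionTable(amino_acid, total, False, table)
    table["fraction"] = table["delta_consumption"] / total
    table = table.sort_values("fraction", ascending=False)
    return AttributionTable(amino_acid, total, True, table)


# ---------------------------------------------------------------------------
# differential expression


def differential_expression_calls(profile_base: ExpressionProfile,
                                  profile_stress: ExpressionProfile,
                                  epsilon: float = 0.05,
                                  layer: str = "translation") -> pd.DataFrame:
    """Call up/down/unchanged per gene from two expression profiles.

    A gene is up (down) when its relative flux change exceeds
    ``epsilon``; genes present in only one profile are dropped.
    """
    shared = profile_base.table.index.intersection(profile_stress.table.index)
    if shared.empty:
        raise ContractError("profiles share no genes")
    base = profile_base.table.loc[shared, layer]
    stress = profile_stress.table.loc[shared, layer]
    rel = pd.Series(0.0, index=shared)
    nonzero = base.abs() > 0
    rel[nonzero] = (stress[nonzero] - base[nonzero]) / base[nonzero].abs()
    rel[~nonzero & (stress.abs() > 0)] = np.inf  # silent gene switched on
    call = pd.Series("unchanged", index=shared)
    call[rel > epsilon] = "up"
    call[rel < -epsilon] = "down"
    return pd.DataFrame({"base": base, "stress": stress,
                         "relative_change": rel, "call": call})


def score_de(calls: pd.DataFrame, reference: pd.DataFrame) -> dict:
    """Accuracy of differential-expression calls against reference labels.

    ``reference`` has a ``direction`` column (up/down/unchanged) and an
    optional ``subsystem`` column. Accuracy is computed over the genes
    the reference marks as differentially expressed, overall, per
    direction, and per subsystem.
    """
    shared = calls.index.intersection(reference.index)
    if shared.empty:
        raise ContractError("no genes shared with the reference")
    pred = calls.loc[shared, "call"]
    ref = reference.loc[shared, "direction"]
    changed = ref.isin(["up", "down"])
    if not changed.any():
        raise ContractError("reference marks no gene as changed")
    correct = (pred[changed] == ref[changed])
    report = {
        "n_reference_changed": int(changed.sum()),
        "accuracy": float(correct.mean()),
        "accuracy_by_direction": {
            d: float((pred[changed & (ref == d)] == d).mean())
            for d in ("up", "down") if (changed & (ref == d)).any()
        },
    }
    if "subsystem" in reference.columns:
        by_sub = {}
        for sub, idx in reference.loc[shared].groupby("subsystem").groups.items():
            mask = changed.loc[idx]
            if mask.any():
                sel = pd.Index(idx)[mask.values]
                by_sub[sub] = float((pred.loc[sel] == ref.loc[sel]).mean())
        report["accuracy_by_subsystem"] = by_sub
    return report
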