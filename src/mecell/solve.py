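"""Growth maximization by bisection over LP feasibility.

At a fixed growth rate mu every coefficient of the ME model is numeric,
so the model is an ordinary linear program: find v with S(mu) v = 0
within bounds. Feasibility is monotone in mu (larger growth only adds
expression burden and biomass demand), so the maximum feasible growth
rate is located by binary search, exactly as nonlinear ME formulations
are solved in practice. LPs are solved in double precision with HiGHS
and tight feasibility tolerances, and the steady-state residual of every
reported solution is checked explicitly rather than assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from scipy.stats import pearsonr

from .errors import ContractError, SolveError
from .memodel import MEModel

#: default LP feasibility tolerance handed to HiGHS
FEAS_TOL = 1e-9
#: allowed steady-state residual of accepted solutions
RESIDUAL_TOL = 1e-7


@dataclass
class LinearProblem:
    """Numeric LP at one growth rate: S v = 0, lb <= v <= ub."""

    S: sparse.csr_matrix
    lower: np.ndarray
    upper: np.ndarray
    reaction_ids: list[str]
    species_ids: list[str]
    mu: float


@dataclass
class FluxSolution:
    status: str                      # "feasible" | "infeasible"
    fluxes: pd.Series | None = None  # reaction id -> mmol/gDW/h

    @property
    def feasible(self) -> bool:
        return self.status == "feasible"

    def __getitem__(self, rid: str) -> float:
        if self.fluxes is None:
            raise KeyError("infeasible solution carries no fluxes")
        return float(self.fluxes[rid])


@dataclass
class GrowthResult:
    mu_star: float
    bracket: tuple[float, float]
    solution: FluxSolution
    iterations: int


@dataclass
class _Compiled:
    A0: sparse.csr_matrix
    A1: sparse.csr_matrix
    lb0: np.ndarray
    lb1: np.ndarray
    ub0: np.ndarray
    ub1: np.ndarray
    reaction_ids: list[str]
    species_ids: list[str]


def _compile(model: MEModel) -> _Compiled:
    cached = getattr(model, "_compiled", None)
    if cached is not None:
        return cached
    species_ids = list(model.species)
    sidx = {s: i for i, s in enumerate(species_ids)}
    reaction_ids = list(model.reactions)
    rows0, cols0, vals0 = [], [], []
    rows1, cols1, vals1 = [], [], []
    nr = len(reaction_ids)
    lb0, lb1 = np.zeros(nr), np.zeros(nr)
    ub0, ub1 = np.zeros(nr), np.zeros(nr)
    for j, rid in enumerate(reaction_ids):
        rxn = model.reactions[rid]
        lb0[j], lb1[j] = rxn.lower_bound.constant, rxn.lower_bound.mu_linear
        ub0[j], ub1[j] = rxn.upper_bound.constant, rxn.upper_bound.mu_linear
        for sp, coeff in rxn.stoichiometry.items():
            i = sidx[sp]
            if coeff.constant:
                rows0.append(i); cols0.append(j); vals0.append(coeff.constant)
            if coeff.mu_linear:
                rows1.append(i); cols1.append(j); vals1.append(coeff.mu_linear)
    shape = (len(species_ids), nr)
    compiled = _Compiled(
        sparse.csr_matrix((vals0, (rows0, cols0)), shape=shape),
        sparse.csr_matrix((vals1, (rows1, cols1)), shape=shape),
        lb0, lb1, ub0, ub1, reaction_ids, species_ids,
    )
    model._compiled = compiled
    return compiled


def substitute_mu(model: MEModel, mu: float) -> LinearProblem:
    """Evaluate every mu-dependent coefficient at a fixed growth rate."""
    if mu < 0:
        raise ContractError(f"growth rate must be non-negative, got {mu}")
    c = _compile(model)
    return LinearProblem(
        S=(c.A0 + mu * c.A1).tocsr(),
        lower=c.lb0 + mu * c.lb1,
        upper=c.ub0 + mu * c.ub1,
        reaction_ids=c.reaction_ids,
        species_ids=c.species_ids,
        mu=mu,
    )


def check_feasible(lp: LinearProblem, minimize_total_flux: bool = False,
                   feas_tol: float = FEAS_TOL,
                   residual_tol: float = RESIDUAL_TOL) -> FluxSolution:
    """Solve the steady-state LP; distinguish infeasibility from failure.

    With ``minimize_total_flux`` the LP minimizes the sum of (signed
    absolute) fluxes, which yields a stable, loop-free representative
    flux vector; otherwise any feasible point is accepted.
    """
    if np.any(lp.lower > lp.upper + 1e-12):
        # conflicting bounds (e.g. a structurally closed reaction whose
        # flux is forced at mu > 0): infeasible without a solver call
        return FluxSolution("infeasible")
    n = len(lp.reaction_ids)
    if minimize_total_flux:
        # all non-exchange reactions are non-negative by construction;
        # penalize magnitude so reversible exchanges are not rewarded
        cost = np.where(lp.lower >= 0, 1.0, 0.0)
    else:
        cost = np.zeros(n)
    args = dict(A_eq=lp.S, b_eq=np.zeros(lp.S.shape[0]),
                bounds=np.column_stack([lp.lower, lp.upper]), method="highs")
    res = linprog(cost, **args,
                  options={"primal_feasibility_tolerance": feas_tol,
                           "dual_feasibility_tolerance": feas_tol})
    if res.status == 4:
        # presolve + tight tolerances can leave HiGHS undecided on
        # near-degenerate problems; re-solve without presolve
        res = linprog(cost, **args,
                      options={"primal_feasibility_tolerance": feas_tol,
                               "dual_feasibility_tolerance": feas_tol,
                               "presolve": False})
    if res.status == 2:
        return FluxSolution("infeasible")
    if res.status != 0:
        raise SolveError(f"LP solver failure (status {res.status}): {res.message}")
    v = np.asarray(res.x)
    residual = np.abs(lp.S @ v)
    if residual.size and residual.max() > residual_tol:
        raise SolveError(
            f"steady-state residual {residual.max():.2e} exceeds {residual_tol:.0e}")
    return FluxSolution("feasible", pd.Series(v, index=lp.reaction_ids))


def _feasible_at(model: MEModel, mu: float, **kw) -> FluxSolution:
    return check_feasible(substitute_mu(model, mu), **kw)


def maximize_growth(model: MEModel, mu_min: float = 0.0, mu_max: float = 2.0,
                    tol: float = 1e-6,
                    minimize_total_flux: bool = True) -> GrowthResult:
    """Binary search for the maximum feasible growth rate.

    The bracket is tightened until it is no wider than ``tol``; the
    reported ``mu_star`` is the feasible lower end, and the attached
    flux solution is re-solved there (by default with the total-flux
    secondary objective for a stable vector).
    """
    if tol <= 0:
        raise ContractError("tol must be positive")
    if not _feasible_at(model, mu_min).feasible:
        raise SolveError(f"no growth: model infeasible at mu={mu_min}")
    iterations = 0
    if _feasible_at(model, mu_max).feasible:
        warnings.warn("model feasible at mu_max; bracket saturated",
                      RuntimeWarning, stacklevel=2)
        sol = _feasible_at(model, mu_max, minimize_total_flux=minimize_total_flux)
        return GrowthResult(mu_max, (mu_max, mu_max), sol, 1)
    lo, hi = mu_min, mu_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        iterations += 1
        if _feasible_at(model, mid).feasible:
            lo = mid
        else:
            hi = mid
    sol = _feasible_at(model, lo, minimize_total_flux=minimize_total_flux)
    return GrowthResult(lo, (lo, hi), sol, iterations)


def grid_search_growth(model: MEModel, mu_min: float = 0.0, mu_max: float = 2.0,
                       step: float = 5e-7, points: int = 41) -> float:
    """Feasibility-scan oracle for the maximum growth rate.

    Scans successively finer uniform grids (every point is tested, no
    bisection logic) until the grid spacing drops below ``step``, and
    returns the largest feasible grid point. Used as an independent
    check of :func:`maximize_growth`.
    """
    lo, hi = mu_min, mu_max
    if not _feasible_at(model, lo).feasible:
        raise SolveError(f"infeasible at mu={lo}")
    while hi - lo > step:
        grid = np.linspace(lo, hi, points)
        feas = [True] + [_feasible_at(model, mu).feasible for mu in grid[1:]]
        last = max(i for i, ok in enumerate(feas) if ok)
        lo = grid[last]
        hi = grid[last + 1] if last + 1 < points else hi
        if last == points - 1:
            break
    return lo


_MU_PROBE = 0.5  # representative mu>0 for sign queries on affine coefficients


def _can_produce(rxn, coeff) -> bool:
    c = coeff.value(_MU_PROBE)
    return ((c > 0 and rxn.upper_bound.value(_MU_PROBE) > 1e-15)
            or (c < 0 and rxn.lower_bound.value(_MU_PROBE) < -1e-15))


def _can_consume(rxn, coeff) -> bool:
    c = coeff.value(_MU_PROBE)
    return ((c < 0 and rxn.upper_bound.value(_MU_PROBE) > 1e-15)
            or (c > 0 and rxn.lower_bound.value(_MU_PROBE) < -1e-15))


def _propagate_unproducible(model: MEModel) -> None:
    """Exact structural consequence of closed reactions, for mu > 0.

    A species none of whose remaining reactions can produce it must not
    be consumed, so every consuming direction is closed; this is iterated
    to a fixed point. In exact arithmetic the LP enforces the same
    zeros through chains of mu/keff couplings; closing them explicitly
    keeps machinery-loss phenotypes visible at double precision. A
    reaction whose lower bound is forced positive at mu > 0 (the biomass
    dilution) is left with conflicting bounds, making the model
    infeasible at every positive growth rate — i.e., the knockout is
    lethal — while mu = 0 stays feasible.
    """
    from .memodel import MuCoefficient

    producers: dict[str, set[str]] = {s: set() for s in model.species}
    consumers: dict[str, set[str]] = {s: set() for s in model.species}
    changed = True
    while changed:
        changed = False
        for s in producers:
            producers[s].clear()
            consumers[s].clear()
        for rid, rxn in model.reactions.items():
            for sp, coeff in rxn.stoichiometry.items():
                if _can_produce(rxn, coeff):
                    producers[sp].add(rid)
                if _can_consume(rxn, coeff):
                    consumers[sp].add(rid)
        for sp, prods in producers.items():
            if prods or not consumers[sp]:
                continue
            for rid in consumers[sp]:
                rxn = model.reactions[rid]
                c = rxn.stoichiometry[sp].value(_MU_PROBE)
                if c < 0 and rxn.upper_bound.value(_MU_PROBE) > 1e-15:
                    rxn.upper_bound = MuCoefficient(0.0, 0.0)
                    changed = True
                if c > 0 and rxn.lower_bound.value(_MU_PROBE) < -1e-15:
                    rxn.lower_bound = MuCoefficient(0.0, 0.0)
                    changed = True


def knockout_gene(model: MEModel, gene_id: str, propagate: bool = True) -> MEModel:
    """Close the gene's translation reaction (single-gene knockout).

    With ``propagate`` (default) the exact structural consequences of
    the missing protein — unformable complexes, unfulfillable coupling
    demands — are closed as well; see :func:`_propagate_unproducible`.
    """
    rid = model.translation_index.get(gene_id)
    if rid is None:
        raise ContractError(f"unknown or non-protein gene {gene_id!r}")
    out = model.copy()
    rxn = out.reactions[rid]
    rxn.lower_bound = rxn.upper_bound = type(rxn.lower_bound)(0.0, 0.0)
    if propagate:
        _propagate_unproducible(out)
    return out


def knockout_genes(model: MEModel, gene_ids, propagate: bool = True) -> MEModel:
    """Simultaneous knockout of several genes (double-knockout utility)."""
    out = model.copy()
    for gid in gene_ids:
        rid = out.translation_index.get(gid)
        if rid is None:
            raise ContractError(f"unknown or non-protein gene {gid!r}")
        rxn = out.reactions[rid]
        rxn.lower_bound = rxn.upper_bound = type(rxn.lower_bound)(0.0, 0.0)
    if propagate:
        _propagate_unproducible(out)
    return out


@dataclass
class ComparisonTable:
    table: pd.DataFrame       # per shared reaction: flux_a, flux_b, log10 each
    r_squared: float
    log10_bins: np.ndarray = field(default_factory=lambda: np.array([]))
    hist_a: np.ndarray = field(default_factory=lambda: np.array([]))
    hist_b: np.ndarray = field(default_factory=lambda: np.array([]))


def compare_solutions(sol_a: FluxSolution, sol_b: FluxSolution,
                      shared_reactions: list[str] | None = None,
                      threshold: float = 1e-9, n_bins: int = 20) -> ComparisonTable:
    """Pair log10 fluxes of two solutions and report their correlation.

    Reactions with |flux| below ``threshold`` in either solution are
    excluded from the pairing; the Pearson correlation on the log10
    pairs is reported as R^2, alongside log-flux histograms.
    """
    if not (sol_a.feasible and sol_b.feasible):
        raise ContractError("both solutions must be feasible")
    if shared_reactions is None:
        shared_reactions = [r for r in sol_a.fluxes.index
                            if r in sol_b.fluxes.index]
    if not shared_reactions:
        raise ContractError("no shared reactions to compare")
    a = sol_a.fluxes[shared_reactions].abs()
    b = sol_b.fluxes[shared_reactions].abs()
    mask = (a > threshold) & (b > threshold)
    if not mask.any():
        raise ContractError("no reaction carries flux in both solutions")
    la, lb = np.log10(a[mask]), np.log10(b[mask])
    if la.std() == 0 or lb.std() == 0:
        r2 = 1.0 if np.allclose(la, lb) else 0.0
    else:
        r2 = float(pearsonr(la, lb)[0] ** 2)
    table = pd.DataFrame({
        "flux_a": sol_a.fluxes[shared_reactions],
        "flux_b": sol_b.fluxes[shared_reactions],
        "log10_a": np.log10(a.where(a > threshold)),
        "log10_b": np.log10(b.where(b > threshold)),
    })
    table["log10_discrepancy"] = (table["log10_a"] - table["log10_b"]).abs()
    lo = min(la.min(), lb.min())
    hi = max(la.max(), lb.max())
    bins = np.linspace(lo, hi + 1e-12, n_bins + 1)
    return ComparisonTable(
        table=table.sort_values("log10_discrepancy", ascending=False),
        r_squared=r2, log10_bins=bins,
        hist_a=np.histogram(la, bins=bins)[0],
        hist_b=np.histogram(lb, bins=bins)[0],
    )
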