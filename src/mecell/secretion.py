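"""Protein-secretion analysis: kinetics, sampling, PCA, sensitivity.

Batch-culture estimators
    Exponential growth dX/dt = mu X is fitted on the natural-log scale
    (log X = mu t + k); the secretion rate follows from the product mass
    balance dC/dt = nu X as nu = (Cf - C0) / integral(X dt), with the
    integral taken by the trapezoid rule on the reported grid. Enzyme
    activities convert to concentration through a specific-activity
    range, and to molar units through the molecular weight of the mature
    protein sequence.

Solution-space analysis
    The near-optimal space (growth above a fraction of the optimum,
    exchange bounds randomized within the hull of two reference
    conditions) and the forced-overexpression space (growth fixed,
    secretion flux forced) are sampled with seeded draws; samples are
    z-scored and decomposed with PCA, and per-amino-acid sensitivities
    are mean flux differences between two sampled conditions divided by
    the secretion-rate difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ContractError, SolveError
from .memodel import MEModel, MuCoefficient
from .solve import check_feasible, maximize_growth, substitute_mu


# ---------------------------------------------------------------------------
# batch-culture kinetics


@dataclass
class TimeCourse:
    times: np.ndarray          # h
    biomass: np.ndarray        # g/L
    product: Optional[np.ndarray] = None  # mg/mL (or mU/mL for activity)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if self.product is not None:
            self.product = np.asarray(self.product, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ContractError("times must be strictly increasing")
        if len(self.times) < 3:
            raise ContractError("need at least 3 time points")


@dataclass
class KineticsFit:
    mu: float = np.nan          # 1/h
    intercept: float = np.nan   # log-scale k
    r_squared: float = np.nan
    nu: float = np.nan          # secretion rate per biomass per h
    window: tuple[int, int] = (0, 0)


def simulate_batch_timecourse(mu: float, nu: float, x0: float,
                              times: Iterable[float],
                              noise_cv: float = 0.0,
                              seed: int = 0) -> TimeCourse:
    """Exact exponential batch culture with constant specific secretion.

    X(t) = x0 e^{mu t}; C(t) = C0 + nu * integral X = nu x0 (e^{mu t}-1)/mu
    (or nu x0 t when mu = 0). Optional seeded multiplicative noise.
    """
    t = np.asarray(list(times), dtype=float)
    x = x0 * np.exp(mu * t)
    if mu != 0:
        c = nu * x0 * (np.exp(mu * t) - 1.0) / mu
    else:
        c = nu * x0 * t
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        x = x * np.exp(rng.normal(0.0, noise_cv, size=t.shape))
        c = c * np.exp(rng.normal(0.0, noise_cv, size=t.shape))
    return TimeCourse(t, x, c)


def estimate_growth_rate(tc: TimeCourse,
                         window: Optional[tuple[int, int]] = None
                         ) -> KineticsFit:
    """Least-squares fit of log biomass vs time over the chosen window."""
    i0, i1 = window if window else (0, len(tc.times))
    t = tc.times[i0:i1]
    x = tc.biomass[i0:i1]
    if len(t) < 3:
        raise ContractError("window selects fewer than 3 points")
    if np.any(x <= 0):
        raise ContractError("non-positive biomass in fit window")
    res = stats.linregress(t, np.log(x))
    return KineticsFit(mu=float(res.slope), intercept=float(res.intercept),
                       r_squared=float(res.rvalue ** 2), window=(i0, i1))


def estimate_secretion_rate(tc_biomass: TimeCourse,
                            tc_product: TimeCourse) -> KineticsFit:
    """Secretion rate nu = (Cf - C0) / integral(X dt) (trapezoid rule)."""
    if not np.array_equal(tc_biomass.times, tc_product.times):
        raise ContractError("time grids are not aligned")
    if tc_product.product is None:
        raise ContractError("product series missing")
    integral = float(np.trapezoid(tc_biomass.biomass, tc_biomass.times))
    if integral == 0:
        raise ContractError("biomass integral is zero")
    c = tc_product.product
    fit = estimate_growth_rate(tc_biomass)
    fit.nu = float((c[-1] - c[0]) / integral)
    return fit


def activity_to_concentration(activity_mU_per_mL: float,
                              specific_activity_range: tuple[float, float],
                              protein_sequence: Optional[str] = None
                              ) -> dict:
    """Convert an enzyme activity to a concentration interval.

    C = (A/1000)/SA in mg/mL at each end of the specific-activity range
    (U/mg); with a protein sequence, also mmol/L via the molecular
    weight of the (mature) sequence.
    """
    if activity_mU_per_mL < 0:
        raise ContractError("activity must be non-negative")
    lo_sa, hi_sa = sorted(specific_activity_range)
    if lo_sa <= 0:
        raise ContractError("specific activity must be positive")
    u_per_ml = activity_mU_per_mL / 1000.0
    conc = {"mg_per_mL": (u_per_ml / hi_sa, u_per_ml / lo_sa)}
    if protein_sequence:
        mw = molecular_weight(protein_sequence, seq_type="protein")  # g/mol
        conc["mmol_per_L"] = tuple(c * 1e6 / mw for c in conc["mg_per_mL"])
        conc["molecular_weight"] = mw
    return conc


# ---------------------------------------------------------------------------
# solution-space sampling


@dataclass
class SampleSet:
    fluxes: pd.DataFrame       # n_samples x reactions
    condition: dict
    seed: int

    @property
    def n(self) -> int:
        return len(self.fluxes)


def _force(model: MEModel, rid: str, lo: float, hi: float) -> None:
    rxn = model.reactions[rid]
    rxn.lower_bound = MuCoefficient(lo, 0.0)
    rxn.upper_bound = MuCoefficient(hi, 0.0)


def feasible_exchange_bounds(model: MEModel,
                             conditions: Iterable[Mapping[str, tuple[float, float]]]
                             ) -> pd.DataFrame:
    """Exchange-flux hull over a set of solved conditions.

    Each condition is a mapping reaction id -> (lo, hi) bound override;
    the model is solved to optimal growth under each and the per-exchange
    interval spanning the condition solutions is returned.
    """
    sols = []
    for cond in conditions:
        variant = model.copy()
        for rid, (lo, hi) in cond.items():
            _force(variant, rid, lo, hi)
        res = maximize_growth(variant)
        sols.append(res.solution.fluxes)
    if not sols:
        raise ContractError("no conditions given")
    ex_ids = [r.id for r in model.exchanges()]
    mat = pd.DataFrame([s[ex_ids] for s in sols])
    return pd.DataFrame({"lo": mat.min(axis=0), "hi": mat.max(axis=0)})


def sample_solution_space(model: MEModel, growth_frac: float = 0.9,
                          n: int = 100, seed: int = 0,
                          exchange_bounds: Optional[pd.DataFrame] = None,
                          max_retries: int = 50) -> SampleSet:
    """Sample near-optimal flux vectors.

    Per sample, a growth rate is drawn uniformly in
    ``[growth_frac, 1] * mu_opt``, each uptake exchange gets a capacity
    drawn uniformly inside its feasible hull (spanning the optimal and
    the ``growth_frac``-growth solutions), and the LP is re-solved with
    the minimum-total-flux objective. Draws whose capacity cannot carry
    the drawn growth are re-drawn within a retry budget. Reproducible
    for a fixed seed.
    """
    if not 0 < growth_frac <= 1:
        raise ContractError("growth_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    mu_opt = maximize_growth(model).mu_star
    if mu_opt <= 0:
        raise SolveError("model does not grow; nothing to sample")
    if exchange_bounds is None:
        sol_hi = check_feasible(substitute_mu(model, mu_opt),
                                minimize_total_flux=True)
        sol_lo = check_feasible(substitute_mu(model, growth_frac * mu_opt),
                                minimize_total_flux=True)
        ex_ids = [r.id for r in model.exchanges()]
        mat = pd.DataFrame([sol_lo.fluxes[ex_ids], sol_hi.fluxes[ex_ids]])
        exchange_bounds = pd.DataFrame({"lo": mat.min(axis=0),
                                        "hi": mat.max(axis=0)})
    # randomize uptake capacities only; export capacity stays free
    uptakes = exchange_bounds[exchange_bounds["lo"] < 0]
    rows = []
    for _ in range(n):
        for attempt in range(max_retries):
            mu = mu_opt * rng.uniform(growth_frac, 1.0)
            variant = model.copy()
            for rid, (lo, hi) in uptakes.iterrows():
                draw = rng.uniform(lo, min(hi, 0.0))
                variant.reactions[rid].lower_bound = MuCoefficient(draw, 0.0)
            sol = check_feasible(substitute_mu(variant, mu),
                                 minimize_total_flux=True)
            if sol.feasible:
                rows.append(sol.fluxes.rename(len(rows)))
                break
        else:
            binding = ", ".join(uptakes.index[:5])
            raise SolveError(
                f"sampling failed after {max_retries} draws "
                f"(binding exchanges among: {binding})")
    return SampleSet(pd.DataFrame(rows),
                     {"growth_frac": growth_frac, "mu_opt": mu_opt}, seed)


def sample_overexpression(model: MEModel, mu_fixed: float,
                          secretion_lo: float, secretion_hi: float,
                          secretion_reaction: Optional[str] = None,
                          n: int = 100, seed: int = 0) -> SampleSet:
    """Sample the forced-overexpression space at a fixed growth rate.

    Growth is pinned at ``mu_fixed`` and the secretion flux is forced to
    a uniform draw in ``[secretion_lo, secretion_hi]`` per sample.
    """
    if secretion_reaction is None:
        secretion_reaction = model.motifs.get("secretion_reaction")
    if not secretion_reaction or secretion_reaction not in model.reactions:
        raise ContractError("no secretion reaction identified")
    rng = np.random.default_rng(seed)
    probe = model.copy()
    _force(probe, secretion_reaction, secretion_lo, secretion_lo)
    if not check_feasible(substitute_mu(probe, mu_fixed)).feasible:
        raise SolveError(
            f"infeasible at mu={mu_fixed} with secretion {secretion_lo}")
    rows = []
    for _ in range(n):
        s = rng.uniform(secretion_lo, secretion_hi)
        variant = model.copy()
        _force(variant, secretion_reaction, s, s)
        sol = check_feasible(substitute_mu(variant, mu_fixed),
                             minimize_total_flux=True)
        if not sol.feasible:
            hi_ok = _max_feasible_secretion(model, mu_fixed,
                                            secretion_reaction,
                                            secretion_lo, secretion_hi)
            raise SolveError(
                f"secretion {s:.4g} infeasible at mu={mu_fixed}; maximum "
                f"feasible secretion is in [{hi_ok[0]:.4g}, {hi_ok[1]:.4g}]")
        rows.append(sol.fluxes.rename(len(rows)))
    return SampleSet(pd.DataFrame(rows),
                     {"mu_fixed": mu_fixed, "secretion_reaction": secretion_reaction,
                      "secretion_range": (secretion_lo, secretion_hi)}, seed)


def _max_feasible_secretion(model, mu, rid, lo, hi, iters=30):
    a, b = lo, hi
    for _ in range(iters):
        mid = 0.5 * (a + b)
        variant = model.copy()
        _force(variant, rid, mid, mid)
        if check_feasible(substitute_mu(variant, mu)).feasible:
            a = mid
        else:
            b = mid
    return a, b


# ---------------------------------------------------------------------------
# PCA over sampled fluxes


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # reactions x components
    variance_fractions: np.ndarray
    scores: pd.DataFrame            # samples x components
    subsystem_loadings: pd.DataFrame  # mean |loading| per subsystem


def pca_fluxes(samples: SampleSet, model: Optional[MEModel] = None,
               n_components: int = 2) -> PCAResult:
    """Z-score the sampled fluxes and decompose with PCA.

    Constant-flux reactions are dropped before scaling; loadings are the
    orthonormal principal axes, and with a model the mean absolute
    loading per subsystem is reported.
    """
    if samples.n < 3:
        raise ContractError("need at least 3 samples")
    X = samples.fluxes
    sd = X.std(axis=0, ddof=0)
    keep = sd[sd > 1e-12].index
    if len(keep) < 2:
        raise ContractError("fewer than 2 non-constant reactions")
    Z = (X[keep] - X[keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=min(n_components, len(keep), samples.n - 1))
    scores = pca.fit_transform(Z.values)
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    loadings = pd.DataFrame(pca.components_.T, index=keep, columns=comp_names)
    subsystem = pd.DataFrame()
    if model is not None:
        subs = pd.Series({r: model.reactions[r].subsystem for r in keep
                          if r in model.reactions})
        subsystem = loadings.abs().groupby(subs).mean().sort_values(
            "PC1", ascending=False)
    return PCAResult(
        loadings=loadings,
        variance_fractions=pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, columns=comp_names),
        subsystem_loadings=subsystem,
    )


# ---------------------------------------------------------------------------
# amino-acid sensitivity (overexpression response)


@dataclass
class SensitivityResult:
    x_bar_high: float
    x_bar_low: float
    r_high: float
    r_low: float
    sensitivity: float
    p_value: float
    n_high: int
    n_low: int


def _trim_outliers(values: np.ndarray, z: float = 1.96) -> np.ndarray:
    """One pass of mean +/- z*SD trimming (95% confidence by default)."""
    sd = values.std(ddof=0)
    if sd == 0:
        return values
    center = values.mean()
    keep = np.abs(values - center) <= z * sd
    return values[keep] if keep.any() else values


def sensitivity(set_low: SampleSet, set_high: SampleSet,
                synthesis_reaction: str, r_low: float, r_high: float,
                outlier_z: float = 1.96) -> SensitivityResult:
    """Flux sensitivity to secretion: (x_high - x_low)/(r_high - r_low).

    Means are taken after one pass of outlier trimming per condition,
    and a two-sided two-sample t test reports whether the synthesis-flux
    distributions differ.
    """
    if r_high == r_low:
        raise ContractError("secretion rates of the two conditions coincide")
    lo = _trim_outliers(set_low.fluxes[synthesis_reaction].to_numpy(), outlier_z)
    hi = _trim_outliers(set_high.fluxes[synthesis_reaction].to_numpy(), outlier_z)
    if len(lo) == 0 or len(hi) == 0:
        raise ContractError("outlier removal left an empty sample")
    if np.allclose(lo.std(), 0) and np.allclose(hi.std(), 0):
        p = 1.0 if np.isclose(lo.mean(), hi.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(hi, lo, equal_var=False).pvalue)
    x_hi, x_lo = float(hi.mean()), float(lo.mean())
    return SensitivityResult(
        x_bar_high=x_hi, x_bar_low=x_lo, r_high=r_high, r_low=r_low,
        sensitivity=(x_hi - x_lo) / (r_high - r_low), p_value=p,
        n_high=len(hi), n_low=len(lo),
    )


def molar_fractions(protein_sequence: str) -> pd.Series:
    """Amino-acid molar fractions of a protein sequence."""
    if not protein_sequence:
        raise ContractError("empty protein sequence")
    counts = pd.Series(list(protein_sequence)).value_counts()
    return counts / counts.sum()


def composition_vs_sensitivity(protein_sequence: str,
                               sensitivities: Mapping[str, float],
                               confidence: float = 0.95) -> dict:
    """Regress predicted sensitivity on molar fraction in the protein.

    Fits the line twice: on all amino acids, and after excluding points
    outside the ``confidence`` prediction interval of the first fit.
    """
    if len(sensitivities) < 3:
        raise ContractError("need sensitivities for at least 3 amino acids")
    frac = molar_fractions(protein_sequence)
    aas = sorted(sensitivities)
    x = np.array([frac.get(a, 0.0) for a in aas])
    y = np.array([sensitivities[a] for a in aas])
    if np.allclose(x.std(), 0):
        raise ContractError("degenerate molar-fraction variance")
    fit = stats.linregress(x, y)
    # leave-one-out prediction intervals: a point is an outlier when it
    # falls outside the interval predicted by the fit to the others
    outliers = []
    if len(x) >= 4:
        for i, aa in enumerate(aas):
            keep_i = np.arange(len(x)) != i
            xr, yr = x[keep_i], y[keep_i]
            if np.allclose(xr.std(), 0):
                continue
            f = stats.linregress(xr, yr)
            dof = len(xr) - 2
            if dof <= 0:
                continue
            resid_r = yr - (f.intercept + f.slope * xr)
            s_err = np.sqrt((resid_r ** 2).sum() / dof)
            ssx = ((xr - xr.mean()) ** 2).sum()
            half = stats.t.ppf(0.5 + confidence / 2, dof) * s_err * np.sqrt(
                1 + 1 / len(xr) + (x[i] - xr.mean()) ** 2 / ssx)
            if abs(y[i] - (f.intercept + f.slope * x[i])) > half:
                outliers.append(aa)
    keep = [a not in outliers for a in aas]
    report = {
        "slope": fit.slope, "intercept": fit.intercept,
        "r_squared": fit.rvalue ** 2, "p_value": fit.pvalue,
        "outliers": outliers,
    }
    if sum(keep) >= 3 and outliers:
        xk, yk = x[keep], y[keep]
        if not np.allclose(xk.std(), 0):
            refit = stats.linregress(xk, yk)
            report["without_outliers"] = {
                "slope": refit.slope, "intercept": refit.intercept,
                "r_squared": refit.rvalue ** 2, "p_value": refit.pvalue,
            }
    return report
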