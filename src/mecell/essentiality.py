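"""Genome-wide knockout screens and prediction scoring.

A gene is called essential when its single knockout drives the maximum
feasible growth rate to zero (below a small threshold tied to the
bisection tolerance). Predictions are scored against a truth set with
the standard confusion-matrix statistics: true positive rate, true
negative rate, false discovery rate, Matthews correlation coefficient
(with the conventional square-rooted denominator), precision, and
coverage (modeled genes over database genes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import ContractError, SolveError
from .memodel import MEModel, MuCoefficient
from .solve import (
    _feasible_at,
    knockout_gene,
    knockout_genes,
    maximize_growth,
)

ESSENTIAL = "essential"
NON_ESSENTIAL = "non_essential"


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class EssentialityScores:
    """Scores may be None when their denominator is zero (undefined)."""

    TPR: Optional[float]
    TNR: Optional[float]
    FDR: Optional[float]
    MCC: Optional[float]
    Precision: Optional[float]
    Coverage: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "TPR": self.TPR, "TNR": self.TNR, "FDR": self.FDR,
            "MCC": self.MCC, "Precision": self.Precision,
            "Coverage": self.Coverage,
        }


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den else None


def score_predictions(
    predictions: Mapping[str, str],
    truth: Mapping[str, str],
    database_size: Optional[int] = None,
    model_gene_count: Optional[int] = None,
) -> tuple[ConfusionMatrix, EssentialityScores]:
    """Confusion matrix and scores for a binary essentiality call set.

    ``predictions`` and ``truth`` map the same gene ids to
    ``"essential"`` / ``"non_essential"``. Coverage needs the database
    size (and defaults the model gene count to the prediction set).
    """
    if set(predictions) != set(truth):
        raise ContractError("prediction and truth key sets differ")
    if not predictions:
        raise ContractError("empty prediction set")
    tp = fp = tn = fn = 0
    for g, p in predictions.items():
        t = truth[g]
        if p == ESSENTIAL and t == ESSENTIAL:
            tp += 1
        elif p == ESSENTIAL and t != ESSENTIAL:
            fp += 1
        elif p != ESSENTIAL and t != ESSENTIAL:
            tn += 1
        else:
            fn += 1
    cm = ConfusionMatrix(tp, fp, tn, fn)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    scores = EssentialityScores(
        TPR=_ratio(tp, tp + fn),
        TNR=_ratio(tn, tn + fp),
        FDR=_ratio(fp, fp + tp),
        MCC=(tp * tn - fp * fn) / mcc_den if mcc_den else None,
        Precision=_ratio(tp, tp + fp),
        Coverage=_ratio(model_gene_count or len(predictions), database_size)
        if database_size else None,
    )
    return cm, scores


def essentiality_screen(model: MEModel,
                        gene_ids: Optional[Iterable[str]] = None,
                        tol: float = 1e-6,
                        exact: bool = False) -> dict[str, str]:
    """Single-knockout screen over protein-coding genes.

    A knockout is essential when no growth above ``10*tol`` is feasible.
    By default each gene costs one LP (feasibility at the threshold,
    justified by feasibility monotonicity in mu); ``exact`` re-runs the
    full bisection per knockout.
    """
    threshold = 10.0 * tol
    if gene_ids is None:
        gene_ids = sorted(model.translation_index)
    if not _feasible_at(model, threshold).feasible:
        raise SolveError("wild type does not grow; screen is undefined")
    calls: dict[str, str] = {}
    for gid in gene_ids:
        ko = knockout_gene(model, gid)
        if exact:
            grows = maximize_growth(ko, tol=tol).mu_star >= threshold
        else:
            grows = _feasible_at(ko, threshold).feasible
        calls[gid] = NON_ESSENTIAL if grows else ESSENTIAL
    return calls


def double_knockout_growth(model: MEModel, gene_a: str, gene_b: str,
                           tol: float = 1e-6) -> float:
    """Maximum growth after a simultaneous two-gene knockout."""
    return maximize_growth(knockout_genes(model, [gene_a, gene_b]),
                           tol=tol).mu_star


def carbon_screen(model: MEModel,
                  substrates: Mapping[str, str] | Iterable[str],
                  uptake_rate: float = 5.0,
                  carbon_exchanges: Optional[Iterable[str]] = None,
                  tol: float = 1e-6) -> pd.DataFrame:
    """Growth calls on single carbon substrates.

    For each substrate, every carbon-uptake exchange is closed, the
    substrate's own exchange is opened at ``uptake_rate``, and growth is
    called if the maximum feasible growth rate clears the zero
    threshold. Substrates without an exchange produce a per-row error
    and the screen continues.

    ``substrates`` maps metabolite id to exchange id, or is an iterable
    of metabolite ids whose exchanges are located by their single
    stoichiometric entry. Carbon exchanges default to all exchanges on
    carbon-containing metabolites.
    """
    if not isinstance(substrates, Mapping):
        located: dict[str, str] = {}
        for met in substrates:
            exch = [r.id for r in model.exchanges()
                    if list(r.stoichiometry) == [met]]
            located[met] = exch[0] if exch else ""
        substrates = located
    if carbon_exchanges is None:
        carbon_exchanges = [
            r.id for r in model.exchanges()
            for sp in [model.species[next(iter(r.stoichiometry))]]
            if sp.formula and sp.formula.get("C")
        ]
    rows = []
    threshold = 10.0 * tol
    for met, exch in substrates.items():
        if not exch or exch not in model.reactions:
            rows.append({"substrate": met, "exchange": exch or None,
                         "growth_rate": None, "grows": None,
                         "error": "no exchange reaction"})
            continue
        variant = model.copy()
        for rid in carbon_exchanges:
            rxn = variant.reactions[rid]
            if rxn.lower_bound.value(0.0) < 0:
                rxn.lower_bound = MuCoefficient(0.0, 0.0)
        rxn = variant.reactions[exch]
        rxn.lower_bound = MuCoefficient(-abs(uptake_rate), 0.0)
        try:
            mu = maximize_growth(variant, tol=tol).mu_star
            rows.append({"substrate": met, "exchange": exch,
                         "growth_rate": mu, "grows": mu >= threshold,
                         "error": None})
        except SolveError as exc:
            rows.append({"substrate": met, "exchange": exch,
                         "growth_rate": 0.0, "grows": False,
                         "error": str(exc)})
    return pd.DataFrame(rows).set_index("substrate")


def score_growth_calls(predicted: Mapping[str, bool],
                       reference: Mapping[str, bool]
                       ) -> tuple[ConfusionMatrix, EssentialityScores]:
    """Score substrate growth calls with the same statistics as
    essentiality (growth = positive)."""
    pred = {k: ESSENTIAL if v else NON_ESSENTIAL for k, v in predicted.items()}
    ref = {k: ESSENTIAL if v else NON_ESSENTIAL for k, v in reference.items()}
    return score_predictions(pred, ref)
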