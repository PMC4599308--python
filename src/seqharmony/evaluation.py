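"""Interface prediction from SH scores and its evaluation.

Residues whose column SH falls at or below a cut-off (0.2 by default)
are predicted to form the interface.  Predictions are compared against
the structure-derived position classes: positives are interface
residues; negatives are surface plus buried residues by default, or
surface residues only when the contrast of interest is interface vs
the rest of the solvent-accessible surface.

Threshold-free performance is the area under the ROC curve, computed by
the rank-sum (Mann-Whitney) formulation with midranks for ties, using
-SH as the predictor score (lower SH = more interface-like).
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConfusionCounts, EvalReport, PositionClass, ResidueAnnotation

Universe = Literal["all_classified", "surface_only"]

SH_CUTOFF_DEFAULT = 0.2


def predict_interface(scores: pd.DataFrame, cutoff: float = SH_CUTOFF_DEFAULT) -> set[int]:
    """Residues predicted as interface: column SH <= cutoff (inclusive).

    Columns with no defined SH or no query residue are never predicted.
    """
    mask = scores["sh"].notna() & scores["query_residue_index"].notna()
    sel = scores.loc[mask & (scores["sh"] <= cutoff), "query_residue_index"]
    return {int(i) for i in sel}


def _evaluated_annotations(
    annotations: Sequence[ResidueAnnotation],
    universe: Universe,
    scored: Iterable[int] | None,
) -> list[ResidueAnnotation]:
    scored_set = None if scored is None else set(scored)
    out = []
    for a in annotations:
        if a.position_class is None:
            raise ValueError(
                f"residue {a.residue_index} not classified; classify annotations first"
            )
        if scored_set is not None and a.residue_index not in scored_set:
            continue
        if universe == "surface_only" and a.position_class is PositionClass.BURIED:
            continue
        out.append(a)
    return out


def confusion(
    predicted: set[int],
    annotations: Sequence[ResidueAnnotation],
    universe: Universe = "all_classified",
    scored: Iterable[int] | None = None,
) -> ConfusionCounts:
    """Confusion counts over residues that are annotated (and scored).

    ``scored`` optionally restricts the evaluated universe to residues
    for which an SH score exists; predicted residues must be a subset
    of the annotated ones.
    """
    evaluated = _evaluated_annotations(annotations, universe, scored)
    stray = predicted - {a.residue_index for a in annotations}
    if stray:
        raise ValueError(f"predicted residues outside annotated set: {sorted(stray)}")
    counts = ConfusionCounts()
    for a in evaluated:
        is_pos = a.position_class is PositionClass.INTERFACE
        is_pred = a.residue_index in predicted
        if is_pos and is_pred:
            counts.tp += 1
        elif is_pos:
            counts.fn += 1
        elif is_pred:
            counts.fp += 1
        else:
            counts.tn += 1
    return counts


def metrics(counts: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(recall, false-positive rate, precision); None where undefined."""
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    fpr = counts.fp / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    return recall, fpr, precision


def auc_rank_sum(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank-sum formulation with midranks.

    Equals the probability that a random positive outranks a random
    negative, ties counting one half; identical to the trapezoidal area
    under the ROC curve.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    n_p, n_n = len(pos), len(neg)
    return float((r_pos - n_p * (n_p + 1) / 2) / (n_p * n_n))


def roc_auc(
    scores: pd.DataFrame,
    annotations: Sequence[ResidueAnnotation],
    universe: Universe = "all_classified",
) -> float | None:
    """AUC of interface prediction over the evaluated residues.

    The predictor score is -SH (lower SH ranks higher).  Returns
    ``None`` when the evaluated set lacks positives or negatives.
    """
    sh_of = {
        int(r["query_residue_index"]): float(r["sh"])
        for _, r in scores.iterrows()
        if not pd.isna(r["query_residue_index"]) and not pd.isna(r["sh"])
    }
    evaluated = _evaluated_annotations(annotations, universe, scored=sh_of)
    pos = [-sh_of[a.residue_index] for a in evaluated
           if a.position_class is PositionClass.INTERFACE]
    neg = [-sh_of[a.residue_index] for a in evaluated
           if a.position_class is not PositionClass.INTERFACE]
    if not pos or not neg:
        return None
    return auc_rank_sum(np.array(pos), np.array(neg))


def evaluate_group(
    group_id: str,
    scores: pd.DataFrame,
    annotations: Sequence[ResidueAnnotation],
    cutoff: float = SH_CUTOFF_DEFAULT,
    universe: Universe = "all_classified",
) -> EvalReport:
    """Full per-group evaluation: confusion, point metrics, AUC, means."""
    from .scoring import mean_scores_by_class

    scored = {
        int(r["query_residue_index"])
        for _, r in scores.iterrows()
        if not pd.isna(r["query_residue_index"]) and not pd.isna(r["sh"])
    }
    predicted = predict_interface(scores, cutoff) & scored
    counts = confusion(predicted, annotations, universe, scored=scored)
    recall, fpr, precision = metrics(counts)
    auc = roc_auc(scores, annotations, universe)
    try:
        class_means = {
            cls.value: means
            for cls, means in mean_scores_by_class(scores, list(annotations)).items()
        }
    except LookupError:
        class_means = {}
    return EvalReport(
        group_id=group_id,
        counts=counts,
        recall=recall,
        fpr=fpr,
        precision=precision,
        auc=auc,
        n_evaluated=counts.tp + counts.fp + counts.tn + counts.fn,
        class_means=class_means,
    )


def aggregate(reports: Sequence[EvalReport]) -> dict:
    """Aggregate per-group reports into one summary.

    Mean AUC is taken over groups with a defined AUC (the number of
    excluded groups is reported); per-class mean entropy and SH are
    averaged across the groups in which the class occurs.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    aucs = [r.auc for r in reports if r.auc is not None]
    summary: dict = {
        "n_groups": len(reports),
        "n_auc_undefined": len(reports) - len(aucs),
        "mean_auc": float(np.mean(aucs)) if aucs else None,
        "class_means": {},
    }
    per_class: dict[str, dict[str, list[float]]] = {}
    for r in reports:
        for cls, means in r.class_means.items():
            bucket = per_class.setdefault(cls, {})
            for key, val in means.items():
                bucket.setdefault(key, []).append(val)
    summary["class_means"] = {
        cls: {k: float(np.mean(v)) for k, v in vals.items()}
        for cls, vals in sorted(per_class.items())
    }
    return summary


def class_difference_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample two-sided Student's t-test on per-group class means.

    Pooled-variance by default (``welch=True`` switches to Welch).
    Degenerate inputs: zero variance in both samples yields p = 1 for
    equal means and p = 0 for unequal means.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
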