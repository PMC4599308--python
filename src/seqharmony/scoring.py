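"""Per-column conservation and specificity scoring.

For each alignment column, amino-acid frequencies are computed
separately in the interacting (H) and non-interacting (M) subgroups.
Two column statistics are derived:

* Shannon entropy ``S_i = -sum_x p_{i,x} log2 p_{i,x}`` per subgroup,
  the classical conservation measure (low entropy = conserved);
* Sequence Harmony

  ``SH_i = -1/2 sum_x p^H log2[p^H / (p^H + p^M)]
           -1/2 sum_x p^M log2[p^M / (p^H + p^M)]``

  which measures compositional *overlap* between the two groups at a
  position.  SH = 0 means no residue type co-occurs in the two groups
  (complete specificity); SH = 1 means identical compositions (complete
  overlap).  Base-2 logarithms are forced by that normalisation: with
  p^H = p^M every log term equals log(1/2), so the -1/2 prefactors
  yield exactly 1 only in base 2.

Low-SH columns are the interface candidates: positions where the
interacting and non-interacting homologs have diverged in composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import (
    AA_INDEX,
    AMINO_ACIDS,
    AlignedGroup,
    GAP,
    InteractionClass,
    PositionClass,
    ResidueAnnotation,
)

MAX_ENTROPY = float(np.log2(len(AMINO_ACIDS)))  # log2(20)


@dataclass
class ColumnProfile:
    """Amino-acid composition of one column, per subgroup.

    Frequency vectors run over the 20 canonical amino acids in the
    fixed :data:`~seqharmony.types.AMINO_ACIDS` order; gaps and X are
    excluded from the counts.  A subgroup with no countable residue at
    the column yields an all-zero vector and ``n_ungapped == 0``.
    """

    column_index: int
    freq_H: np.ndarray
    freq_M: np.ndarray
    n_ungapped_H: int
    n_ungapped_M: int

    @property
    def empty_H(self) -> bool:
        return self.n_ungapped_H == 0

    @property
    def empty_M(self) -> bool:
        return self.n_ungapped_M == 0


def _column_freq(rows: Iterable[str], column: int) -> tuple[np.ndarray, int]:
    counts = np.zeros(len(AMINO_ACIDS))
    n = 0
    for seq in rows:
        aa = seq[column]
        idx = AA_INDEX.get(aa)
        if idx is None:  # gap or X
            continue
        counts[idx] += 1
        n += 1
    if n:
        counts /= n
    return counts, n


def column_profile(group: AlignedGroup, column: int) -> ColumnProfile:
    """Composition of one column in each subgroup separately."""
    if not 0 <= column < group.n_columns:
        raise IndexError(
            f"column {column} out of range [0, {group.n_columns})"
        )
    freq_H, n_H = _column_freq(group.rows_of(InteractionClass.HOMODIMER), column)
    freq_M, n_M = _column_freq(group.rows_of(InteractionClass.MONOMER), column)
    return ColumnProfile(column, freq_H, freq_M, n_H, n_M)


def entropy(freq: np.ndarray) -> float:
    """Shannon entropy of a composition vector, in bits.

    ``0 * log 0`` counts as 0; the result lies in ``[0, log2 20]``.
    """
    freq = np.asarray(freq, dtype=float)
    total = freq.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequency vector sums to {total}, not 1")
    p = freq[freq > 0]
    return float(-(p * np.log2(p)).sum())


def sh_score(freq_H: np.ndarray, freq_M: np.ndarray) -> float:
    """Sequence Harmony overlap between two composition vectors.

    Returns a value in [0, 1]: 0 for disjoint support, 1 for identical
    compositions.  Terms with ``p = 0`` contribute nothing, as do
    residue types absent from both groups.
    """
    pH = np.asarray(freq_H, dtype=float)
    pM = np.asarray(freq_M, dtype=float)
    for name, p in (("H", pH), ("M", pM)):
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"group {name} profile sums to {p.sum()}, not 1")
    total = pH + pM
    sh = 0.0
    for p in (pH, pM):
        mask = p > 0
        sh += -0.5 * float((p[mask] * np.log2(p[mask] / total[mask])).sum())
    # clamp tiny numerical excursions outside [0, 1]
    if -1e-9 <= sh < 0.0:
        sh = 0.0
    elif 1.0 < sh <= 1.0 + 1e-9:
        sh = 1.0
    return sh


def score_group(group: AlignedGroup) -> pd.DataFrame:
    """Score every column of a labelled alignment.

    Returns one row per column with columns ``column_index``,
    ``query_residue_index`` (1-based position in the ungapped query,
    NA where the query row has a gap), ``query_aa``, ``n_H``, ``n_M``,
    ``entropy_H``, ``entropy_M`` and ``sh``.  Columns where either
    subgroup has no countable residue get NA scores for the undefined
    quantities and are excluded from prediction and evaluation
    downstream.
    """
    query_seq = group.query_row
    rows = []
    residue_counter = 0
    for col in range(group.n_columns):
        prof = column_profile(group, col)
        q_aa = query_seq[col]
        if q_aa != GAP:
            residue_counter += 1
            q_idx: float | None = residue_counter
        else:
            q_idx = None
        ent_H = entropy(prof.freq_H) if not prof.empty_H else np.nan
        ent_M = entropy(prof.freq_M) if not prof.empty_M else np.nan
        sh = (
            sh_score(prof.freq_H, prof.freq_M)
            if not (prof.empty_H or prof.empty_M)
            else np.nan
        )
        rows.append(
            {
                "column_index": col,
                "query_residue_index": q_idx,
                "query_aa": q_aa,
                "n_H": prof.n_ungapped_H,
                "n_M": prof.n_ungapped_M,
                "entropy_H": ent_H,
                "entropy_M": ent_M,
                "sh": sh,
            }
        )
    return pd.DataFrame(rows)


def mean_scores_by_class(
    scores: pd.DataFrame,
    annotations: list[ResidueAnnotation],
) -> dict[PositionClass, dict[str, float]]:
    """Mean entropy and SH per structural position class.

    Score rows are joined to annotations on ``query_residue_index``;
    rows without a matching annotation (or without a defined SH) are
    dropped.  Raises ``LookupError`` when nothing joins.
    """
    by_index: Mapping[int, ResidueAnnotation] = {
        a.residue_index: a for a in annotations
    }
    buckets: dict[PositionClass, dict[str, list[float]]] = {}
    for _, row in scores.iterrows():
        if pd.isna(row["query_residue_index"]) or pd.isna(row["sh"]):
            continue
        ann = by_index.get(int(row["query_residue_index"]))
        if ann is None or ann.position_class is None:
            continue
        b = buckets.setdefault(
            ann.position_class, {"entropy_H": [], "sh": []}
        )
        if not pd.isna(row["entropy_H"]):
            b["entropy_H"].append(float(row["entropy_H"]))
        b["sh"].append(float(row["sh"]))
    if not buckets:
        raise LookupError("no scored column matches any classified annotation")
    return {
        cls: {k: float(np.mean(v)) for k, v in vals.items() if v}
        for cls, vals in buckets.items()
    }
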