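"""Prediction cut-off, confusion counts, metrics, AUC, aggregation."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqharmony import evaluation
from seqharmony.types import ConfusionCounts, EvalReport, PositionClass, ResidueAnnotation


def scores_df(sh_by_residue: dict[int, float]) -> pd.DataFrame:
    rows = []
    for i, (res, sh) in enumerate(sorted(sh_by_residue.items())):
        rows.append(
            {
                "column_index": i,
                "query_residue_index": float(res),
                "query_aa": "A",
                "n_H": 5,
                "n_M": 5,
                "entropy_H": 1.0,
                "entropy_M": 1.0,
                "sh": sh,
            }
        )
    return pd.DataFrame(rows)


def annotations_for(classes: dict[int, PositionClass]) -> list[ResidueAnnotation]:
    anns = []
    for res, cls in sorted(classes.items()):
        asa, bsa = {
            PositionClass.INTERFACE: (30.0, 10.0),
            PositionClass.SURFACE: (30.0, 0.0),
            PositionClass.BURIED: (0.0, 0.0),
        }[cls]
        a = ResidueAnnotation(res, "A", asa, bsa)
        a.position_class = cls
        anns.append(a)
    return anns


class TestPredictInterface:
    def test_cutoff_inclusive(self):
        df = scores_df({1: 0.15, 2: 0.2, 3: 0.25})
        assert evaluation.predict_interface(df, 0.2) == {1, 2}

    def test_extreme_cutoffs(self):
        df = scores_df({1: 0.15, 2: 0.2, 3: 0.25})
        assert evaluation.predict_interface(df, 0.0) == set()
        assert evaluation.predict_interface(df, 1.0) == {1, 2, 3}

    def test_undefined_sh_never_predicted(self):
        df = scores_df({1: 0.1, 2: 0.1})
        df.loc[df["query_residue_index"] == 2, "sh"] = np.nan
        assert evaluation.predict_interface(df, 0.2) == {1}


class TestConfusionAndMetrics:
    def test_phosphatase_worked_example_counts(self):
        """85 predicted positions, 21 of 31 interface sites correct."""
        classes = {}
        for r in range(1, 32):
            classes[r] = PositionClass.INTERFACE
        for r in range(32, 263):
            classes[r] = PositionClass.SURFACE
        predicted = set(range(1, 22)) | set(range(32, 96))  # 21 TP + 64 FP
        counts = evaluation.confusion(predicted, annotations_for(classes))
        assert (counts.tp, counts.fn, counts.fp) == (21, 10, 64)
        recall, fpr, precision = evaluation.metrics(counts)
        assert recall == pytest.approx(21 / 31)
        assert precision == pytest.approx(21 / 85)
        assert fpr == pytest.approx(64 / 231)

    def test_empty_prediction(self):
        counts = evaluation.confusion(
            set(), annotations_for({1: PositionClass.INTERFACE, 2: PositionClass.SURFACE})
        )
        assert (counts.tp, counts.fp) == (0, 0)
        recall, fpr, precision = evaluation.metrics(counts)
        assert precision is None and recall == 0.0

    def test_perfect_prediction(self):
        classes = {1: PositionClass.INTERFACE, 2: PositionClass.SURFACE,
                   3: PositionClass.BURIED}
        counts = evaluation.confusion({1}, annotations_for(classes))
        assert (counts.fp, counts.fn) == (0, 0)
        recall, fpr, _ = evaluation.metrics(counts)
        assert recall == 1.0 and fpr == 0.0

    def test_surface_only_universe_drops_buried(self):
        classes = {1: PositionClass.INTERFACE, 2: PositionClass.SURFACE,
                   3: PositionClass.BURIED}
        counts = evaluation.confusion({3}, annotations_for(classes), "surface_only")
        assert counts.tp + counts.fp + counts.tn + counts.fn == 2

    def test_prediction_outside_annotations_rejected(self):
        with pytest.raises(ValueError, match="outside annotated"):
            evaluation.confusion(
                {9}, annotations_for({1: PositionClass.SURFACE})
            )

    def test_unclassified_annotation_rejected(self):
        ann = ResidueAnnotation(1, "A", 30.0, 0.0)
        with pytest.raises(ValueError, match="not classified"):
            evaluation.confusion(set(), [ann])


def brute_force_auc(pos: list[float], neg: list[float]) -> float:
    """Exhaustive positive-negative pair counting (ties score 1/2)."""
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        df = scores_df({1: 0.05, 2: 0.1, 3: 0.8, 4: 0.9})
        anns = annotations_for(
            {1: PositionClass.INTERFACE, 2: PositionClass.INTERFACE,
             3: PositionClass.SURFACE, 4: PositionClass.BURIED}
        )
        assert evaluation.roc_auc(df, anns) == 1.0

    def test_all_tied_is_half(self):
        df = scores_df({1: 0.4, 2: 0.4, 3: 0.4})
        anns = annotations_for(
            {1: PositionClass.INTERFACE, 2: PositionClass.SURFACE,
             3: PositionClass.SURFACE}
        )
        assert evaluation.roc_auc(df, anns) == 0.5

    def test_single_class_undefined(self):
        df = scores_df({1: 0.1, 2: 0.2})
        anns = annotations_for(
            {1: PositionClass.INTERFACE, 2: PositionClass.INTERFACE}
        )
        assert evaluation.roc_auc(df, anns) is None

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(6, 13))
            sh = np.round(rng.uniform(0, 1, size=n), 1)  # rounding makes ties
            n_pos = int(rng.integers(1, n))
            classes = {
                i + 1: (PositionClass.INTERFACE if i < n_pos else PositionClass.SURFACE)
                for i in range(n)
            }
            df = scores_df({i + 1: float(s) for i, s in enumerate(sh)})
            got = evaluation.roc_auc(df, annotations_for(classes))
            pos = [-s for s in sh[:n_pos]]
            neg = [-s for s in sh[n_pos:]]
            assert got == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        sh = rng.uniform(0, 1, size=10)
        classes = {
            i + 1: (PositionClass.INTERFACE if i % 3 == 0 else PositionClass.SURFACE)
            for i in range(10)
        }
        base = evaluation.roc_auc(
            scores_df({i + 1: float(s) for i, s in enumerate(sh)}),
            annotations_for(classes),
        )
        warped = evaluation.roc_auc(
            scores_df({i + 1: float(s**3 + 0.1 * s) for i, s in enumerate(sh)}),
            annotations_for(classes),
        )
        assert warped == pytest.approx(base, abs=1e-12)

    def test_rank_formulation_equals_trapezoid(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(8, 40))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.normal(size=n), 1)
            ours = evaluation.auc_rank_sum(s[y == 1], s[y == 0])
            assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestAggregate:
    def _report(self, gid, auc, class_means=None):
        return EvalReport(
            group_id=gid,
            counts=ConfusionCounts(1, 1, 1, 1),
            recall=0.5, fpr=0.5, precision=0.5,
            auc=auc, n_evaluated=4,
            class_means=class_means or {},
        )

    def test_mean_auc(self):
        summary = evaluation.aggregate(
            [self._report("a", 0.6), self._report("b", 0.8)]
        )
        assert summary["mean_auc"] == pytest.approx(0.7)
        assert summary["n_auc_undefined"] == 0

    def test_undefined_auc_excluded_and_counted(self):
        summary = evaluation.aggregate(
            [self._report("a", 0.6), self._report("b", None)]
        )
        assert summary["mean_auc"] == pytest.approx(0.6)
        assert summary["n_auc_undefined"] == 1

    def test_mean_bounded_by_group_aucs(self):
        aucs = [0.55, 0.6, 0.9]
        summary = evaluation.aggregate([self._report(str(i), a) for i, a in enumerate(aucs)])
        assert min(aucs) <= summary["mean_auc"] <= max(aucs)

    def test_class_missing_in_one_group(self):
        r1 = self._report("a", 0.6, {"interface": {"sh": 0.2}})
        r2 = self._report("b", 0.7, {"interface": {"sh": 0.4}, "buried": {"sh": 0.9}})
        summary = evaluation.aggregate([r1, r2])
        assert summary["class_means"]["interface"]["sh"] == pytest.approx(0.3)
        assert summary["class_means"]["buried"]["sh"] == pytest.approx(0.9)


class TestClassDifferenceTest:
    def test_identical_lists(self):
        t, p = evaluation.class_difference_test([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
        assert t == 0.0 and p == 1.0

    def test_degenerate_variance_unequal_means(self):
        t, p = evaluation.class_difference_test([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert p == 0.0 and math.isinf(t)

    def test_matches_pooled_variance_formula(self):
        a = [0.31, 0.35, 0.33, 0.40, 0.36]
        b = [0.38, 0.41, 0.37, 0.43, 0.39]
        t, p = evaluation.class_difference_test(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
            na + nb - 2
        )
        t_direct = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p_direct = 2 * stats.t.sf(abs(t_direct), na + nb - 2)
        assert t == pytest.approx(t_direct, abs=1e-12)
        assert p == pytest.approx(p_direct, abs=1e-12)

    def test_short_samples_rejected(self):
        with pytest.raises(ValueError):
            evaluation.class_difference_test([0.1], [0.2, 0.3])
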