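"""Confusion matrices with missingness, metric formulas, ROC/AUC, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicedx.evaluation import (
    ConfusionMatrix,
    JoinError,
    UndefinedMetricError,
    confusion,
    metrics,
    reconstruct_confusion,
    roc_auc,
    round4,
)


class TestConfusion:
    def test_hand_count_with_missing(self):
        calls = {"a": "positive", "b": "negative", "c": "positive", "d": "missing"}
        truth = {"a": True, "b": False, "c": False, "d": True}
        cm = confusion(calls, truth)
        assert (cm.tp, cm.tn, cm.fp, cm.fn, cm.n_missing) == (1, 1, 1, 0, 1)
        assert cm.n_total == 4

    def test_all_missing(self):
        cm = confusion({"a": "missing", "b": "missing"}, {"a": True, "b": False})
        assert cm.n_scored == 0 and cm.n_missing == cm.n_total == 2

    def test_join_error_lists_offenders(self):
        with pytest.raises(JoinError, match="only"):
            confusion({"a": "positive"}, {"b": True})

    def test_partition_invariant(self, small_bundle):
        from splicedx.pipeline import benchmark_predictors

        bench = benchmark_predictors(small_bundle.tool_scores, small_bundle.truth)
        for cm in bench.confusions.values():
            assert cm.tp + cm.fp + cm.tn + cm.fn + cm.n_missing == cm.n_total


class TestMetrics:
    def test_reconstructed_row_values(self):
        """Frozen values derived by integer search over matrices consistent
        with a published row (n=257, 85 positives, 11 missing)."""
        m = metrics(ConfusionMatrix(tp=71, fn=8, fp=14, tn=153, n_missing=11)).rounded()
        assert (m.sensitivity, m.specificity, m.accuracy, m.ppv, m.npv) == (
            0.8987, 0.9162, 0.9106, 0.8353, 0.9503,
        )

    def test_low_specificity_row(self):
        m = metrics(ConfusionMatrix(tp=76, fn=9, fp=87, tn=57, n_missing=28))
        assert m.accuracy == pytest.approx(133 / 229)
        assert round4(m.accuracy) == 0.5808

    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(tp=1, fn=0, fp=0, tn=1))
        assert (m.sensitivity, m.specificity, m.accuracy, m.ppv, m.npv) == (1, 1, 1, 1, 1)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = metrics(ConfusionMatrix(tp=0, fn=0, fp=2, tn=3))
        assert m.sensitivity is None and m.npv is not None

    @settings(max_examples=100, deadline=None)
    @given(
        tp=st.integers(0, 200), fp=st.integers(0, 200),
        tn=st.integers(0, 200), fn=st.integers(0, 200),
    )
    def test_accuracy_is_prevalence_weighted_average(self, tp, fp, tn, fn):
        """accuracy = sens * prevalence + spec * (1 - prevalence)."""
        cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
        m = metrics(cm)
        if m.sensitivity is None or m.specificity is None:
            return
        prev = (tp + fn) / cm.n_scored
        assert m.accuracy == pytest.approx(m.sensitivity * prev + m.specificity * (1 - prev))


def _auc_pair_oracle(scores, truth):
    """Mann-Whitney pair count: P(pos > neg) + 0.5 P(tie)."""
    pos = [scores[v] for v in scores if truth[v]]
    neg = [scores[v] for v in scores if not truth[v]]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        scores = {"a": 0.9, "b": 0.8, "c": 0.1, "d": 0.2}
        truth = {"a": True, "b": True, "c": False, "d": False}
        assert roc_auc(scores, truth).auc == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = {f"v{i}": float(rng.random()) for i in range(4000)}
        truth = {v: bool(rng.random() < 0.5) for v in scores}
        assert roc_auc(scores, truth).auc == pytest.approx(0.5, abs=0.03)

    def test_six_point_toy_equals_pair_count(self):
        scores = {"a": 3.0, "b": 2.0, "c": 2.0, "d": 1.5, "e": 1.0, "f": 0.5}
        truth = {"a": True, "b": True, "c": False, "d": True, "e": False, "f": False}
        rr = roc_auc(scores, truth)
        assert rr.auc == pytest.approx(_auc_pair_oracle(scores, truth))

    def test_sweep_equals_rank_oracle_and_sklearn_on_1000_toys(self):
        """Trapezoid AUC = Mann-Whitney pair count = sklearn, with ties."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(4, 15))
            scores = {f"v{i}": float(rng.integers(0, 6)) for i in range(n)}
            truth = {v: bool(rng.random() < 0.5) for v in scores}
            if len(set(truth.values())) < 2:
                continue
            rr = roc_auc(scores, truth)
            oracle = _auc_pair_oracle(scores, truth)
            assert rr.auc == pytest.approx(oracle, abs=1e-12)
            sk = roc_auc_score(
                [truth[v] for v in scores], [scores[v] for v in scores]
            )
            assert rr.auc == pytest.approx(float(sk), abs=1e-12)

    def test_monotone_points(self):
        rng = np.random.default_rng(1)
        scores = {f"v{i}": float(rng.random()) for i in range(100)}
        truth = {v: bool(rng.random() < 0.4) for v in scores}
        pts = roc_auc(scores, truth).points
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        assert all(x2 >= x1 and y2 >= y1 for (x1, y1), (x2, y2) in zip(pts, pts[1:]))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = {f"v{i}": float(rng.random()) for i in range(60)}
        truth = {v: bool(rng.random() < 0.5) for v in scores}
        warped = {v: float(np.exp(3 * s)) for v, s in scores.items()}
        assert roc_auc(scores, truth).auc == pytest.approx(roc_auc(warped, truth).auc)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc({"a": 1.0, "b": 2.0}, {"a": True, "b": True})


class TestReconstruction:
    def test_unique_matrix_from_four_metrics(self):
        sols = reconstruct_confusion(
            257, 85, 11,
            {"sensitivity": 0.8987, "specificity": 0.9162, "ppv": 0.8353, "npv": 0.9503},
        )
        (cm,) = sols
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (71, 14, 153, 8)

    def test_inconsistent_metrics_have_no_solution(self):
        with pytest.raises(ValueError, match="found 0"):
            reconstruct_confusion(
                257, 85, 11,
                {"sensitivity": 0.9999, "specificity": 0.9162, "ppv": 0.1111, "npv": 0.9503},
            )

    def test_underdetermined_search_not_unique(self):
        sols = reconstruct_confusion(257, 85, 11, {"sensitivity": 0.8987},
                                     require_unique=False)
        assert len(sols) > 1
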