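"""Benchmark thresholded predictions against experimental splicing outcomes.

Confusion matrices keep explicit missing-score bookkeeping: missing
calls are excluded from the 2x2 table but counted, so
tp + fp + tn + fn + n_missing = n_total always holds.  The five
performance metrics (sensitivity, specificity, accuracy, PPV, NPV) are
computed over scored variants only, and compared against published
values at 4-decimal half-up rounding.

``reconstruct_confusion`` inverts that computation: given a cohort size,
positive count, missing count and printed metrics it exhaustively
searches integer confusion matrices reproducing them — used to recover
the unpublished 2x2 tables behind a published benchmark row.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


class JoinError(ValueError):
    """Calls and truth labels do not match one-to-one."""


class UndefinedMetricError(ZeroDivisionError):
    """A requested metric has a zero denominator."""


def round4(x: float) -> float:
    """Half-up rounding at 4 decimals (printed-table precision)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn", "n_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.n_missing

    @property
    def n_scored(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The five performance metrics plus the missing-score rate.

    A metric whose denominator is zero is None (undefined), never 0 or NaN.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None
    missing_rate: float

    def rounded(self) -> "MetricSet":
        r = lambda v: None if v is None else round4(v)
        return MetricSet(
            r(self.sensitivity), r(self.specificity), r(self.accuracy),
            r(self.ppv), r(self.npv), round4(self.missing_rate),
        )


def confusion(calls: dict[str, str], truth: dict[str, bool]) -> ConfusionMatrix:
    """2x2 table from per-variant calls vs experimental outcomes.

    ``calls`` maps variant_id -> 'positive'/'negative'/'missing';
    ``truth`` maps variant_id -> splice-affecting.  The two must cover
    the same variants; offenders are listed in the error.
    """
    only_calls = sorted(set(calls) - set(truth))
    only_truth = sorted(set(truth) - set(calls))
    if only_calls or only_truth:
        raise JoinError(
            f"variant_id mismatch between calls and truth; "
            f"calls-only={only_calls[:10]}, truth-only={only_truth[:10]}"
        )
    tp = fp = tn = fn = miss = 0
    for vid, call in calls.items():
        affected = truth[vid]
        if call == "missing":
            miss += 1
        elif call == "positive":
            tp, fp = (tp + 1, fp) if affected else (tp, fp + 1)
        elif call == "negative":
            fn, tn = (fn + 1, tn) if affected else (fn, tn + 1)
        else:
            raise ValueError(f"bad call {call!r} for {vid}")
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn, n_missing=miss)


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Performance metrics over scored variants; missing rate over the cohort."""
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return MetricSet(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        accuracy=ratio(cm.tp + cm.tn, cm.n_scored),
        ppv=ratio(cm.tp, cm.tp + cm.fp),
        npv=ratio(cm.tn, cm.tn + cm.fn),
        missing_rate=cm.n_missing / cm.n_total if cm.n_total else 0.0,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    points: tuple[tuple[float, float], ...]  # (1 - specificity, sensitivity)
    auc: float
    n_pos: int
    n_neg: int
    thresholds: tuple[float, ...] = ()


def roc_auc(scores: dict[str, float], truth: dict[str, bool]) -> RocResult:
    """ROC by threshold sweep over unique score values; AUC by trapezoid.

    Ties are grouped (one ROC point per unique score).  Variants present
    in ``truth`` but absent from ``scores`` are excluded by the caller;
    here the two mappings must cover identical variants.  Single-class
    truth has no ROC and raises.
    """
    if set(scores) != set(truth):
        raise JoinError("scores and truth must cover the same variants")
    y = np.array([truth[v] for v in scores], dtype=bool)
    s = np.array([scores[v] for v in scores], dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: truth contains a single class")
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    points = [(0.0, 0.0)]
    thresholds = []
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        thr = s[i]
        while i < n and s[i] == thr:
            tp += int(y[i])
            fp += int(not y[i])
            i += 1
        thresholds.append(float(thr))
        points.append((fp / n_neg, tp / n_pos))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return RocResult(
        points=tuple(points), auc=auc, n_pos=n_pos, n_neg=n_neg,
        thresholds=tuple(thresholds),
    )


def overlap_variants(scores_by_tool: dict[str, dict[str, float | None]]) -> set[str]:
    """Variants carrying a non-missing score from every tool."""
    sets = [
        {v for v, x in per_tool.items() if x is not None}
        for per_tool in scores_by_tool.values()
    ]
    return set.intersection(*sets) if sets else set()


# ---------------------------------------------------------------------------
# published-row reconstruction
# ---------------------------------------------------------------------------

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "ppv", "npv")


def reconstruct_confusion(
    n_total: int,
    n_positive: int,
    n_missing: int,
    printed: dict[str, float],
    require_unique: bool = True,
) -> list[ConfusionMatrix]:
    """All integer confusion matrices consistent with printed metrics.

    The search runs over how many of the ``n_missing`` unscored variants
    are experimentally positive, then over tp and tn, keeping matrices
    whose metrics round (half-up, 4 dp) to every value in ``printed``
    (a subset of sensitivity/specificity/accuracy/ppv/npv).  With
    ``require_unique`` a non-unique solution raises.
    """
    unknown = set(printed) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metric names {sorted(unknown)}")
    n_scored = n_total - n_missing
    solutions: list[ConfusionMatrix] = []
    for miss_pos in range(0, min(n_missing, n_positive) + 1):
        pos = n_positive - miss_pos
        neg = n_scored - pos
        if neg < 0:
            continue
        tp_candidates = range(0, pos + 1)
        if "sensitivity" in printed and pos > 0:
            tp_candidates = [
                tp for tp in tp_candidates if round4(tp / pos) == printed["sensitivity"]
            ]
        for tp in tp_candidates:
            fn = pos - tp
            tn_candidates = range(0, neg + 1)
            if "specificity" in printed and neg > 0:
                tn_candidates = [
                    tn for tn in tn_candidates if round4(tn / neg) == printed["specificity"]
                ]
            for tn in tn_candidates:
                fp = neg - tn
                cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn, n_missing=n_missing)
                m = metrics(cm).rounded()
                ok = all(
                    getattr(m, name) is not None and getattr(m, name) == value
                    for name, value in printed.items()
                )
                if ok:
                    solutions.append(cm)
    if require_unique and len(solutions) != 1:
        raise ValueError(
            f"expected a unique confusion matrix, found {len(solutions)} "
            f"for printed metrics {printed}"
        )
    return solutions


def metrics_table(rows: dict[str, ConfusionMatrix]) -> pd.DataFrame:
    """One row per tool in the published column order."""
    out = []
    for tool, cm in rows.items():
        m = metrics(cm).rounded()
        out.append(
            {
                "tool": tool,
                "n_missing": cm.n_missing,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
                "ppv": m.ppv,
                "npv": m.npv,
            }
        )
    return pd.DataFrame(out)
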