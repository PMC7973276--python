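"""Single-analyte linear-threshold biomarkers with leave-one-out evaluation.

Each analyte gets a cutoff with a direction (high or low values call the
long-PFS class), chosen to maximize sensitivity + specificity over all
candidate cutoffs (midpoints between consecutive distinct values).
Performance is summarized from leave-one-out predictions as a confusion
matrix and the derived accuracy / PPV / NPV / sensitivity / specificity,
with the long-PFS outcome as the positive class throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, CohortError, group_median

__all__ = [
    "ConfusionCounts",
    "BinaryMetrics",
    "ThresholdRule",
    "AnalyteReport",
    "confusion_metrics",
    "fit_threshold",
    "loo_evaluate_single",
    "rank_sum_p",
    "analyte_table",
    "reports_to_frame",
    "round_half_away",
]

POSITIVE = "long"   # positive class: long progression-free survival
NEGATIVE = "short"

Direction = Literal["high_is_positive", "low_is_positive"]


def round_half_away(x: float) -> int:
    """Round half away from zero (89.5 -> 90, -0.5 -> -1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class BinaryMetrics:
    """Percentages in [0, 100]; ``None`` marks an undefined (0/0) entry."""

    accuracy: float | None
    ppv: float | None
    npv: float | None
    sensitivity: float | None
    specificity: float | None

    _FIELDS = ("accuracy", "ppv", "npv", "sensitivity", "specificity")

    def rounded(self) -> dict[str, int | None]:
        return {
            f: (None if getattr(self, f) is None else round_half_away(getattr(self, f)))
            for f in self._FIELDS
        }

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(f for f in self._FIELDS if getattr(self, f) is None)


def confusion_metrics(c: ConfusionCounts) -> BinaryMetrics:
    """Accuracy/PPV/NPV/sensitivity/specificity (percent) from counts.

    Zero-denominator entries come back as ``None`` rather than a
    fabricated number.
    """
    if c.n == 0:
        raise ValueError("confusion matrix with all-zero counts")

    def pct(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return BinaryMetrics(
        accuracy=pct(c.tp + c.tn, c.n),
        ppv=pct(c.tp, c.tp + c.fp),
        npv=pct(c.tn, c.tn + c.fn),
        sensitivity=pct(c.tp, c.tp + c.fn),
        specificity=pct(c.tn, c.tn + c.fp),
    )


@dataclass(frozen=True)
class ThresholdRule:
    """A cutoff with direction; boundary values call the positive class.

    ``high_is_positive`` predicts long for value >= threshold;
    ``low_is_positive`` predicts long for value <= threshold. A
    degenerate rule (all training values identical) has no usable
    cutoff and predicts the training majority class.
    """

    analyte: str | None
    threshold: float | None
    direction: Direction
    degenerate: bool = False
    majority: str = POSITIVE

    def predict(self, values: Iterable[float]) -> np.ndarray:
        """Boolean array: True where the positive (long) class is called."""
        v = np.asarray(list(values), dtype=float)
        if self.degenerate:
            return np.full(v.shape, self.majority == POSITIVE)
        if self.direction == "high_is_positive":
            return v >= self.threshold
        return v <= self.threshold


def _as_positive_mask(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr == POSITIVE


def fit_threshold(values: Sequence[float], labels: Sequence,
                  analyte: str | None = None) -> ThresholdRule:
    """Exhaustive threshold search maximizing sensitivity + specificity.

    Candidates are midpoints between consecutive distinct sorted values,
    tried in both directions. Ties are broken by higher accuracy, then
    the smaller threshold, then ``high_is_positive``.
    """
    v = np.asarray(values, dtype=float)
    pos = _as_positive_mask(labels)
    if v.shape[0] != pos.shape[0]:
        raise ValueError("values and labels differ in length")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to fit a threshold")
    distinct = np.unique(v)
    if distinct.size < 2:
        majority = POSITIVE if n_pos >= n_neg else NEGATIVE
        return ThresholdRule(analyte, None, "high_is_positive",
                             degenerate=True, majority=majority)
    mids = (distinct[:-1] + distinct[1:]) / 2.0

    # vectorized confusion over candidates x directions
    ge = v[:, None] >= mids[None, :]            # high_is_positive predictions
    best: tuple | None = None
    for direction, pred in (("high_is_positive", ge), ("low_is_positive", ~ge)):
        tp = (pred & pos[:, None]).sum(axis=0)
        tn = (~pred & ~pos[:, None]).sum(axis=0)
        sens = tp / n_pos
        spec = tn / n_neg
        acc = (tp + tn) / v.shape[0]
        for j in range(mids.size):
            key = (sens[j] + spec[j], acc[j], -mids[j],
                   1 if direction == "high_is_positive" else 0)
            if best is None or key > best[0]:
                best = (key, mids[j], direction)
    assert best is not None
    return ThresholdRule(analyte, float(best[1]), best[2])


FoldHook = Callable[[int, np.ndarray], None]


def loo_evaluate_single(
    values: Sequence[float],
    labels: Sequence,
    analyte: str | None = None,
    fold_hook: FoldHook | None = None,
) -> tuple[BinaryMetrics, ConfusionCounts, list[str]]:
    """Leave-one-out evaluation of the threshold rule.

    Each sample is predicted by a rule fit on the other n-1; the n
    predictions form the confusion matrix. A fold whose training data
    holds a single class predicts that class. ``fold_hook`` receives
    ``(left_out_index, training_indices)`` per fold, for instrumentation.
    """
    v = np.asarray(values, dtype=float)
    pos = _as_positive_mask(labels)
    n = v.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    pred = np.zeros(n, dtype=bool)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        if fold_hook is not None:
            fold_hook(i, train)
        tr_pos = pos[train]
        if tr_pos.all() or (~tr_pos).all():
            pred[i] = tr_pos.all()
            continue
        rule = fit_threshold(v[train], tr_pos, analyte)
        pred[i] = bool(rule.predict([v[i]])[0])
    counts = ConfusionCounts(
        tp=int((pred & pos).sum()),
        fn=int((~pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
    )
    classes = [POSITIVE if p else NEGATIVE for p in pred]
    return confusion_metrics(counts), counts, classes


def rank_sum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when n1 + n2 <= 25 and the pooled sample has no
    ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return 1.0  # every observation tied: no evidence either way
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= 25 and no_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    return float(res.pvalue)


@dataclass
class AnalyteReport:
    """One row of the per-analyte biomarker table."""

    analyte: str
    median_long: float
    median_short: float
    threshold: float | None
    p_value: float
    metrics: BinaryMetrics
    counts: ConfusionCounts
    loo_predictions: dict[str, str] = field(default_factory=dict)

    @property
    def accuracy(self) -> float | None:
        return self.metrics.accuracy


def analyte_table(cohort: Cohort,
                  analyte_order: Sequence[str] | None = None,
                  fold_hook: FoldHook | None = None) -> list[AnalyteReport]:
    """Per-analyte biomarker reports on the long + short samples.

    The reported threshold is fit on the full two-group data; metrics
    come from leave-one-out predictions; the p-value is a two-sided
    rank-sum test of long vs short values.
    """
    two = cohort.restrict_groups([POSITIVE, NEGATIVE])
    groups = two.groups()
    if not (groups == POSITIVE).any() or not (groups == NEGATIVE).any():
        raise CohortError("cohort must contain both long and short groups")
    labels = (groups == POSITIVE).to_numpy()
    order = list(analyte_order) if analyte_order is not None else two.analytes()
    reports = []
    for analyte in order:
        v = two.values(analyte).to_numpy(dtype=float)
        rule = fit_threshold(v, labels, analyte)
        metrics, counts, classes = loo_evaluate_single(
            v, labels, analyte, fold_hook=fold_hook)
        reports.append(
            AnalyteReport(
                analyte=analyte,
                median_long=group_median(v[labels]),
                median_short=group_median(v[~labels]),
                threshold=rule.threshold,
                p_value=rank_sum_p(v[labels], v[~labels]),
                metrics=metrics,
                counts=counts,
                loo_predictions=dict(zip(two.matrix.index, classes)),
            )
        )
    return reports


def reports_to_frame(reports: Iterable[AnalyteReport]) -> pd.DataFrame:
    """Tabular form of the analyte reports; undefined cells become '-'."""
    rows = []
    for r in reports:
        rounded = r.metrics.rounded()
        rows.append({
            "analyte": r.analyte,
            "median_long": r.median_long,
            "median_short": r.median_short,
            "threshold": "-" if r.threshold is None else r.threshold,
            "p_value": r.p_value,
            **{k: ("-" if val is None else val) for k, val in rounded.items()},
        })
    return pd.DataFrame(rows)
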