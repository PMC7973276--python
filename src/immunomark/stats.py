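"""Association statistics across ordered outcome groups.

Implements the Wilcoxon-type trend test across ordered groups (Cuzick
1985) with midranks and tie-corrected variance, Spearman rank
correlation pairs and matrices, a balanced median split, two-sample
t-tests (paired and pooled-variance unpaired), and mean fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

__all__ = [
    "TrendResult",
    "CorrPair",
    "CorrMatrix",
    "MedianSplit",
    "FoldChangeResult",
    "cuzick_trend",
    "spearman",
    "correlation_matrix",
    "median_split",
    "two_sample_t",
    "fold_change",
]


@dataclass(frozen=True)
class TrendResult:
    T: float
    z: float
    p: float
    group_scores: tuple[int, ...]
    group_sizes: tuple[int, ...]
    N: int


def cuzick_trend(values: Sequence[float], groups: Sequence,
                 order: Sequence | None = None,
                 scores: Sequence[int] | None = None) -> TrendResult:
    """Wilcoxon-type test for trend across ordered groups.

    Groups receive integer scores l_j (1, 2, ... in the stated order by
    default; for PFS groups pass ``order=("short", "intermediate",
    "long")`` so a positive z means values rise with longer PFS). With
    midranks R_i over the pooled sample, the statistic is T = sum l_i
    R_i with

        E[T]   = (N + 1) / 2 * sum n_j l_j
        Var[T] = (N + 1) / 12 * (N sum n_j l_j^2 - (sum n_j l_j)^2)

    and the variance is multiplied by the tie-correction factor
    1 - sum(t^3 - t) / (N^3 - N) over tie-group sizes t. z is referred
    to the standard normal, two-sided. A degenerate sample (all values
    tied) yields z = 0, p = 1.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape[0] != g.shape[0]:
        raise ValueError("values and groups differ in length")
    if order is None:
        order = list(dict.fromkeys(g.tolist()))
    order = list(order)
    if len(order) < 2:
        raise ValueError("need at least 2 ordered groups")
    if scores is None:
        scores = list(range(1, len(order) + 1))
    scores = [int(s) for s in scores]
    sizes = []
    l_per_obs = np.empty(v.shape[0])
    for grp, sc in zip(order, scores):
        mask = g == grp
        n_j = int(mask.sum())
        if n_j == 0:
            raise ValueError(f"empty group {grp!r}")
        sizes.append(n_j)
        l_per_obs[mask] = sc
    if sum(sizes) != v.shape[0]:
        extra = sorted(set(g.tolist()) - set(order))
        raise ValueError(f"observations in groups outside the order: {extra}")
    N = v.shape[0]
    ranks = stats.rankdata(v)  # midranks
    T = float(np.sum(l_per_obs * ranks))
    sum_nl = float(np.dot(sizes, scores))
    sum_nl2 = float(np.dot(sizes, np.square(scores)))
    ET = (N + 1) / 2.0 * sum_nl
    var = (N + 1) / 12.0 * (N * sum_nl2 - sum_nl ** 2)
    _, tie_counts = np.unique(v, return_counts=True)
    tie_factor = 1.0 - float(np.sum(tie_counts ** 3 - tie_counts)) / (N ** 3 - N)
    var *= tie_factor
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = (T - ET) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return TrendResult(T=T, z=float(z), p=float(min(p, 1.0)),
                       group_scores=tuple(scores), group_sizes=tuple(sizes), N=N)


@dataclass(frozen=True)
class CorrPair:
    r: float | None
    p: float | None
    n: int

    @property
    def undefined(self) -> bool:
        return self.r is None


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrPair:
    """Spearman rank correlation with a t-approximation p-value.

    Zero variance in either vector leaves the coefficient undefined;
    |r| = 1 reports the limiting p of 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("paired vectors differ in length")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrPair(r=None, p=None, n=n)
    rho = float(stats.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0:
        return CorrPair(r=float(np.sign(rho)), p=0.0, n=n)
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrPair(r=rho, p=float(p), n=n)


@dataclass
class CorrMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def pair(self, row: str, col: str) -> CorrPair:
        r = self.r.loc[row, col]
        p = self.p.loc[row, col]
        return CorrPair(r=None if pd.isna(r) else float(r),
                        p=None if pd.isna(p) else float(p),
                        n=int(self.n.loc[row, col]))

    def to_long(self) -> pd.DataFrame:
        rows = []
        for row in self.r.index:
            for col in self.r.columns:
                pair = self.pair(row, col)
                rows.append({"row": row, "col": col,
                             "r": "-" if pair.r is None else pair.r,
                             "p": "-" if pair.p is None else pair.p,
                             "n": pair.n})
        return pd.DataFrame(rows)


def correlation_matrix(cohort: Cohort, rows: Sequence[str],
                       cols: Sequence[str]) -> CorrMatrix:
    """All pairwise Spearman correlations between two analyte lists."""
    for a in list(rows) + list(cols):
        if a not in cohort.matrix.columns:
            raise KeyError(f"analyte {a!r} not in cohort")
    r = pd.DataFrame(index=list(rows), columns=list(cols), dtype=float)
    p = pd.DataFrame(index=list(rows), columns=list(cols), dtype=float)
    n = pd.DataFrame(index=list(rows), columns=list(cols), dtype=int)
    for a in rows:
        for b in cols:
            pair = spearman(cohort.values(a), cohort.values(b))
            r.loc[a, b] = np.nan if pair.r is None else pair.r
            p.loc[a, b] = np.nan if pair.p is None else pair.p
            n.loc[a, b] = pair.n
    return CorrMatrix(r=r, p=p, n=n)


@dataclass(frozen=True)
class MedianSplit:
    cut: float
    low_ids: tuple
    high_ids: tuple


def median_split(values: Sequence[float],
                 ids: Sequence | None = None) -> MedianSplit:
    """Split at the median into balanced low/high halves.

    Values strictly below the cut go low, strictly above go high;
    values tied with the cut are assigned in stable sorted order so the
    two halves differ in size by at most one.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 values to split")
    if ids is None:
        ids = np.arange(v.shape[0])
    ids = np.asarray(ids, dtype=object)
    cut = float(np.median(v))
    order = np.argsort(v, kind="stable")
    half = v.shape[0] // 2
    low = order[:half]
    high = order[half:]
    return MedianSplit(cut=cut, low_ids=tuple(ids[low]), high_ids=tuple(ids[high]))


def two_sample_t(a: Sequence[float], b: Sequence[float],
                 paired: bool = False) -> float:
    """Two-tailed Student t-test p-value.

    Unpaired uses the pooled-variance statistic; paired tests the
    difference scores. Degenerate zero-variance data follow the
    contract: equal means give p = 1, unequal means the limiting p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape[0] != b.shape[0] or a.shape[0] < 2:
            raise ValueError("paired test needs >= 2 pairs of equal length")
        d = a - b
        if np.allclose(d.var(ddof=1), 0.0):
            return 1.0 if np.allclose(d.mean(), 0.0) else 0.0
        return float(stats.ttest_rel(a, b).pvalue)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("unpaired test needs >= 2 per arm")
    pooled_num = (a.shape[0] - 1) * a.var(ddof=1) + (b.shape[0] - 1) * b.var(ddof=1)
    if np.allclose(pooled_num, 0.0):
        return 1.0 if np.allclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


@dataclass(frozen=True)
class FoldChangeResult:
    fold: float
    p: float


def fold_change(numerator: Sequence[float], denominator: Sequence[float],
                paired: bool = True) -> FoldChangeResult:
    """Ratio of arithmetic means with a t-test p-value on the raw values."""
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if den.mean() <= 0:
        raise ValueError("denominator mean must be positive")
    return FoldChangeResult(
        fold=float(num.mean() / den.mean()),
        p=two_sample_t(num, den, paired=paired),
    )
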