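"""Multidimensional biomarker: forest-based subset search and scoring.

The procedure mirrors a two-step model selection on a small two-group
cohort: (1) take the top-k single-analyte biomarkers ranked by
leave-one-out accuracy then p-value, train a random forest on every
non-empty subset of them, and keep the subset with the lowest
leave-one-out misclassification count (ties prefer more analytes);
(2) grid-search forest hyperparameters on the chosen subset, again by
leave-one-out error. The final model's per-sample score is
``s = P(short) - P(long)`` (tree vote fractions), so the long-PFS group
sits at negative scores and the decision threshold is 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cohort import Cohort
from .thresholds import (
    NEGATIVE,
    POSITIVE,
    AnalyteReport,
    BinaryMetrics,
    ConfusionCounts,
    confusion_metrics,
)

__all__ = [
    "ForestParams",
    "AnalyteRanking",
    "SubsetSearchResult",
    "MultidimModel",
    "RocCurve",
    "rank_analytes",
    "powerset_select",
    "grid_search",
    "default_grid",
    "score_samples",
    "roc_auc",
    "build_multidim_biomarker",
]


@dataclass(frozen=True)
class ForestParams:
    """Random-forest hyperparameters.

    ``features_per_split=None`` means floor(sqrt(n_features)), at least
    1 — the conventional default. ``n_trees=100`` follows the common
    library default for an unconfigured forest.
    """

    n_trees: int = 100
    features_per_split: int | None = None
    min_leaf: int = 1
    max_depth: int | None = None

    def resolve_features(self, n_features: int) -> int:
        if self.features_per_split is None:
            return max(1, int(np.sqrt(n_features)))
        if not 1 <= self.features_per_split <= n_features:
            raise ValueError(
                f"features_per_split={self.features_per_split} outside "
                f"[1, {n_features}]"
            )
        return self.features_per_split

    def build(self, n_features: int, random_state: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.resolve_features(n_features),
            min_samples_leaf=self.min_leaf,
            max_depth=self.max_depth,
            bootstrap=True,
            n_jobs=1,
            random_state=random_state,
        )


@dataclass(frozen=True)
class AnalyteRanking:
    analytes: tuple[str, ...]
    keys: tuple[tuple[float, float], ...]  # (accuracy, p_value) per analyte


def rank_analytes(reports: Sequence[AnalyteReport], k: int = 5) -> AnalyteRanking:
    """Top-k analytes by accuracy (descending) then p-value (ascending).

    The sort is stable, so analytes tied on both keys keep their input
    order.
    """
    if k > len(reports):
        raise ValueError(f"k={k} exceeds the number of analytes ({len(reports)})")
    order = sorted(
        reports,
        key=lambda r: (-(r.accuracy if r.accuracy is not None else -1.0), r.p_value),
    )[:k]
    return AnalyteRanking(
        analytes=tuple(r.analyte for r in order),
        keys=tuple((r.accuracy, r.p_value) for r in order),
    )


def _signed_scores(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """s = P(short) - P(long); a single-class forest votes at full strength."""
    proba = clf.predict_proba(X)
    classes = list(clf.classes_)
    p_short = proba[:, classes.index(NEGATIVE)] if NEGATIVE in classes else 0.0
    p_long = proba[:, classes.index(POSITIVE)] if POSITIVE in classes else 0.0
    return np.asarray(p_short - p_long, dtype=float).reshape(-1)


FoldHook = Callable[[int, np.ndarray], None]


def _loo_scores(X: np.ndarray, y: np.ndarray, params: ForestParams,
                master_seed: int, fold_hook: FoldHook | None = None) -> np.ndarray:
    """Leave-one-out signed scores; per-fold forest seeded master+fold."""
    n = X.shape[0]
    scores = np.zeros(n)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        if fold_hook is not None:
            fold_hook(i, train)
        clf = params.build(X.shape[1], random_state=master_seed + i)
        clf.fit(X[train], y[train])
        scores[i] = _signed_scores(clf, X[i:i + 1])[0]
    return scores


def _loo_error(X: np.ndarray, y: np.ndarray, params: ForestParams,
               master_seed: int) -> tuple[int, np.ndarray]:
    scores = _loo_scores(X, y, params, master_seed)
    pred = np.where(scores < 0, POSITIVE, NEGATIVE)
    return int((pred != y).sum()), scores


@dataclass
class SubsetSearchResult:
    chosen: tuple[str, ...]
    loo_errors: dict[tuple[str, ...], int]


def powerset_select(cohort: Cohort, candidates: Sequence[str],
                    defaults: ForestParams | None = None,
                    master_seed: int = 0) -> SubsetSearchResult:
    """Exhaustive subset search over the candidate analytes.

    Every non-empty subset is scored by leave-one-out misclassification
    count with default-hyperparameter forests. The minimum-error subset
    wins; ties prefer more analytes, then (deterministically) the subset
    whose members rank higher in the candidate order.
    """
    if not 1 <= len(candidates) <= 8:
        raise ValueError("candidate set must hold 1..8 analytes")
    defaults = defaults or ForestParams()
    two = cohort.restrict_groups([POSITIVE, NEGATIVE])
    y = two.groups().to_numpy(dtype=object)
    errors: dict[tuple[str, ...], int] = {}
    best_key: tuple | None = None
    chosen: tuple[str, ...] = ()
    idx = range(len(candidates))
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(idx, size):
            subset = tuple(candidates[i] for i in combo)
            X = two.matrix[list(subset)].to_numpy(dtype=float)
            err, _ = _loo_error(X, y, defaults, master_seed)
            errors[subset] = err
            key = (err, -size, combo)  # min error, then max size, then rank order
            if best_key is None or key < best_key:
                best_key, chosen = key, subset
    return SubsetSearchResult(chosen=chosen, loo_errors=errors)


def default_grid(subset_size: int) -> list[ForestParams]:
    """Desk-scale exhaustive hyperparameter grid for the chosen subset."""
    grid = []
    for n_trees in (100, 300):
        for mtry in range(1, subset_size + 1):
            for min_leaf in (1, 2):
                for max_depth in (None, 3):
                    grid.append(ForestParams(n_trees, mtry, min_leaf, max_depth))
    return grid


@dataclass
class MultidimModel:
    """Final multidimensional biomarker with its LOO evaluation."""

    subset: tuple[str, ...]
    params: ForestParams
    estimator: RandomForestClassifier
    sample_ids: tuple[str, ...]
    loo_scores: np.ndarray          # signed scores in [-1, 1]
    loo_classes: tuple[str, ...]    # long iff score < 0
    counts: ConfusionCounts
    metrics: BinaryMetrics
    grid_errors: dict[int, int] = field(default_factory=dict)
    decision_threshold: float = 0.0


def grid_search(cohort: Cohort, subset: Sequence[str],
                grid: Sequence[ForestParams] | None = None,
                master_seed: int = 0) -> MultidimModel:
    """Pick the grid point with the lowest leave-one-out error.

    Ties go to the earliest grid point. The final model is refit on all
    two-group samples; reported per-sample scores are the winning grid
    point's leave-one-out fold scores.
    """
    subset = tuple(subset)
    two = cohort.restrict_groups([POSITIVE, NEGATIVE])
    X = two.matrix[list(subset)].to_numpy(dtype=float)
    y = two.groups().to_numpy(dtype=object)
    if grid is None:
        grid = default_grid(len(subset))
    if not grid:
        raise ValueError("empty hyperparameter grid")
    grid_errors: dict[int, int] = {}
    best_i, best_err, best_scores = 0, None, None
    for i, params in enumerate(grid):
        err, scores = _loo_error(X, y, params, master_seed)
        grid_errors[i] = err
        if best_err is None or err < best_err:
            best_i, best_err, best_scores = i, err, scores
    winner = grid[best_i]
    final = winner.build(X.shape[1], random_state=master_seed)
    final.fit(X, y)
    assert best_scores is not None
    pred = np.where(best_scores < 0, POSITIVE, NEGATIVE)
    pos = y == POSITIVE
    called_pos = pred == POSITIVE
    counts = ConfusionCounts(
        tp=int((called_pos & pos).sum()),
        fn=int((~called_pos & pos).sum()),
        fp=int((called_pos & ~pos).sum()),
        tn=int((~called_pos & ~pos).sum()),
    )
    return MultidimModel(
        subset=subset,
        params=winner,
        estimator=final,
        sample_ids=tuple(two.matrix.index),
        loo_scores=best_scores,
        loo_classes=tuple(pred),
        counts=counts,
        metrics=confusion_metrics(counts),
        grid_errors=grid_errors,
    )


def score_samples(model: MultidimModel, cohort: Cohort) -> pd.DataFrame:
    """Signed score and class call for every cohort sample."""
    missing = [a for a in model.subset if a not in cohort.matrix.columns]
    if missing:
        raise KeyError(f"cohort lacks model analytes: {missing}")
    X = cohort.matrix[list(model.subset)].to_numpy(dtype=float)
    s = _signed_scores(model.estimator, X)
    return pd.DataFrame(
        {"score": s, "class": np.where(s < 0, POSITIVE, NEGATIVE)},
        index=cohort.matrix.index,
    )


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence) -> RocCurve:
    """ROC over a threshold sweep; the short-PFS class (higher score) is
    treated as positive; AUC by trapezoidal integration."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == NEGATIVE if y.dtype != bool else y
    if pos.all() or (~pos).all():
        raise ValueError("ROC needs both classes")
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    tpr = [(s[pos] >= t).mean() for t in thresholds]
    fpr = [(s[~pos] >= t).mean() for t in thresholds]
    fpr_arr, tpr_arr = np.asarray(fpr), np.asarray(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocCurve(fpr=fpr_arr, tpr=tpr_arr, auc=auc)


def build_multidim_biomarker(
    cohort: Cohort,
    reports: Sequence[AnalyteReport],
    top_k: int = 5,
    defaults: ForestParams | None = None,
    grid: Sequence[ForestParams] | None = None,
    master_seed: int = 0,
) -> tuple[AnalyteRanking, SubsetSearchResult, MultidimModel, RocCurve]:
    """Full two-step construction: rank, subset search, grid search, ROC."""
    ranking = rank_analytes(reports, k=top_k)
    search = powerset_select(cohort, ranking.analytes, defaults, master_seed)
    model = grid_search(cohort, search.chosen, grid, master_seed)
    two = cohort.restrict_groups([POSITIVE, NEGATIVE])
    roc = roc_auc(model.loo_scores, two.groups().to_numpy(dtype=object))
    return ranking, search, model, roc
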