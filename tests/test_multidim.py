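"""Multidimensional forest biomarker: ranking, subset search, scoring."""

import numpy as np
import pytest
from scipy import stats

from immunomark.multidim import (
    ForestParams,
    _loo_scores,
    grid_search,
    powerset_select,
    rank_analytes,
    roc_auc,
    score_samples,
)
from immunomark.thresholds import AnalyteReport, BinaryMetrics, ConfusionCounts
from tests.conftest import make_two_group_cohort

FAST = ForestParams(n_trees=25)


def _report(analyte, accuracy, p):
    m = BinaryMetrics(accuracy, None, None, None, None)
    return AnalyteReport(analyte, 0, 0, 0, p, m, ConfusionCounts(1, 0, 0, 1))


def _separable_cohort(rng, n_long=7, n_short=5, n_noise=2):
    sig = np.concatenate([rng.normal(3, 0.3, n_long), rng.normal(0, 0.3, n_short)])
    cols = {"signal": np.exp(sig)}
    for i in range(n_noise):
        cols[f"noise{i}"] = np.exp(rng.normal(size=n_long + n_short))
    return make_two_group_cohort(cols, n_long, n_short)


# -- ranking -------------------------------------------------------------------

def test_rank_analytes_orders_by_accuracy_then_p():
    reports = [_report("a", 70, 0.5), _report("b", 90, 0.2),
               _report("c", 70, 0.01), _report("d", 90, 0.4)]
    ranking = rank_analytes(reports, k=4)
    assert ranking.analytes == ("b", "d", "c", "a")
    assert rank_analytes([_report("only", 50, 1.0)], k=1).analytes == ("only",)
    with pytest.raises(ValueError):
        rank_analytes(reports, k=9)


def test_rank_analytes_tie_on_both_keys_is_stable():
    reports = [_report("first", 80, 0.3), _report("second", 80, 0.3)]
    assert rank_analytes(reports, k=2).analytes == ("first", "second")


# -- subset search -------------------------------------------------------------

def test_powerset_keeps_planted_analyte(rng):
    cohort = _separable_cohort(rng)
    res = powerset_select(cohort, ["signal", "noise0", "noise1"],
                          defaults=FAST, master_seed=3)
    assert "signal" in res.chosen
    assert len(res.loo_errors) == 7
    assert res.loo_errors[res.chosen] == min(res.loo_errors.values())


def test_powerset_tie_prefers_more_analytes(rng):
    # two strongly separating analytes: every subset containing either
    # reaches zero error, so the full set must win the tie
    sig1 = np.exp(np.concatenate([rng.normal(4, 0.2, 7), rng.normal(0, 0.2, 5)]))
    sig2 = np.exp(np.concatenate([rng.normal(4, 0.2, 7), rng.normal(0, 0.2, 5)]))
    cohort = make_two_group_cohort({"s1": sig1, "s2": sig2}, 7, 5)
    res = powerset_select(cohort, ["s1", "s2"], defaults=FAST, master_seed=0)
    errors = res.loo_errors
    assert errors[("s1",)] == errors[("s2",)] == errors[("s1", "s2")] == 0
    assert res.chosen == ("s1", "s2")


def test_powerset_pure_noise_has_high_error(rng):
    cols = {f"n{i}": np.exp(rng.normal(size=19)) for i in range(3)}
    cohort = make_two_group_cohort(cols, 11, 8)
    res = powerset_select(cohort, list(cols), defaults=FAST, master_seed=1)
    # minority class has 8 members; noise-only models stay near that error
    assert res.loo_errors[res.chosen] >= 4


def test_powerset_determinism(rng):
    cohort = _separable_cohort(rng)
    a = powerset_select(cohort, ["signal", "noise0"], defaults=FAST, master_seed=7)
    b = powerset_select(cohort, ["signal", "noise0"], defaults=FAST, master_seed=7)
    assert a.chosen == b.chosen
    assert a.loo_errors == b.loo_errors


# -- grid search and scoring ---------------------------------------------------

def test_grid_single_point_and_tie_rules(rng):
    cohort = _separable_cohort(rng)
    single = [ForestParams(n_trees=25, min_leaf=2)]
    model = grid_search(cohort, ("signal",), grid=single, master_seed=0)
    assert model.params == single[0]

    flat = make_two_group_cohort({"flat": np.full(12, 3.0)}, 7, 5)
    grid = [ForestParams(n_trees=25), ForestParams(n_trees=25, min_leaf=2)]
    model = grid_search(flat, ("flat",), grid=grid, master_seed=0)
    assert model.params == grid[0]  # all tie -> earliest grid point

    with pytest.raises(ValueError):
        grid_search(cohort, ("signal",), grid=[], master_seed=0)


def test_grid_search_separable_reaches_zero_error(rng):
    cohort = _separable_cohort(rng)
    model = grid_search(cohort, ("signal",),
                        grid=[ForestParams(n_trees=25)], master_seed=0)
    assert min(model.grid_errors.values()) == 0
    assert model.metrics.rounded()["accuracy"] == 100


def test_loo_scores_in_range_and_fold_purity(rng):
    cohort = _separable_cohort(rng)
    X = cohort.matrix[["signal"]].to_numpy()
    y = cohort.groups().to_numpy(dtype=object)
    seen = []
    scores = _loo_scores(X, y, FAST, 0, fold_hook=lambda i, tr: seen.append((i, tr)))
    assert np.all(scores >= -1) and np.all(scores <= 1)
    for i, train in seen:
        assert i not in train and train.size == X.shape[0] - 1


def test_score_sign_convention(rng):
    """Long-group scores sit below 0, short-group above, on planted data."""
    cohort = _separable_cohort(rng, n_long=8, n_short=6, n_noise=0)
    model = grid_search(cohort, ("signal",),
                        grid=[ForestParams(n_trees=50)], master_seed=0)
    labels = cohort.groups()
    scored = score_samples(model, cohort)
    assert scored.loc[labels == "long", "score"].median() < 0
    assert scored.loc[labels == "short", "score"].median() > 0
    assert (scored["class"] == np.where(scored["score"] < 0, "long", "short")).all()
    with pytest.raises(KeyError):
        score_samples(model, make_two_group_cohort(
            {"other": np.ones(4)}, 2, 2))


def test_grid_confusion_consistent_with_loo_classes(rng):
    cohort = _separable_cohort(rng, n_long=6, n_short=6, n_noise=1)
    model = grid_search(cohort, ("signal", "noise0"),
                        grid=[ForestParams(n_trees=25)], master_seed=5)
    y = cohort.restrict_groups(["long", "short"]).groups().to_numpy(dtype=object)
    pred = np.array(model.loo_classes)
    assert model.counts.tp == int(((pred == "long") & (y == "long")).sum())
    assert model.counts.tn == int(((pred == "short") & (y == "short")).sum())
    assert model.counts.n == len(y)


# -- ROC -----------------------------------------------------------------------

def test_roc_trivial_orderings():
    labels = ["long"] * 3 + ["short"] * 3
    assert roc_auc([-1, -0.5, -0.2, 0.3, 0.6, 1], labels).auc == pytest.approx(1.0)
    assert roc_auc([1, 0.6, 0.3, -0.2, -0.5, -1], labels).auc == pytest.approx(0.0)
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], ["long", "long"])


def test_roc_curve_monotone_and_matches_mann_whitney(rng):
    labels = np.array(["long"] * 9 + ["short"] * 7)
    for _ in range(20):
        s = rng.normal(size=16)
        curve = roc_auc(s, labels)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        u = stats.mannwhitneyu(s[labels == "short"], s[labels == "long"],
                               alternative="two-sided").statistic
        assert curve.auc == pytest.approx(u / (9 * 7), abs=1e-12)


def test_roc_random_scores_auc_near_half(rng):
    labels = np.array(["long"] * 10 + ["short"] * 9)
    aucs = [roc_auc(rng.normal(size=19), labels).auc for _ in range(1000)]
    assert abs(np.mean(aucs) - 0.5) < 0.03
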