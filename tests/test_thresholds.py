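"""Single-analyte threshold biomarker: metrics, fitting, LOO, rank-sum."""

import itertools

import numpy as np
import pytest
from scipy import stats

from immunomark.thresholds import (
    ConfusionCounts,
    analyte_table,
    confusion_metrics,
    fit_threshold,
    loo_evaluate_single,
    rank_sum_p,
    reports_to_frame,
    round_half_away,
)
from tests.conftest import make_two_group_cohort


# -- confusion metrics ---------------------------------------------------------

@pytest.mark.parametrize(
    "counts, expected",
    [
        # published multidimensional-biomarker and single-gene rows,
        # reconstructed as the unique integer matrices for 11 vs 8
        (ConfusionCounts(9, 2, 0, 8),
         dict(accuracy=89, ppv=100, npv=80, sensitivity=82, specificity=100)),
        (ConfusionCounts(10, 1, 2, 6),
         dict(accuracy=84, ppv=83, npv=86, sensitivity=91, specificity=75)),
        (ConfusionCounts(7, 0, 0, 5),
         dict(accuracy=100, ppv=100, npv=100, sensitivity=100, specificity=100)),
    ],
)
def test_confusion_metrics_rows(counts, expected):
    assert confusion_metrics(counts).rounded() == expected


def test_confusion_metrics_undefined_flagged():
    m = confusion_metrics(ConfusionCounts(tp=0, fn=5, fp=0, tn=5))
    assert m.ppv is None
    assert "ppv" in m.undefined
    assert m.rounded()["ppv"] is None
    with pytest.raises(ValueError):
        confusion_metrics(ConfusionCounts(0, 0, 0, 0))


def test_confusion_metric_identities_enumerated():
    """Row sums are conserved and every defined entry lies in [0, 100]."""
    for tp, fn, fp, tn in itertools.product(range(4), repeat=4):
        if tp + fn + fp + tn == 0:
            continue
        c = ConfusionCounts(tp, fn, fp, tn)
        m = confusion_metrics(c)
        if m.sensitivity is not None:
            assert m.sensitivity == pytest.approx(100 * tp / (tp + fn))
        if m.specificity is not None:
            assert m.specificity == pytest.approx(100 * tn / (tn + fp))
        for v in (m.accuracy, m.ppv, m.npv, m.sensitivity, m.specificity):
            assert v is None or 0 <= v <= 100


def test_round_half_away():
    assert round_half_away(89.47) == 89
    assert round_half_away(85.5) == 86
    assert round_half_away(85.7) == 86


# -- threshold fitting ---------------------------------------------------------

def _brute_force_threshold(values, labels):
    """Independent exhaustive search with the documented tie-breaks."""
    v = np.asarray(values, float)
    pos = np.asarray(labels) == "long"
    distinct = np.unique(v)
    mids = (distinct[:-1] + distinct[1:]) / 2
    best = None
    for thr in mids:
        for direction in ("high_is_positive", "low_is_positive"):
            pred = v >= thr if direction == "high_is_positive" else v <= thr
            sens = (pred & pos).sum() / pos.sum()
            spec = (~pred & ~pos).sum() / (~pos).sum()
            acc = (pred == pos).mean()
            key = (sens + spec, acc, -thr, direction == "high_is_positive")
            if best is None or key > best[0]:
                best = (key, thr, direction)
    return best[1], best[2]


def test_fit_threshold_separated():
    rule = fit_threshold([1, 2, 3, 10, 11],
                         ["long", "long", "long", "short", "short"])
    assert rule.threshold == 6.5
    assert rule.direction == "low_is_positive"
    assert list(rule.predict([1, 2, 3])) == [True, True, True]
    assert list(rule.predict([10, 11])) == [False, False]


def test_fit_threshold_label_swap_symmetry(rng):
    v = rng.normal(size=12)
    labels = np.array(["long"] * 7 + ["short"] * 5)
    a = fit_threshold(v, labels)
    b = fit_threshold(v, np.where(labels == "long", "short", "long"))
    assert a.threshold == b.threshold
    assert a.direction != b.direction


def test_fit_threshold_matches_brute_force(rng):
    for _ in range(200):
        n = int(rng.integers(4, 21))
        n_pos = int(rng.integers(1, n))
        v = np.round(rng.normal(size=n), 1)  # induces occasional ties
        labels = np.array(["long"] * n_pos + ["short"] * (n - n_pos))
        rng.shuffle(labels)
        if len(set(labels)) < 2 or np.unique(v).size < 2:
            continue
        rule = fit_threshold(v, labels)
        thr, direction = _brute_force_threshold(v, labels)
        assert rule.threshold == pytest.approx(thr)
        assert rule.direction == direction


def test_fit_threshold_degenerate_and_errors():
    with pytest.raises(ValueError):
        fit_threshold([1, 2, 3], ["long", "long", "long"])
    rule = fit_threshold([5, 5, 5], ["long", "long", "short"])
    assert rule.degenerate
    assert list(rule.predict([5, 7])) == [True, True]  # majority is long


# -- leave-one-out evaluation --------------------------------------------------

def test_loo_perfectly_separated():
    v = np.array([1, 2, 3, 4, 20, 21, 22], float)
    labels = ["long"] * 4 + ["short"] * 3
    metrics, counts, classes = loo_evaluate_single(v, labels)
    assert metrics.rounded() == dict(accuracy=100, ppv=100, npv=100,
                                     sensitivity=100, specificity=100)
    assert classes == labels


def test_loo_counts_conserve_class_sizes(rng):
    v = rng.normal(size=19)
    labels = np.array(["long"] * 11 + ["short"] * 8)
    _, counts, _ = loo_evaluate_single(v, labels)
    assert counts.tp + counts.fn == 11
    assert counts.fp + counts.tn == 8


def test_loo_never_trains_on_left_out_sample(rng):
    seen: list[tuple[int, np.ndarray]] = []
    v = rng.normal(size=10)
    labels = ["long"] * 6 + ["short"] * 4
    loo_evaluate_single(v, labels, fold_hook=lambda i, tr: seen.append((i, tr)))
    assert len(seen) == 10
    for i, train in seen:
        assert i not in train
        assert train.size == 9


def test_loo_null_labels_center_on_chance_rate(rng):
    """Labels independent of values: LOO accuracy near the 50% chance
    rate (the balanced sens+spec criterion is not majority-seeking)."""
    v = rng.normal(size=19)
    accs = []
    labels = np.array(["long"] * 11 + ["short"] * 8)
    for _ in range(300):
        rng.shuffle(labels)
        m, _, _ = loo_evaluate_single(v, labels)
        accs.append(m.accuracy)
    assert abs(np.mean(accs) - 50.0) < 5.0


# -- rank-sum test -------------------------------------------------------------

def test_rank_sum_identical_multisets():
    assert rank_sum_p([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
    assert rank_sum_p([5, 5], [5, 5, 5]) == 1.0


def test_rank_sum_complete_separation_small():
    # exact: 2 / C(6,3)
    assert rank_sum_p([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)


def test_rank_sum_exact_matches_enumeration(rng):
    """Exact branch equals brute-force enumeration over C(19, 8) splits."""
    pooled = rng.normal(size=19)
    a, b = pooled[:11], pooled[11:]
    ranks = stats.rankdata(pooled)
    u_obs = np.sum(ranks[:11]) - 11 * 12 / 2
    count = 0
    total = 0
    n1n2 = 11 * 8
    u_hi = max(u_obs, n1n2 - u_obs)
    for combo in itertools.combinations(range(19), 11):
        u = ranks[list(combo)].sum() - 11 * 12 / 2
        count += u >= u_hi or u <= n1n2 - u_hi
        total += 1
    assert rank_sum_p(a, b) == pytest.approx(count / total, abs=1e-12)


def test_rank_sum_asymptotic_close_to_permutation_on_ties(rng):
    a = np.round(rng.normal(size=15), 0)
    b = np.round(rng.normal(0.8, size=14), 0)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    obs = ranks[:15].sum()
    mu = ranks.sum() * 15 / 29
    draws = np.argsort(rng.random((100_000, 29)), axis=1)[:, :15]
    perm = ranks[draws].sum(axis=1)
    p_perm = np.mean(np.abs(perm - mu) >= abs(obs - mu) - 1e-9)
    assert abs(rank_sum_p(a, b) - p_perm) < 0.02


# -- analyte table -------------------------------------------------------------

def test_analyte_table_planted_analyte_wins(rng):
    n_long, n_short = 11, 8
    effect = np.concatenate([rng.normal(2.0, 1.0, n_long),
                             rng.normal(0.0, 1.0, n_short)])
    noise = {f"noise{i}": np.exp(rng.normal(size=19)) for i in range(4)}
    cohort = make_two_group_cohort({"planted": np.exp(effect), **noise},
                                   n_long, n_short)
    reports = analyte_table(cohort)
    best = max(reports, key=lambda r: r.accuracy)
    assert best.analyte == "planted"
    assert best.p_value < 0.05


def test_analyte_table_identical_samples():
    cohort = make_two_group_cohort({"flat": np.full(19, 7.0)}, 11, 8)
    reports = analyte_table(cohort)
    r = reports[0]
    assert r.p_value == 1.0
    assert r.threshold is None
    # every LOO fold predicts the training majority (long)
    assert r.metrics.rounded()["accuracy"] == round_half_away(100 * 11 / 19)


def test_report_frame_schema(fixture_cohort):
    reports = analyte_table(fixture_cohort)
    frame = reports_to_frame(reports)
    assert list(frame.columns) == [
        "analyte", "median_long", "median_short", "threshold", "p_value",
        "accuracy", "ppv", "npv", "sensitivity", "specificity",
    ]
    assert len(frame) == 40
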