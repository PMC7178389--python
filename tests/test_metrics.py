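"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pytest

from protlm.metrics import (
    InformationContentTable,
    accuracy,
    auc,
    auc50,
    aupr,
    fmax,
    information_content,
    mean_f1,
    smin,
)

# ---------------------------------------------------------------------------
# Independent oracles (straight re-derivations from the definitions; kept
# deliberately naive and separate from the implementation)
# ---------------------------------------------------------------------------


def oracle_mean_f1(truth, pred):
    classes = sorted(set(truth) | set(pred))
    f1s = []
    for c in classes:
        tp = sum(1 for t, p in zip(truth, pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(truth, pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(truth, pred) if t == c and p != c)
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))


def oracle_fmax(truth_sets, score_table, thresholds):
    best = 0.0
    for t in thresholds:
        prec_sum, n_pred, rec_sum = 0.0, 0, 0.0
        for i, true in enumerate(truth_sets):
            pred = {k for k, s in score_table[i].items() if s >= t}
            if pred:
                n_pred += 1
                prec_sum += len(pred & true) / len(pred)
            if true:
                rec_sum += len(pred & true) / len(true)
        pr = prec_sum / n_pred if n_pred else 0.0
        rc = rec_sum / len(truth_sets)
        if pr + rc > 0:
            best = max(best, 2 * pr * rc / (pr + rc))
    return best


def oracle_smin(truth_sets, score_table, ic, thresholds):
    best = np.inf
    for t in thresholds:
        ru = mi = 0.0
        for i, true in enumerate(truth_sets):
            pred = {k for k, s in score_table[i].items() if s >= t}
            ru += sum(ic(term) for term in true - pred)
            mi += sum(ic(term) for term in pred - true)
        n = len(truth_sets)
        best = min(best, np.hypot(ru / n, mi / n))
    return best


def oracle_auc(labels, scores):
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def oracle_auc50(labels, scores, cap=50):
    order = np.argsort(-np.asarray(scores), kind="stable")
    ranked = [(labels[i], scores[i]) for i in order]
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    n_top = min(cap, n_neg)
    total, seen_neg = 0.0, 0
    for y, s in ranked:
        if y == 0:
            if seen_neg < n_top:
                above = sum(1.0 if sp > s else (0.5 if sp == s else 0.0)
                            for yp, sp in ranked if yp == 1)
                total += above
            seen_neg += 1
    return total / (n_top * n_pos)


def oracle_aupr(labels, scores):
    # trapezoidal integral over the PR curve at every distinct score cut
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    s = np.asarray(scores)[order]
    pts = []
    tp = fp = 0
    n_pos = int(y.sum())
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            tp += int(y[j] == 1)
            fp += int(y[j] == 0)
            j += 1
        pts.append((tp / n_pos, tp / (tp + fp)))
        i = j
    area, (r_prev, p_prev) = 0.0, (0.0, 1.0)
    for r, p in pts:
        area += (r - r_prev) * (p + p_prev) / 2
        r_prev, p_prev = r, p
    return area


# ---------------------------------------------------------------------------


def test_accuracy_counting():
    assert accuracy([1, 0, 1, 0], [1, 1, 1, 0]) == 0.75
    assert accuracy([2, 2], [2, 2]) == 1.0
    with pytest.raises(ValueError):
        accuracy([], [])


def test_mean_f1_against_confusion_matrix_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(4, 40)
        truth = rng.integers(0, 4, size=n)
        pred = rng.integers(0, 4, size=n)
        assert abs(mean_f1(truth, pred) - oracle_mean_f1(truth, pred)) < 1e-9


def random_multilabel_instance(rng, grid_snap=True):
    n_prot = int(rng.integers(1, 10))
    n_terms = int(rng.integers(1, 10))
    truth = []
    table = {}
    for i in range(n_prot):
        truth.append(set(np.flatnonzero(rng.random(n_terms) < 0.4)))
        scores = rng.random(n_terms)
        if grid_snap:
            scores = np.round(scores, 2)  # align with the 0.01 grid
        table[i] = dict(enumerate(scores))
    if not any(truth):
        truth[0] = {0}
    return truth, table


def test_fmax_matches_exhaustive_threshold_oracle():
    rng = np.random.default_rng(1)
    grid = np.linspace(0, 1, 101)
    for _ in range(100):
        truth, table = random_multilabel_instance(rng)
        got, _ = fmax(truth, table)
        assert abs(got - oracle_fmax(truth, table, grid)) < 1e-9


def test_fmax_examples():
    # perfect scores give Fmax 1
    truth = [{0, 2}, {1}]
    table = {0: {0: 1.0, 1: 0.0, 2: 1.0}, 1: {0: 0.0, 1: 1.0, 2: 0.0}}
    assert fmax(truth, table)[0] == 1.0
    # one protein, truth {A}, scores A=0.9 B=0.4 -> thresholds in (0.4, 0.9]
    got, curve = fmax([{"A"}], [{"A": 0.9, "B": 0.4}])
    assert got == 1.0
    assert np.all(curve.recall[1:] <= curve.recall[:-1] + 1e-12)


def test_smin_matches_oracle_and_limits():
    rng = np.random.default_rng(2)
    grid = np.linspace(0, 1, 101)
    for _ in range(100):
        truth, table = random_multilabel_instance(rng)
        terms = {t for d in table.values() for t in d} | set().union(*truth)
        ic = InformationContentTable(
            ic={t: float(rng.random() * 3) for t in terms}, max_ic=3.0
        )
        got, _ = smin(truth, table, ic)
        assert abs(got - oracle_smin(truth, table, ic, grid)) < 1e-9
    # perfect prediction -> 0
    truth = [{0}, {1}]
    table = {0: {0: 1.0, 1: 0.0}, 1: {0: 0.0, 1: 1.0}}
    ic = InformationContentTable(ic={0: 1.0, 1: 2.0}, max_ic=2.0)
    assert smin(truth, table, ic)[0] == 0.0


def test_smin_empty_prediction_limit():
    """Above every score the curve point is (mean total IC of truth, 0)."""
    truth = [{0, 1}]
    table = [{0: 0.3, 1: 0.2}]
    ic = InformationContentTable(ic={0: 1.0, 1: 2.0}, max_ic=2.0)
    _, curve = smin(truth, table, ic)
    assert curve.ru[-1] == pytest.approx(3.0)
    assert curve.mi[-1] == 0.0


def test_information_content_closed_forms():
    table = information_content(
        [{"a", "b"}] + [{"a"}] * 7  # b on 1 of 8 proteins, a on all
    )
    assert table("a") == pytest.approx(0.0)  # annotated on every protein
    assert table("b") == pytest.approx(3.0)  # 1 of 8 -> 3 bits
    assert table("unseen") == table.max_ic


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        scores = np.round(rng.random(n), 2)  # ties occur
        assert abs(auc(labels, scores) - oracle_auc(labels, scores)) < 1e-9


def test_auc_examples():
    assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert auc([1, 0], [0.5, 0.5]) == 0.5
    with pytest.raises(ValueError):
        auc([1, 1], [0.1, 0.2])


def test_auc50_matches_truncated_roc_oracle():
    rng = np.random.default_rng(4)
    for _ in range(100):
        n_pos = int(rng.integers(1, 10))
        n_neg = int(rng.integers(1, 290))
        labels = np.array([1] * n_pos + [0] * n_neg)
        scores = np.round(rng.random(n_pos + n_neg), 2)
        got = auc50(labels, scores)
        assert abs(got - oracle_auc50(labels, scores)) < 1e-9
        assert 0.0 <= got <= 1.0


def test_auc50_equals_auc_when_cap_not_binding():
    rng = np.random.default_rng(5)
    labels = np.array([1] * 10 + [0] * 10)
    scores = rng.random(20)
    assert auc50(labels, scores) == pytest.approx(auc(labels, scores), abs=1e-12)


def test_aupr_matches_trapezoid_oracle():
    rng = np.random.default_rng(6)
    for _ in range(100):
        n = int(rng.integers(5, 60))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() == 0:
            labels[0] = 1
        scores = rng.random(n)
        assert abs(aupr(labels, scores) - oracle_aupr(labels, scores)) < 1e-6


def test_metrics_permutation_invariant():
    rng = np.random.default_rng(7)
    labels = rng.integers(0, 2, size=40)
    labels[:2] = [0, 1]
    scores = rng.random(40)
    perm = rng.permutation(40)
    assert auc(labels, scores) == pytest.approx(auc(labels[perm], scores[perm]))
    assert auc50(labels, scores) == pytest.approx(
        auc50(labels[perm], scores[perm])
    )
    assert aupr(labels, scores) == pytest.approx(
        aupr(labels[perm], scores[perm]), abs=1e-9
    )
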