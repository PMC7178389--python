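"""Evaluation statistics for protein classification.

Single-label: accuracy and unweighted (macro) mean F1.  Multi-label,
protein-centric (the CAFA convention): Fmax — the maximum over score
thresholds of the harmonic mean of threshold precision and recall — and Smin,
the minimum over thresholds of the Euclidean norm of (remaining uncertainty,
misinformation), each weighted by per-term information content estimated from
training annotation frequencies.  Ranking: AUC, area under the
precision-recall curve (trapezoidal), and AUC50 — the ROC area truncated at
the first 50 false positives, normalized to [0, 1], the standard statistic in
remote-homology benchmarks.

Standard quantities route through scikit-learn (macro F1, ROC AUC, the PR
curve); Fmax, Smin, information content and AUC50 are implemented here and
cross-checked against brute-force oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import f1_score, precision_recall_curve, roc_auc_score

DEFAULT_GRID_STEP = 0.01


def accuracy(truth, predictions) -> float:
    truth, predictions = np.asarray(truth), np.asarray(predictions)
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.shape != predictions.shape:
        raise ValueError("length mismatch")
    return float((truth == predictions).mean())


def mean_f1(truth, predictions) -> float:
    """Unweighted mean of per-class F1 (macro average)."""
    truth, predictions = np.asarray(truth), np.asarray(predictions)
    if truth.size == 0:
        raise ValueError("empty input")
    return float(f1_score(truth, predictions, average="macro", zero_division=0.0))


# ---------------------------------------------------------------------------
# Protein-centric multi-label metrics
# ---------------------------------------------------------------------------


@dataclass
class ThresholdCurve:
    """Per-threshold precision/recall and IC-weighted error masses."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    ru: np.ndarray | None = None
    mi: np.ndarray | None = None


def _threshold_grid(grid_step: float) -> np.ndarray:
    n = int(round(1.0 / grid_step))
    return np.linspace(0.0, 1.0, n + 1)


def fmax(
    truth_sets, score_table, grid_step: float = DEFAULT_GRID_STEP
) -> tuple[float, ThresholdCurve]:
    """Protein-centric maximum F-measure.

    ``truth_sets``: per-protein sets of true terms; ``score_table``:
    per-protein dict term -> score in [0, 1].  At each threshold t the
    predicted set is {term : score >= t}; precision is averaged over proteins
    with at least one prediction, recall over all proteins; Fmax is the
    maximum harmonic mean over the grid.
    """
    if not any(truth_sets):
        raise ValueError("no protein has any ground-truth term")
    thresholds = _threshold_grid(grid_step)
    n = len(truth_sets)
    precisions, recalls = np.zeros_like(thresholds), np.zeros_like(thresholds)
    for ti, t in enumerate(thresholds):
        prec_sum, n_pred, rec_sum = 0.0, 0, 0.0
        for i in range(n):
            pred = {term for term, s in score_table[i].items() if s >= t}
            true = truth_sets[i]
            if pred:
                prec_sum += len(pred & true) / len(pred)
                n_pred += 1
            if true:
                rec_sum += len(pred & true) / len(true)
        precisions[ti] = prec_sum / n_pred if n_pred else 0.0
        recalls[ti] = rec_sum / n
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 2 * precisions * recalls / (precisions + recalls)
    f = np.nan_to_num(f)
    best = float(f.max())
    return best, ThresholdCurve(thresholds, precisions, recalls)


@dataclass
class InformationContentTable:
    """Per-term information content (bits by default).

    Terms never seen in training fall back to the maximum observed IC.
    """

    ic: dict
    max_ic: float

    def __call__(self, term) -> float:
        v = self.ic.get(term, self.max_ic)
        if v < 0:
            raise ValueError(f"negative IC for term {term!r}")
        return v


def information_content(
    training_annotations, n_proteins: int | None = None, base: float = 2.0
) -> InformationContentTable:
    """IC(term) = -log_base(n_term / N) from the training partition only.

    ``training_annotations``: iterable of per-protein term sets.
    """
    annotations = list(training_annotations)
    if not annotations:
        raise ValueError("empty annotation table")
    n = n_proteins or len(annotations)
    counts: dict = {}
    for terms in annotations:
        for term in terms:
            counts[term] = counts.get(term, 0) + 1
    ic = {
        term: -np.log(c / n) / np.log(base) for term, c in counts.items()
    }
    max_ic = max(ic.values()) if ic else 0.0
    return InformationContentTable(ic={k: float(v) for k, v in ic.items()},
                                   max_ic=float(max_ic))


def smin(
    truth_sets,
    score_table,
    ic: InformationContentTable,
    grid_step: float = DEFAULT_GRID_STEP,
) -> tuple[float, ThresholdCurve]:
    """Semantic-distance minimum.

    ru(t) = mean over proteins of the summed IC of false negatives;
    mi(t) = mean summed IC of false positives;
    Smin = min over the threshold grid of sqrt(ru^2 + mi^2).
    """
    for true in truth_sets:
        for term in true:
            if term not in ic.ic:
                raise ValueError(f"missing information content for term {term!r}")
    thresholds = _threshold_grid(grid_step)
    n = len(truth_sets)
    ru = np.zeros_like(thresholds)
    mi = np.zeros_like(thresholds)
    for ti, t in enumerate(thresholds):
        ru_sum = mi_sum = 0.0
        for i in range(n):
            pred = {term for term, s in score_table[i].items() if s >= t}
            true = truth_sets[i]
            ru_sum += sum(ic(term) for term in true - pred)
            mi_sum += sum(ic(term) for term in pred - true)
        ru[ti] = ru_sum / n
        mi[ti] = mi_sum / n
    s = np.sqrt(ru**2 + mi**2)
    return float(s.min()), ThresholdCurve(thresholds, np.zeros_like(ru),
                                          np.zeros_like(ru), ru=ru, mi=mi)


# ---------------------------------------------------------------------------
# Ranking metrics
# ---------------------------------------------------------------------------


def _check_two_class(labels):
    labels = np.asarray(labels)
    if labels.size == 0 or len(np.unique(labels)) < 2:
        raise ValueError("need both classes present")
    return labels


def auc(labels, scores) -> float:
    """Probability that a random positive outranks a random negative
    (ties count 1/2)."""
    labels = _check_two_class(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(labels, scores) -> float:
    """Trapezoidal integral of the precision-recall curve."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("need at least one positive")
    precision, recall, _ = precision_recall_curve(labels, np.asarray(scores))
    return float(_trapezoid_auc(recall, precision))


def auc50(labels, scores, fp_cap: int = 50) -> float:
    """ROC area truncated at the first ``fp_cap`` false positives.

    Rank all instances by decreasing score; for each of the first
    min(fp_cap, N_neg) negatives count the positives ranked above it (tied
    positives count 1/2, midpoint convention); normalize by
    min(fp_cap, N_neg) * N_pos.  Equals standard AUC when N_neg <= fp_cap.
    """
    labels = _check_two_class(labels)
    scores = np.asarray(scores, dtype=float)
    pos_scores = scores[labels == 1]
    neg_scores = np.sort(scores[labels == 0])[::-1]
    n_top = min(fp_cap, len(neg_scores))
    total = 0.0
    for s_neg in neg_scores[:n_top]:
        total += (pos_scores > s_neg).sum() + 0.5 * (pos_scores == s_neg).sum()
    return float(total / (n_top * len(pos_scores)))


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-task metric bundle; unused fields stay None."""

    accuracy: float | None = None
    mean_f1: float | None = None
    fmax: float | None = None
    smin: float | None = None
    aupr: float | None = None
    auc: float | None = None
    auc50: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}
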