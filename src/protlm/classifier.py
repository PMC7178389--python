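"""Transfer-learning classifiers on top of the pre-trained sequence encoder.

The language model's decoder is replaced by a concat-pooling layer (last
hidden state ‖ max-pool ‖ mean-pool over time) followed by two dense layers.
Fine-tuning proceeds by gradual unfreezing of four layer groups (embedding /
first LSTM / remaining LSTMs / head) with discriminative learning rates halved
per group toward the input, a one-cycle schedule within each stage, and
gradients truncated at a maximum context of 1024 tokens.  Bidirectional
context is recovered by averaging the output probabilities of independently
trained forward and backward models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus import CLUSTER, make_split
from .lm import LMConfig, SequenceEncoder, _clip_gradients
from .metrics import accuracy, auc, auc50, fmax
from .nn import (
    AdamW,
    Linear,
    Module,
    Tensor,
    bce_logits,
    cross_entropy_logits,
    dropout_mask,
    no_grad,
    one_cycle_schedule,
)
from .vocab import FORWARD, AminoAcidVocabulary, tokenize

CATEGORICAL = "categorical"
BINARY = "binary"


@dataclass
class ClassifierConfig:
    """Classifier head and fine-tuning settings.

    ``head_hidden`` defaults to 256 for single-label tasks; the multi-label
    gene-ontology configuration enlarges it to 1024.  ``epochs_final`` is the
    length of the last (fully unfrozen) one-cycle stage.
    """

    n_outputs: int = 2
    head_hidden: int = 256
    loss: str = CATEGORICAL
    max_context: int = 1024
    n_layer_groups: int = 4
    base_lr: float = 5e-3
    epochs_final: int = 30
    epochs_per_stage: int = 1
    batch_size: int = 16
    head_dropout: float = 0.1
    grad_clip: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.loss not in (CATEGORICAL, BINARY):
            raise ValueError(f"loss must be categorical|binary, got {self.loss!r}")
        if self.loss == CATEGORICAL and self.n_outputs < 2:
            raise ValueError("categorical tasks need n_outputs >= 2")
        if self.max_context < 1:
            raise ValueError("max_context must be >= 1")


def go_config(n_terms: int, **overrides) -> ClassifierConfig:
    """The gene-ontology task configuration: flat multi-label output over the
    filtered term space, binary cross-entropy, head hidden width 1024."""
    defaults = dict(n_outputs=n_terms, head_hidden=1024, loss=BINARY)
    defaults.update(overrides)
    return ClassifierConfig(**defaults)


def concat_pool(states: Tensor, lengths: np.ndarray | None = None) -> Tensor:
    """Concatenate (last state, max over time, mean over time) -> (B, 3d).

    ``states`` is (T, B, d); ``lengths`` gives the valid (un-padded) prefix
    length per batch element.  Padding positions are excluded from the max and
    mean, and "last" means the last valid state.
    """
    T, B, d = states.shape
    if T < 1:
        raise ValueError("need at least one timestep")
    if lengths is None:
        lengths = np.full(B, T, dtype=int)
    lengths = np.asarray(lengths, dtype=int)
    if np.any(lengths < 1) or np.any(lengths > T):
        raise ValueError("lengths must be in [1, T]")
    last = states[lengths - 1, np.arange(B)]  # (B, d)
    valid = (np.arange(T)[:, None] < lengths[None, :]).astype(float)  # (T, B)
    neg = Tensor(np.where(valid[:, :, None] > 0, 0.0, -1e30))
    maxed = (states + neg).max(axis=0)  # (B, d)
    summed = (states * Tensor(valid[:, :, None])).sum(axis=0)
    mean = summed * Tensor((1.0 / lengths)[:, None])
    return Tensor.concat([last, maxed, mean], axis=-1)


class PooledClassifier(Module):
    """Encoder + concat-pooling + two dense layers + task output layer."""

    def __init__(self, vocab_size: int, lm_config: LMConfig, config: ClassifierConfig):
        rng = np.random.default_rng(config.seed)
        self.encoder = SequenceEncoder(vocab_size, lm_config, rng)
        E = lm_config.embedding_dim
        self.fc1 = Linear(3 * E, config.head_hidden, rng)
        self.fc2 = Linear(config.head_hidden, config.n_outputs, rng)
        self.config = config
        self.lm_config = lm_config
        self._rng = np.random.default_rng(config.seed + 1)

    # -- layer groups: [embedding] [lstm 1] [lstm 2..n] [head] ----------------
    def layer_groups(self) -> list[list[Tensor]]:
        groups = [
            [self.encoder.embedding.weight],
            list(self.encoder.layers[0].parameters_all()),
            [p for layer in self.encoder.layers[1:] for p in layer.parameters_all()],
            list(self.fc1.parameters_all()) + list(self.fc2.parameters_all()),
        ]
        return groups

    def set_unfrozen(self, n_groups: int):
        """Unfreeze the last ``n_groups`` layer groups (output end first)."""
        groups = self.layer_groups()
        for gi, group in enumerate(groups):
            trainable = gi >= len(groups) - n_groups
            for p in group:
                p.requires_grad = trainable

    def encode(self, ids: np.ndarray, lengths, train: bool = False) -> Tensor:
        """Encode (T, B) padded ids to pooled (B, 3E) features.

        Sequences longer than ``max_context`` are fully encoded, but the
        backward pass is truncated: the leading prefix is run without graph
        construction and its states enter the pooling as constants.
        """
        T = ids.shape[0]
        cut = max(0, T - self.config.max_context)
        rng = self._rng if train else None
        state = None
        prefix_states: list[np.ndarray] = []
        if cut > 0:
            with no_grad():
                outs, state = self.encoder.forward(
                    ids[:cut], state=None, train=train, rng=rng
                )
            prefix_states = [Tensor(h.data) for h in outs]
            state = [(h.detach(), c.detach()) for h, c in state]
        outs, _ = self.encoder.forward(ids[cut:], state=state, train=train, rng=rng)
        all_states = prefix_states + outs
        stacked = Tensor.concat([h.reshape(1, *h.shape) for h in all_states], axis=0)
        return concat_pool(stacked, lengths)

    def forward(self, ids: np.ndarray, lengths, train: bool = False) -> Tensor:
        pooled = self.encode(ids, lengths, train=train)
        if train and self.config.head_dropout > 0:
            pooled = pooled * Tensor(
                dropout_mask(self._rng, pooled.shape, self.config.head_dropout)
            )
        hidden = self.fc1(pooled).relu()
        if train and self.config.head_dropout > 0:
            hidden = hidden * Tensor(
                dropout_mask(self._rng, hidden.shape, self.config.head_dropout)
            )
        return self.fc2(hidden)


def build_classifier(
    lm_weights: dict[str, np.ndarray] | None,
    config: ClassifierConfig,
    lm_config: LMConfig,
    vocab: AminoAcidVocabulary | None = None,
) -> PooledClassifier:
    """Build a task classifier, optionally initializing the encoder
    (embedding and all LSTM weights) from pre-trained language-model weights.
    ``lm_weights=None`` is the from-scratch mode: everything is randomly
    initialized from ``config.seed``."""
    vocab = vocab or AminoAcidVocabulary()
    clf = PooledClassifier(len(vocab), lm_config, config)
    if lm_weights is not None:
        if lm_weights["embedding"].shape != clf.encoder.embedding.weight.shape:
            raise ValueError(
                "pre-trained weights do not match the classifier dimensions: "
                f"{lm_weights['embedding'].shape} vs "
                f"{clf.encoder.embedding.weight.shape}"
            )
        clf.encoder.load_state_dict(lm_weights)
    return clf


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------


def _pad_batch(token_lists, pad_id: int):
    lengths = np.array([len(t) for t in token_lists])
    T = int(lengths.max())
    ids = np.full((T, len(token_lists)), pad_id, dtype=int)
    for j, toks in enumerate(token_lists):
        ids[: len(toks), j] = toks
    return ids, lengths


def _iter_batches(token_lists, labels, batch_size, pad_id, rng=None):
    order = np.arange(len(token_lists))
    if rng is not None:
        rng.shuffle(order)
    # bucket by length within the shuffled order to limit padding waste
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        ids, lengths = _pad_batch([token_lists[i] for i in idx], pad_id)
        yield ids, lengths, labels[idx], idx


@dataclass
class UnfreezeSchedule:
    """Gradual-unfreezing plan over the four layer groups.

    Stage k trains the last k groups; learning rates are halved per group
    toward the input: the output group trains at ``base_lr``, the embedding
    group at ``base_lr / 8``.
    """

    base_lr: float = 5e-3
    n_groups: int = 4
    epochs_per_stage: int = 1
    epochs_final: int = 30

    def group_lrs(self) -> list[float]:
        """Learning rates from output group down to the input group."""
        return [self.base_lr / (2**i) for i in range(self.n_groups)]

    def stages(self):
        for k in range(1, self.n_groups + 1):
            epochs = self.epochs_final if k == self.n_groups else self.epochs_per_stage
            yield k, epochs


def finetune(
    classifier: PooledClassifier,
    train_tokens,
    train_labels: np.ndarray,
    valid_tokens,
    valid_labels: np.ndarray,
    schedule: UnfreezeSchedule | None = None,
    vocab: AminoAcidVocabulary | None = None,
    selection_metric: str = "accuracy",
):
    """Gradual-unfreezing fine-tuning with one-cycle stages.

    Returns (history, best_state) where ``best_state`` is the parameter
    snapshot of the final-stage epoch with the best validation metric (ties
    resolved toward the earliest epoch).
    """
    if len(valid_tokens) == 0:
        raise ValueError("empty validation set")
    vocab = vocab or AminoAcidVocabulary()
    cfg = classifier.config
    schedule = schedule or UnfreezeSchedule(
        base_lr=cfg.base_lr,
        n_groups=cfg.n_layer_groups,
        epochs_per_stage=cfg.epochs_per_stage,
        epochs_final=cfg.epochs_final,
    )
    rng = np.random.default_rng(cfg.seed + 2)
    train_labels = np.asarray(train_labels)
    history = []
    best = (-math.inf, None, None)  # (metric, epoch index, weights)
    groups = classifier.layer_groups()
    lrs_by_group = schedule.group_lrs()  # output ... input
    n_batches = math.ceil(len(train_tokens) / cfg.batch_size)
    epoch_counter = 0
    for stage, epochs in schedule.stages():
        classifier.set_unfrozen(stage)
        param_groups = []
        for gi, group in enumerate(groups):
            if gi >= len(groups) - stage:
                # distance from the output group sets the lr divisor
                dist = len(groups) - 1 - gi
                param_groups.append(
                    {"params": group, "lr_scale": lrs_by_group[dist] / schedule.base_lr}
                )
        opt = AdamW(param_groups, lr=schedule.base_lr, weight_decay=1e-6)
        lr_trace = one_cycle_schedule(max(1, epochs * n_batches), schedule.base_lr)
        stage_lrs: list[float] = []
        step = 0
        for _ in range(epochs):
            for ids, lengths, yb, _ in _iter_batches(
                train_tokens, train_labels, cfg.batch_size, vocab.pad_id, rng
            ):
                logits = classifier.forward(ids, lengths, train=True)
                if cfg.loss == CATEGORICAL:
                    loss = cross_entropy_logits(logits, yb)
                else:
                    loss = bce_logits(logits, yb)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"non-finite loss in stage {stage}")
                opt.zero_grad()
                loss.backward()
                _clip_gradients(classifier.parameters(), cfg.grad_clip)
                opt.lr = lr_trace[min(step, len(lr_trace) - 1)]
                stage_lrs.append(opt.lr)
                opt.step()
                step += 1
            val = _validation_metric(
                classifier, valid_tokens, valid_labels, vocab, selection_metric
            )
            entry = {
                "stage": stage,
                "epoch": epoch_counter,
                "train_loss": float(loss.data),
                "valid_metric": val,
                "lr_trace": list(stage_lrs),
            }
            stage_lrs = []
            history.append(entry)
            if stage == schedule.n_groups and val > best[0]:
                best = (val, epoch_counter, _snapshot(classifier))
            epoch_counter += 1
    if best[2] is not None:
        _restore(classifier, best[2])
    return history, {"best_metric": best[0], "best_epoch": best[1]}


def _snapshot(classifier) -> list[np.ndarray]:
    return [p.data.copy() for p in classifier.parameters_all()]


def _restore(classifier, snapshot):
    for p, arr in zip(classifier.parameters_all(), snapshot):
        p.data[...] = arr


def _validation_metric(classifier, tokens, labels, vocab, metric: str) -> float:
    scores = predict_proba_tokens(classifier, tokens, vocab)
    labels = np.asarray(labels)
    if metric == "accuracy":
        return accuracy(labels, scores.argmax(axis=1))
    if metric == "auc":
        pos = scores[:, 1] if scores.ndim == 2 and scores.shape[1] == 2 else scores.ravel()
        return auc(labels.ravel(), pos)
    if metric == "fmax":
        truth_sets = [set(np.flatnonzero(row)) for row in labels]
        table = {i: dict(enumerate(scores[i])) for i in range(len(tokens))}
        return fmax(truth_sets, table)[0]
    raise ValueError(f"unknown selection metric {metric!r}")


def predict_proba_tokens(
    classifier: PooledClassifier, token_lists, vocab=None
) -> np.ndarray:
    """Probabilities for already-tokenized records (inference mode)."""
    vocab = vocab or AminoAcidVocabulary()
    cfg = classifier.config
    out = np.zeros((len(token_lists), cfg.n_outputs))
    labels = np.zeros(len(token_lists))
    with no_grad():
        for ids, lengths, _, idx in _iter_batches(
            token_lists, labels, cfg.batch_size, vocab.pad_id, rng=None
        ):
            logits = classifier.forward(ids, lengths, train=False)
            if cfg.loss == CATEGORICAL:
                out[idx] = logits.softmax(axis=-1).data
            else:
                out[idx] = logits.sigmoid().data
    return out


def predict_proba(classifier, records, direction=FORWARD, vocab=None):
    """Per-record probability vectors; unknown-residue records yield an error
    entry instead of aborting the batch."""
    vocab = vocab or AminoAcidVocabulary()
    tokens, errors, keep = [], {}, []
    for i, rec in enumerate(records):
        try:
            tokens.append(tokenize(rec, vocab, direction).ids)
            keep.append(i)
        except ValueError as exc:
            errors[rec.id] = str(exc)
    probs = np.full((len(records), classifier.config.n_outputs), np.nan)
    if tokens:
        probs[keep] = predict_proba_tokens(classifier, tokens, vocab)
    return probs, errors


def ensemble(p_forward: np.ndarray, p_backward: np.ndarray) -> np.ndarray:
    """Elementwise arithmetic mean of forward/backward output probabilities."""
    p_forward, p_backward = np.asarray(p_forward), np.asarray(p_backward)
    if p_forward.shape != p_backward.shape:
        raise ValueError(
            f"shape mismatch: {p_forward.shape} vs {p_backward.shape}"
        )
    return (p_forward + p_backward) / 2.0


# ---------------------------------------------------------------------------
# Task protocols
# ---------------------------------------------------------------------------


def filter_go_terms(
    train_labels: np.ndarray, min_term_count: int = 50
) -> np.ndarray:
    """Indices of terms with at least ``min_term_count`` occurrences in the
    *training* partition (the long-tail label filter)."""
    counts = np.asarray(train_labels).sum(axis=0)
    keep = np.flatnonzero(counts >= min_term_count)
    if keep.size == 0:
        raise ValueError(
            f"no term reaches {min_term_count} training occurrences; "
            f"counts: {counts.tolist()}"
        )
    return keep


def combine_with_external_scores(
    model_scores: np.ndarray, external_scores: np.ndarray, weight: float
) -> np.ndarray:
    """Score-level ensemble with externally computed alignment scores:
    ``(1 - weight) * model + weight * external``."""
    if not (0 <= weight <= 1):
        raise ValueError("weight must be in [0, 1]")
    return (1 - weight) * np.asarray(model_scores) + weight * np.asarray(
        external_scores
    )


def _stratified_cluster_holdout(clusters, label_of, val_ratio: float, seed: int):
    """Cluster-level train/validation split keeping both classes in both
    parts: positive and negative clusters are partitioned separately."""
    members = clusters.members_by_cluster()
    pos, neg = [], []
    for cid, mids in sorted(members.items()):
        (pos if any(label_of[m] for m in mids) else neg).append(cid)
    rng = np.random.default_rng(seed)
    va_clusters = []
    for group in (pos, neg):
        group = list(group)
        rng.shuffle(group)
        n_val = max(1, int(round(val_ratio * len(group)))) if len(group) > 1 else 0
        va_clusters.extend(group[:n_val])
    va_set = set(va_clusters)
    tr_ids = sorted(s for s, c in clusters.member_of.items() if c not in va_set)
    va_ids = sorted(s for s, c in clusters.member_of.items() if c in va_set)
    return tr_ids, va_ids


def run_detection_task(
    datasets,
    lm_config: LMConfig,
    clf_config: ClassifierConfig,
    lm_weights=None,
    vocab: AminoAcidVocabulary | None = None,
    epochs: int = 6,
    val_ratio: float = 0.2,
):
    """Per-dataset binary detection with one shared hyperparameter set.

    For each dataset, the training data is split into train/validation by
    clusters; training runs ``epochs`` epochs with the model snapshot taken at
    the epoch with the highest validation AUC (ties -> earliest).  Datasets
    whose training labels are single-class are skipped with a warning and
    excluded from the means.  Returns a report with per-dataset test AUC and
    AUC50 plus their means.
    """
    vocab = vocab or AminoAcidVocabulary()
    per_dataset = []
    for ds in datasets:
        y_train = np.array([r.labels for r in ds.train_records])
        if len(set(y_train.tolist())) < 2:
            warnings.warn(f"dataset {ds.name}: single-class training labels, skipped")
            continue
        by_id = {r.id: r for r in ds.train_records}
        tr_ids, va_ids = _stratified_cluster_holdout(
            ds.train_clusters, {s: by_id[s].labels for s in by_id},
            val_ratio, clf_config.seed,
        )
        tok = lambda ids: [tokenize(by_id[i], vocab).ids for i in ids]
        lab = lambda ids: np.array([by_id[i].labels for i in ids])
        if len(set(lab(va_ids).tolist())) < 2 or len(set(lab(tr_ids).tolist())) < 2:
            warnings.warn(f"dataset {ds.name}: degenerate validation split, skipped")
            continue
        clf = build_classifier(lm_weights, clf_config, lm_config, vocab)
        clf.set_unfrozen(clf_config.n_layer_groups)
        opt = AdamW(clf.parameters(), lr=clf_config.base_lr, weight_decay=1e-6)
        rng = np.random.default_rng(clf_config.seed + 3)
        tr_tok, tr_lab = tok(tr_ids), lab(tr_ids)
        va_tok, va_lab = tok(va_ids), lab(va_ids)
        best = (-math.inf, None, None)
        for epoch in range(epochs):
            for ids, lengths, yb, _ in _iter_batches(
                tr_tok, tr_lab, clf_config.batch_size, vocab.pad_id, rng
            ):
                logits = clf.forward(ids, lengths, train=True)
                loss = cross_entropy_logits(logits, yb)
                opt.zero_grad()
                loss.backward()
                _clip_gradients(clf.parameters(), clf_config.grad_clip)
                opt.step()
            val_auc = _validation_metric(clf, va_tok, va_lab, vocab, "auc")
            if val_auc > best[0]:  # strict: ties keep the earliest epoch
                best = (val_auc, epoch, _snapshot(clf))
        _restore(clf, best[2])
        te_tok = [tokenize(r, vocab).ids for r in ds.test_records]
        y_test = np.array([r.labels for r in ds.test_records])
        scores = predict_proba_tokens(clf, te_tok, vocab)[:, 1]
        per_dataset.append(
            {
                "name": ds.name,
                "val_auc": best[0],
                "best_epoch": best[1],
                "test_auc": auc(y_test, scores),
                "test_auc50": auc50(y_test, scores),
            }
        )
    if not per_dataset:
        raise ValueError("no usable detection dataset")
    return {
        "per_dataset": per_dataset,
        "mean_auc": float(np.mean([d["test_auc"] for d in per_dataset])),
        "mean_auc50": float(np.mean([d["test_auc50"] for d in per_dataset])),
    }


# ---------------------------------------------------------------------------
# Model/Results facade
# ---------------------------------------------------------------------------


class SequenceClassifier:
    """Protein sequence classifier fine-tuned from a pre-trained encoder.

    Construct with ``lm_weights`` from :class:`~protlm.lm.LMResults`
    (``encoder_weights``) for transfer learning, or ``lm_weights=None`` for
    the from-scratch control.
    """

    def __init__(self, config: ClassifierConfig, lm_config: LMConfig,
                 lm_weights=None, vocab=None, direction: str = FORWARD):
        self.vocab = vocab or AminoAcidVocabulary()
        self.direction = direction
        self.config = config
        self.lm_config = lm_config
        self.classifier = build_classifier(lm_weights, config, lm_config, self.vocab)
        self.pretrained = lm_weights is not None

    def _tokens(self, records):
        return [tokenize(r, self.vocab, self.direction).ids for r in records]

    def fit(self, train_records, valid_records,
            schedule: UnfreezeSchedule | None = None,
            selection_metric: str = "accuracy") -> "ClassifierResults":
        train_tokens = self._tokens(train_records)
        valid_tokens = self._tokens(valid_records)
        y_tr = np.array([r.labels for r in train_records])
        y_va = np.array([r.labels for r in valid_records])
        history, best = finetune(
            self.classifier, train_tokens, y_tr, valid_tokens, y_va,
            schedule=schedule, vocab=self.vocab,
            selection_metric=selection_metric,
        )
        return ClassifierResults(self, history, best)


class ClassifierResults:
    """Fine-tuning artefacts: history, best epoch, prediction interface."""

    def __init__(self, parent: SequenceClassifier, history, best):
        self.parent = parent
        self.classifier = parent.classifier
        self.history = history
        self.best = best

    def predict_proba(self, records) -> np.ndarray:
        tokens = self.parent._tokens(records)
        return predict_proba_tokens(self.classifier, tokens, self.parent.vocab)

    def predict(self, records) -> np.ndarray:
        return self.predict_proba(records).argmax(axis=1)

    def score(self, records) -> float:
        y = np.array([r.labels for r in records])
        return accuracy(y, self.predict(records))

    def summary(self) -> str:
        cfg = self.parent.config
        lines = [
            "Sequence classifier",
            "===================",
            f"pre-trained encoder  {self.parent.pretrained}",
            f"direction            {self.parent.direction}",
            f"outputs / head width {cfg.n_outputs} / {cfg.head_hidden}",
            f"loss                 {cfg.loss}",
            f"epochs run           {len(self.history)}",
            f"best valid metric    {self.best['best_metric']:.3f} "
            f"(epoch {self.best['best_epoch']})",
        ]
        return "\n".join(lines)
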