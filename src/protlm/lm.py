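"""Regularized LSTM language model over amino-acid sequences.

The model is a three-layer LSTM with a tied input/output embedding, trained
autoregressively (predict the next residue) with truncated backpropagation
through time over variable-length windows averaging ~70 tokens.  Five dropout
flavours regularize it: embedding dropout (whole token rows), input dropout,
weight dropout (DropConnect on the recurrent matrices), hidden-state dropout
between layers and output dropout before the decoder.

Public surface: :class:`LMConfig`, :class:`SequenceEncoder` (shared with the
classifiers), :func:`make_bptt_stream`, :func:`train_lm`, :func:`evaluate_lm`,
and the statsmodels-style :class:`ProteinLanguageModel` / :class:`LMResults`
pair built on top of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    AdamW,
    Embedding,
    LSTMLayer,
    Module,
    Tensor,
    cross_entropy_logits,
    dropout_mask,
    no_grad,
    save_checkpoint,
)
from .vocab import AminoAcidVocabulary


@dataclass
class LMConfig:
    """Language-model hyperparameters.

    Defaults are the tiny desk-scale profile (embedding 32, hidden 64) used
    throughout the tests; production-scale values are set via config files.
    """

    embedding_dim: int = 32
    hidden_dim: int = 64
    n_layers: int = 3
    dropout_probs: dict = field(
        default_factory=lambda: {
            "embedding": 0.02,
            "input": 0.1,
            "weight": 0.1,
            "hidden": 0.1,
            "output": 0.1,
        }
    )
    tie_weights: bool = True
    bptt_mean: int = 70
    batch_size: int = 16
    lr: float = 1e-2
    weight_decay: float = 1e-6
    grad_clip: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for k, v in self.dropout_probs.items():
            if not (0 <= v < 1):
                raise ValueError(f"dropout {k} must be in [0,1), got {v}")


class SequenceEncoder(Module):
    """Embedding + stacked LSTM encoder shared by the LM and the classifiers.

    Layer widths are E -> H -> H -> E so the final hidden dimension matches
    the embedding and the decoder can be tied to the embedding matrix.
    """

    def __init__(self, vocab_size: int, config: LMConfig, rng: np.random.Generator):
        if vocab_size < 2:
            raise ValueError("vocabulary must have at least 2 tokens")
        E, H = config.embedding_dim, config.hidden_dim
        self.embedding = Embedding(vocab_size, E, rng)
        dims = [E] + [H] * (config.n_layers - 1) + [E]
        self.layers = [
            LSTMLayer(dims[i], dims[i + 1], rng) for i in range(config.n_layers)
        ]
        self.config = config
        self.vocab_size = vocab_size

    def init_state(self, batch_size: int):
        return [layer.init_state(batch_size) for layer in self.layers]

    def forward(
        self,
        ids: np.ndarray,
        state=None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Encode a (T, B) id array.

        Returns (list of final-layer hidden-state Tensors, new state).  In
        training mode, dropout masks are drawn once per call and locked across
        timesteps (variational dropout).
        """
        T, B = ids.shape
        p = self.config.dropout_probs
        if state is None:
            state = self.init_state(B)
        row_mask = w_masks = None
        if train and rng is not None:
            row_mask = dropout_mask(rng, self.embedding.weight.shape[0], p["embedding"])
            w_masks = [
                dropout_mask(rng, layer.w_recurrent.shape, p["weight"])
                for layer in self.layers
            ]
        emb = self.embedding(ids, row_mask=row_mask)  # (T, B, E)
        xs = [emb[t] for t in range(T)]
        if train and rng is not None and p["input"] > 0:
            m = Tensor(dropout_mask(rng, (B, self.config.embedding_dim), p["input"]))
            xs = [x * m for x in xs]
        new_state = []
        for li, layer in enumerate(self.layers):
            wm = w_masks[li] if w_masks is not None else None
            xs, st = layer(xs, state[li], weight_mask=wm)
            new_state.append(st)
            if train and rng is not None and li < len(self.layers) - 1 and p["hidden"] > 0:
                m = Tensor(dropout_mask(rng, (B, layer.n_hidden), p["hidden"]))
                xs = [x * m for x in xs]
        return xs, new_state

    def state_dict(self) -> dict[str, np.ndarray]:
        arrays = {"embedding": self.embedding.weight.data.copy()}
        for i, layer in enumerate(self.layers):
            arrays[f"lstm{i}.w_input"] = layer.w_input.data.copy()
            arrays[f"lstm{i}.w_recurrent"] = layer.w_recurrent.data.copy()
            arrays[f"lstm{i}.bias"] = layer.bias.data.copy()
        return arrays

    def load_state_dict(self, arrays: dict[str, np.ndarray]):
        self.embedding.weight.data[...] = arrays["embedding"]
        for i, layer in enumerate(self.layers):
            layer.w_input.data[...] = arrays[f"lstm{i}.w_input"]
            layer.w_recurrent.data[...] = arrays[f"lstm{i}.w_recurrent"]
            layer.bias.data[...] = arrays[f"lstm{i}.bias"]


class LanguageModel(Module):
    """Encoder plus (tied) decoder producing next-token distributions."""

    def __init__(self, vocab_size: int, config: LMConfig):
        rng = np.random.default_rng(config.seed)
        self.encoder = SequenceEncoder(vocab_size, config, rng)
        self.config = config
        if config.tie_weights:
            self.decoder_weight = None  # decoder shares the embedding matrix
        else:
            scale = 1.0 / math.sqrt(config.embedding_dim)
            self.decoder_weight = Tensor(
                rng.uniform(-scale, scale, (config.embedding_dim, vocab_size)),
                requires_grad=True,
            )
        self.decoder_bias = Tensor(np.zeros(vocab_size), requires_grad=True)
        self._rng = np.random.default_rng(config.seed + 1)

    def decode(self, hidden: Tensor) -> Tensor:
        w = (
            self.encoder.embedding.weight.T
            if self.config.tie_weights
            else self.decoder_weight
        )
        return hidden @ w + self.decoder_bias

    def forward(self, ids: np.ndarray, state=None, train: bool = False):
        """(T, B) ids -> logits (T*B, V) and the carried state."""
        rng = self._rng if train else None
        outs, state = self.encoder.forward(ids, state=state, train=train, rng=rng)
        p_out = self.config.dropout_probs["output"]
        if train and p_out > 0:
            m = Tensor(
                dropout_mask(self._rng, (ids.shape[1], self.config.embedding_dim), p_out)
            )
            outs = [h * m for h in outs]
        hidden = Tensor.concat([h.reshape(1, *h.shape) for h in outs], axis=0)
        T, B, E = hidden.shape
        return self.decode(hidden.reshape(T * B, E)), state

    def predict_proba(self, ids: np.ndarray) -> np.ndarray:
        """Per-position next-token distributions, dropout off."""
        with no_grad():
            logits, _ = self.forward(ids, train=False)
            return logits.softmax(axis=-1).data


def build_lm(config: LMConfig, vocab: AminoAcidVocabulary) -> LanguageModel:
    return LanguageModel(len(vocab), config)


# ---------------------------------------------------------------------------
# Variable-length BPTT stream
# ---------------------------------------------------------------------------


def _draw_window(rng, bptt_mean: int) -> int:
    """Window length: bptt or bptt/2, jittered by N(0, 5), clamped."""
    base = bptt_mean if rng.random() < 0.95 else bptt_mean / 2
    length = int(round(rng.normal(base, 5)))
    return int(np.clip(length, 5, 2 * bptt_mean))


def make_bptt_stream(
    token_sequences,
    batch_size: int,
    bptt_mean: int = 70,
    seed: int = 0,
    variable: bool = True,
):
    """Concatenate token sequences into ``batch_size`` parallel streams and cut
    them into (input, target, lr_scale) BPTT windows.

    Targets are inputs shifted by one within each stream.  ``lr_scale`` is
    window_length / bptt_mean, compensating shorter windows.  Deterministic
    under ``seed`` (which also fixes the concatenation order).
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(token_sequences))
    flat = np.concatenate([np.asarray(token_sequences[i]) for i in order])
    n_per_stream = len(flat) // batch_size
    if n_per_stream < 2:
        raise ValueError(
            f"corpus too small: {len(flat)} tokens for batch_size {batch_size}"
        )
    streams = flat[: n_per_stream * batch_size].reshape(batch_size, n_per_stream)
    windows = []
    pos = 0
    while pos < n_per_stream - 1:
        T = _draw_window(rng, bptt_mean) if variable else bptt_mean
        T = min(T, n_per_stream - 1 - pos)
        x = streams[:, pos : pos + T].T  # (T, B)
        y = streams[:, pos + 1 : pos + T + 1].T
        windows.append((x, y, T / bptt_mean))
        pos += T
    return windows


def _clip_gradients(params, max_norm: float):
    total = math.sqrt(
        sum(float((p.grad**2).sum()) for p in params if p.grad is not None)
    )
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _detach_state(state):
    return [(h.detach(), c.detach()) for (h, c) in state]


def train_lm(
    model: LanguageModel,
    windows,
    epochs: int = 1,
    valid_windows=None,
    callback=None,
):
    """Train on pre-cut BPTT windows; hidden state persists across windows
    within an epoch.  Returns a per-epoch history list."""
    cfg = model.config
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = []
    for epoch in range(epochs):
        state = None
        total_loss, total_tokens = 0.0, 0
        for x, y, lr_scale in windows:
            if state is not None and state[0][0].shape[0] != x.shape[1]:
                state = None
            logits, state = model.forward(x, state=state, train=True)
            state = _detach_state(state)
            loss = cross_entropy_logits(logits, y.reshape(-1))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite LM loss at epoch {epoch}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            _clip_gradients(model.parameters(), cfg.grad_clip)
            opt.lr = cfg.lr * lr_scale
            opt.step()
            total_loss += float(loss.data) * x.size
            total_tokens += x.size
        entry = {"epoch": epoch, "train_loss": total_loss / total_tokens}
        if valid_windows is not None:
            report = evaluate_lm(model, valid_windows)
            entry["valid_loss"] = math.log(report.perplexity)
            entry["valid_accuracy"] = report.next_token_accuracy
        history.append(entry)
        if callback is not None:
            callback(epoch, entry)
    return history


@dataclass
class LMEvalReport:
    """Held-out language-model quality: perplexity and next-token accuracy."""

    perplexity: float
    next_token_accuracy: float
    n_tokens: int

    def __post_init__(self):
        if self.perplexity < 1 - 1e-9:
            raise ValueError("perplexity cannot be below 1")


def evaluate_lm(model: LanguageModel, windows) -> LMEvalReport:
    """Perplexity = exp(mean per-token NLL); accuracy = argmax hit rate."""
    if not windows:
        raise ValueError("held-out stream is empty")
    nll_sum, correct, total = 0.0, 0, 0
    state = None
    with no_grad():
        for x, y, _ in windows:
            if state is not None and state[0][0].shape[0] != x.shape[1]:
                state = None
            logits, state = model.forward(x, state=state, train=False)
            targets = y.reshape(-1)
            logp = logits.log_softmax(axis=-1).data
            nll_sum += -logp[np.arange(len(targets)), targets].sum()
            correct += int((logp.argmax(axis=1) == targets).sum())
            total += len(targets)
    return LMEvalReport(
        perplexity=math.exp(nll_sum / total),
        next_token_accuracy=correct / total,
        n_tokens=total,
    )


def uniform_guess_accuracy(
    targets: np.ndarray, vocab: AminoAcidVocabulary, seed: int = 0
) -> float:
    """Accuracy of guessing uniformly among the 26 residue tokens.

    The Monte-Carlo estimate of the simplest LM baseline; on residue targets
    its expectation is 1/26 ~ 0.04.
    """
    rng = np.random.default_rng(seed)
    n_special = len(vocab.special_tokens)
    guesses = rng.integers(n_special, len(vocab), size=len(targets))
    return float((guesses == targets).mean())


# ---------------------------------------------------------------------------
# Model/Results facade
# ---------------------------------------------------------------------------


class ProteinLanguageModel:
    """Next-residue language model over a tokenized corpus.

    Parameters
    ----------
    token_sequences : list of id tuples (``<BOS>`` first), one per protein.
    config : LMConfig
    vocab : AminoAcidVocabulary
    valid_sequences : optional held-out sequences for per-epoch evaluation.
    """

    def __init__(self, token_sequences, config: LMConfig, vocab=None,
                 valid_sequences=None):
        self.vocab = vocab or AminoAcidVocabulary()
        self.config = config
        self.token_sequences = list(token_sequences)
        self.valid_sequences = valid_sequences
        self.model = build_lm(config, self.vocab)

    def fit(self, epochs: int = 5) -> "LMResults":
        windows = make_bptt_stream(
            self.token_sequences,
            self.config.batch_size,
            self.config.bptt_mean,
            seed=self.config.seed,
        )
        valid_windows = None
        if self.valid_sequences:
            valid_windows = make_bptt_stream(
                self.valid_sequences,
                self.config.batch_size,
                self.config.bptt_mean,
                seed=self.config.seed,
                variable=False,
            )
        history = train_lm(self.model, windows, epochs=epochs,
                           valid_windows=valid_windows)
        report = (
            evaluate_lm(self.model, valid_windows) if valid_windows else None
        )
        return LMResults(self, history, report)


class LMResults:
    """Fit artefacts: trained weights, training history, held-out report."""

    def __init__(self, parent: ProteinLanguageModel, history, report):
        self.model = parent.model
        self.config = parent.config
        self.vocab = parent.vocab
        self.history = history
        self.report = report

    @property
    def encoder_weights(self) -> dict[str, np.ndarray]:
        return self.model.encoder.state_dict()

    def save(self, path):
        manifest = {
            "kind": "language_model",
            "vocab_size": len(self.vocab),
            "embedding_dim": self.config.embedding_dim,
            "hidden_dim": self.config.hidden_dim,
            "n_layers": self.config.n_layers,
            "epochs": len(self.history),
        }
        arrays = self.encoder_weights
        arrays["decoder_bias"] = self.model.decoder_bias.data.copy()
        save_checkpoint(path, arrays, manifest)

    def summary(self) -> str:
        lines = [
            "Protein language model",
            "======================",
            f"vocabulary size      {len(self.vocab)}",
            f"embedding/hidden dim {self.config.embedding_dim}/{self.config.hidden_dim}",
            f"layers               {self.config.n_layers}",
            f"epochs trained       {len(self.history)}",
            f"final train loss     {self.history[-1]['train_loss']:.4f}",
        ]
        if self.report is not None:
            lines += [
                f"held-out perplexity  {self.report.perplexity:.3f}",
                f"next-token accuracy  {self.report.next_token_accuracy:.3f}",
            ]
        return "\n".join(lines)
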