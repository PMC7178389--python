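"""Neural layers: embedding, LSTM with the AWD-style dropout family, dense
and 1-D convolutional layers.

The dropout taxonomy follows the regularized-LSTM recipe the language model
uses: *embedding dropout* zeroes whole token rows of the embedding matrix,
*input/hidden/output dropout* are ordinary activation dropouts, and *weight
dropout* (DropConnect) masks elements of the hidden-to-hidden recurrent
matrices once per forward pass.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Module:
    """Minimal parameter container."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for x in v:
                    if isinstance(x, Module):
                        params.extend(x.parameters())
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def set_trainable(self, flag: bool):
        for p in self.parameters_all():
            p.requires_grad = flag

    def parameters_all(self) -> list[Tensor]:
        """All parameters regardless of trainable state."""
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters_all())
            elif isinstance(v, (list, tuple)):
                for x in v:
                    if isinstance(x, Module):
                        params.extend(x.parameters_all())
        return params


def _uniform(rng, shape, scale):
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


def dropout_mask(rng, shape, p: float) -> np.ndarray:
    """Inverted-dropout mask: zeros with probability p, else 1/(1-p)."""
    if p <= 0:
        return np.ones(shape)
    return (rng.random(shape) >= p) / (1.0 - p)


class Embedding(Module):
    def __init__(self, vocab_size: int, dim: int, rng):
        self.weight = _uniform(rng, (vocab_size, dim), 0.1)

    def __call__(self, ids: np.ndarray, row_mask: np.ndarray | None = None) -> Tensor:
        """Look up rows for an integer id array of any shape.

        ``row_mask`` (vocab_size,) implements embedding dropout: whole token
        rows are zeroed (and rescaled) for the duration of one forward pass.
        """
        w = self.weight
        if row_mask is not None:
            w = w * Tensor(row_mask[:, None])
        return w[ids]


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng, gain: float = 1.0):
        # gain sqrt(2) (He) for layers feeding a ReLU
        scale = gain * np.sqrt(3.0 / n_in)
        self.weight = _uniform(rng, (n_in, n_out), scale)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LSTMLayer(Module):
    """Single LSTM layer with optional DropConnect on the recurrent matrix.

    Gate layout along the last axis: input, forget, cell, output.
    """

    def __init__(self, n_in: int, n_hidden: int, rng, input_gain: float = 3.0,
                 forget_bias: float = 1.0):
        # scaled-up input weights and a positive forget-gate bias keep
        # activation magnitudes roughly constant through stacked layers, which
        # small tied-decoder models need to escape the unigram plateau
        self.w_input = _uniform(rng, (n_in, 4 * n_hidden),
                                input_gain * np.sqrt(3.0 / n_in))
        self.w_recurrent = _uniform(rng, (n_hidden, 4 * n_hidden),
                                    np.sqrt(3.0 / n_hidden))
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = forget_bias
        self.bias = Tensor(b, requires_grad=True)
        self.n_hidden = n_hidden

    def init_state(self, batch_size: int):
        h = Tensor(np.zeros((batch_size, self.n_hidden)))
        c = Tensor(np.zeros((batch_size, self.n_hidden)))
        return h, c

    def __call__(self, xs: list[Tensor], state, weight_mask: np.ndarray | None = None):
        """Run over a list of (B, n_in) timestep tensors.

        Returns (list of hidden states, final (h, c)).  ``weight_mask``
        applies DropConnect to the hidden-to-hidden matrix for this pass.
        """
        h, c = state
        w_rec = self.w_recurrent
        if weight_mask is not None:
            w_rec = w_rec * Tensor(weight_mask)
        H = self.n_hidden
        outputs: list[Tensor] = []
        for x in xs:
            z = x @ self.w_input + h @ w_rec + self.bias
            i = z[:, 0 * H : 1 * H].sigmoid()
            f = z[:, 1 * H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs.append(h)
        return outputs, (h, c)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, kernel: int) -> Tensor:
    """Valid-padding 1-D convolution.

    x: (B, L, C_in); weight: (kernel*C_in, C_out); output (B, L-kernel+1, C_out).
    Implemented as a patch-matrix (im2col) matmul.
    """
    B, L, C = x.shape
    Lout = L - kernel + 1
    patches = Tensor.concat([x[:, k : k + Lout, :] for k in range(kernel)], axis=-1)
    return patches.reshape(B * Lout, kernel * C) @ weight + bias, Lout


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng):
        # He-uniform: preserves activation scale through ReLU stacks
        scale = np.sqrt(6.0 / (kernel * c_in))
        self.weight = _uniform(rng, (kernel * c_in, c_out), scale)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.kernel = kernel
        self.c_out = c_out

    def __call__(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        out, Lout = conv1d(x, self.weight, self.bias, self.kernel)
        return out.reshape(B, Lout, self.c_out)


def maxpool1d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping max pooling over the length axis (tail truncated)."""
    B, L, C = x.shape
    Lout = L // factor
    x = x[:, : Lout * factor, :].reshape(B, Lout, factor, C)
    return x.max(axis=2)
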