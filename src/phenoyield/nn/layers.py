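"""Network building blocks: dense layers, stacked LSTM, additive attention.

All layers hold their parameters as :class:`~phenoyield.nn.autodiff.Tensor`
objects with ``requires_grad=True`` and expose ``parameters()`` for the
optimizer.  Initialisation is Glorot-uniform from a caller-supplied
``numpy.random.Generator`` so two builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["Dense", "StackedLSTM", "AdditiveAttention", "masked_softmax"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Dense:
    """Affine map with optional activation ('sigmoid', 'tanh' or None)."""

    def __init__(self, rng, n_in: int, n_out: int, activation: str | None = None):
        self.W = _glorot(rng, n_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        z = x @ self.W + self.b
        if self.activation == "sigmoid":
            return z.sigmoid()
        if self.activation == "tanh":
            return z.tanh()
        return z

    def parameters(self):
        return [self.W, self.b]


class _LSTMLayer:
    """Single LSTM layer; gate order [i, f, g, o]; forget bias starts at 1."""

    def __init__(self, rng, n_in: int, n_units: int):
        self.n_units = n_units
        self.Wx = _glorot(rng, n_in, 4 * n_units)
        self.Wh = _glorot(rng, n_units, 4 * n_units)
        b = np.zeros(4 * n_units)
        b[n_units : 2 * n_units] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def parameters(self):
        return [self.Wx, self.Wh, self.b]

    def n_parameters(self) -> int:
        # classic count: 4*(u*(u+i)+u)
        return sum(p.data.size for p in self.parameters())

    def step(self, x_t: Tensor, h: Tensor, c: Tensor):
        u = self.n_units
        z = x_t @ self.Wx + h @ self.Wh + self.b
        i = z[:, 0:u].sigmoid()
        f = z[:, u : 2 * u].sigmoid()
        g = z[:, 2 * u : 3 * u].tanh()
        o = z[:, 3 * u : 4 * u].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class StackedLSTM:
    """Stack of LSTM layers with inter-layer dropout applied in training mode.

    ``__call__`` consumes a (plots, time, features) Tensor and returns the
    list of top-layer hidden states, one (plots, units) Tensor per time-step.
    """

    def __init__(self, rng, n_in: int, n_units: int, n_layers: int, dropout: float):
        self.layers = []
        self.dropout = dropout
        for k in range(n_layers):
            self.layers.append(_LSTMLayer(rng, n_in if k == 0 else n_units, n_units))
        self.n_units = n_units

    def parameters(self):
        return [p for lyr in self.layers for p in lyr.parameters()]

    def n_parameters(self) -> int:
        return sum(lyr.n_parameters() for lyr in self.layers)

    def __call__(self, x: Tensor, training: bool = False, rng=None):
        n = x.shape[0]
        n_steps = x.shape[1]
        seq = [x[:, t, :] for t in range(n_steps)]
        for lyr in self.layers:
            h = Tensor(np.zeros((n, lyr.n_units)))
            c = Tensor(np.zeros((n, lyr.n_units)))
            out = []
            for t in range(n_steps):
                h, c = lyr.step(seq[t], h, c)
                out.append(h)
            if training and self.dropout > 0.0:
                keep = 1.0 - self.dropout
                # one mask per layer, shared across time (variational-style)
                mask = (rng.random((n, lyr.n_units)) < keep) / keep
                out = [h_t * Tensor(mask) for h_t in out]
            seq = out
        return seq


def masked_softmax(scores: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; entries where mask==0 get weight exactly 0."""
    shift = scores.data.max(axis=-1, keepdims=True)
    e = (scores - Tensor(shift)).exp()
    if mask is not None:
        e = e * Tensor(mask.astype(np.float64))
    total = e.sum(axis=-1, keepdims=True)
    return e / total


class AdditiveAttention:
    """Bahdanau-style additive attention decomposed per (time-step, feature).

    Each pair (t, f) is scored by v . tanh(W_h h_t + u_f + x_{t,f} s_f + b)
    where h_t is the top LSTM hidden state, u_f a learned per-feature key and
    s_f a learned per-feature scaling of the raw input value; a joint softmax
    over all (t, f) pairs yields a weight map that sums to one per plot.  The
    context vector is the weight- and value-weighted sum of per-feature
    output embeddings.
    """

    def __init__(self, rng, n_units: int, n_features: int, n_steps: int,
                 attn_dim: int, context_dim: int,
                 final_state_query: bool = False):
        self.Wh = _glorot(rng, n_units, attn_dim)
        # optional explicit query from the final hidden state; the default
        # leaves the query learned (implicit in v)
        self.final_state_query = final_state_query
        self.Wq = _glorot(rng, n_units, attn_dim) if final_state_query else None
        self.U = _glorot(rng, n_features, attn_dim, shape=(n_features, attn_dim))
        self.S = _glorot(rng, n_features, attn_dim, shape=(n_features, attn_dim))
        # learned per-date key (positional embedding) for temporal selectivity;
        # zero-initialized so initial attention carries no date preference
        self.D = Tensor(np.zeros((n_steps, 1, attn_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(attn_dim), requires_grad=True)
        self.v = _glorot(rng, attn_dim, 1)
        self.E = _glorot(rng, n_features, context_dim, shape=(n_features, context_dim))
        self.n_features = n_features
        self.n_steps = n_steps
        self.context_dim = context_dim

    def parameters(self):
        params = [self.Wh, self.U, self.S, self.D, self.b, self.v, self.E]
        if self.Wq is not None:
            params.append(self.Wq)
        return params

    def __call__(self, hidden: list, x: Tensor, gate_mask: np.ndarray | None = None):
        """Return (context (n, context_dim), weights (n, T, F) Tensor)."""
        n_steps = len(hidden)
        n = x.shape[0]
        f = self.n_features
        a = self.Wh.shape[1]
        H = concat([h.reshape(n, 1, -1) for h in hidden], axis=1)  # (n,T,u)
        q = (H @ self.Wh).reshape(n, n_steps, 1, a)                # (n,T,1,a)
        val = x.reshape(n, n_steps, f, 1) * self.S                 # (n,T,F,a)
        key = q + val + self.U + self.D + self.b                   # (n,T,F,a)
        if self.final_state_query:
            key = key + (hidden[-1] @ self.Wq).reshape(n, 1, 1, a)
        k = key.tanh()
        e = (k.reshape(n * n_steps * f, a) @ self.v).reshape(n, n_steps * f)
        mask_flat = None
        if gate_mask is not None:
            mask_flat = np.repeat(gate_mask.astype(np.float64), f)[None, :]
            mask_flat = np.broadcast_to(mask_flat, (n, n_steps * f))
        alpha_flat = masked_softmax(e, mask_flat)  # (n, T*F)
        alpha = alpha_flat.reshape(n, n_steps, f)
        weighted = (alpha * x).reshape(n * n_steps, f)
        ctx = (weighted @ self.E).reshape(n, n_steps, self.context_dim).sum(axis=1)
        return ctx, alpha
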