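"""A compact numpy neural-network engine for the sequence classifiers.

Implements exactly the layers the affinity models need — dense, 1-D
convolution (same padding), GRU, multi-head self-attention / transformer
encoder blocks, layer norm, pooling — with hand-written backward passes,
an Adam optimizer and binary cross-entropy on logits.  Everything is
deterministic given the seed and single-threaded; per-parameter
``trainable`` flags support frozen-layer transfer learning.

Gradients of every layer are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import copy
from typing import Callable, Sequence

import numpy as np


class Param:
    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.trainable = True


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(_glorot(rng, (d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._shape = x.shape
        self._x = x.reshape(-1, x.shape[-1])
        out = self._x @ self.W.value + self.b.value
        return out.reshape(*self._shape[:-1], -1)

    def backward(self, dout):
        d = dout.reshape(-1, dout.shape[-1])
        self.W.grad += self._x.T @ d
        self.b.grad += d.sum(axis=0)
        dx = d @ self.W.value.T
        return dx.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Conv1D(Layer):
    """Same-padded 1-D convolution over (batch, length, channels)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.c_in = c_in
        self.W = Param(_glorot(rng, (kernel * c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        B, T, C = x.shape
        k, p = self.kernel, self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        # cols[b, t, kk, c] = xp[b, t + kk, c]
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        cols = np.ascontiguousarray(np.moveaxis(cols, 3, 2))  # (B, T, k, C)
        self._cols = cols.reshape(B, T, k * C)
        self._in_shape = (B, T, C)
        out = self._cols @ self.W.value + self.b.value
        return out

    def backward(self, dout):
        B, T, C = self._in_shape
        k, p = self.kernel, self.kernel // 2
        d = dout.reshape(-1, dout.shape[-1])
        self.W.grad += self._cols.reshape(-1, k * C).T @ d
        self.b.grad += d.sum(axis=0)
        dcols = (d @ self.W.value.T).reshape(B, T, k, C)
        dxp = np.zeros((B, T + 2 * p, C))
        for kk in range(k):
            dxp[:, kk : kk + T, :] += dcols[:, :, kk, :]
        return dxp[:, p : p + T, :]


class GlobalMaxPool1D(Layer):
    def forward(self, x):
        self._x_shape = x.shape
        self._argmax = np.argmax(x, axis=1)  # (B, C)
        return np.take_along_axis(x, self._argmax[:, None, :], axis=1)[:, 0, :]

    def backward(self, dout):
        dx = np.zeros(self._x_shape)
        np.put_along_axis(dx, self._argmax[:, None, :], dout[:, None, :], axis=1)
        return dx


class MeanPool1D(Layer):
    def forward(self, x):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :], self._T, axis=1) / self._T


class PositionalEmbedding(Layer):
    """Learned additive positional embedding for fixed-length input."""

    def __init__(self, length: int, d: int, rng: np.random.Generator):
        self.P = Param(0.02 * rng.standard_normal((length, d)))

    def params(self):
        return [self.P]

    def forward(self, x):
        return x + self.P.value

    def backward(self, dout):
        self.P.grad += dout.sum(axis=0)
        return dout


class LayerNorm(Layer):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(d))
        self.beta = Param(np.zeros(d))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout):
        xhat = self._xhat
        self.gamma.grad += (dout * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.beta.grad += dout.reshape(-1, xhat.shape[-1]).sum(axis=0)
        dxhat = dout * self.gamma.value
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return (dxhat - m1 - xhat * m2) / self._std


class MultiHeadSelfAttention(Layer):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads != 0:
            raise ValueError("model dim must divide by head count")
        self.d, self.h = d, n_heads
        self.dh = d // n_heads
        self.q = Dense(d, d, rng)
        self.k = Dense(d, d, rng)
        self.v = Dense(d, d, rng)
        self.o = Dense(d, d, rng)

    def params(self):
        return self.q.params() + self.k.params() + self.v.params() + self.o.params()

    def _split(self, x):  # (B, T, D) -> (B, h, T, Dh)
        B, T, _ = x.shape
        return x.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (B, h, T, Dh) -> (B, T, D)
        B, h, T, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dh)

    def forward(self, x):
        Q = self._split(self.q.forward(x))
        K = self._split(self.k.forward(x))
        V = self._split(self.v.forward(x))
        scores = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        A = e / e.sum(axis=-1, keepdims=True)
        ctx = A @ V
        self._Q, self._K, self._V, self._A = Q, K, V, A
        return self.o.forward(self._merge(ctx))

    def backward(self, dout):
        dctx = self._split(self.o.backward(dout))
        A, Q, K, V = self._A, self._Q, self._K, self._V
        dA = dctx @ V.transpose(0, 1, 3, 2)
        dV = A.transpose(0, 1, 3, 2) @ dctx
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS /= np.sqrt(self.dh)
        dQ = dS @ K
        dK = dS.transpose(0, 1, 3, 2) @ Q
        dx = self.q.backward(self._merge(dQ))
        dx += self.k.backward(self._merge(dK))
        dx += self.v.backward(self._merge(dV))
        return dx


class TransformerBlock(Layer):
    """Pre-norm encoder block: x + MHSA(LN(x)), then + FFN(LN(.))."""

    def __init__(self, d: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, n_heads, rng)
        self.ln2 = LayerNorm(d)
        self.ff1 = Dense(d, d_ff, rng)
        self.act = ReLU()
        self.ff2 = Dense(d_ff, d, rng)

    def params(self):
        return (
            self.ln1.params()
            + self.attn.params()
            + self.ln2.params()
            + self.ff1.params()
            + self.ff2.params()
        )

    def forward(self, x):
        a = x + self.attn.forward(self.ln1.forward(x))
        return a + self.ff2.forward(self.act.forward(self.ff1.forward(self.ln2.forward(a))))

    def backward(self, dout):
        da = dout + self.ln2.backward(
            self.ff1.backward(self.act.backward(self.ff2.backward(dout)))
        )
        return da + self.ln1.backward(self.attn.backward(da))


class GRU(Layer):
    """Single-layer GRU; emits the last hidden state (B, H)."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        self.H = hidden
        self.Wz = Param(_glorot(rng, (c_in, hidden)))
        self.Uz = Param(_glorot(rng, (hidden, hidden)))
        self.bz = Param(np.zeros(hidden))
        self.Wr = Param(_glorot(rng, (c_in, hidden)))
        self.Ur = Param(_glorot(rng, (hidden, hidden)))
        self.br = Param(np.zeros(hidden))
        self.Wh = Param(_glorot(rng, (c_in, hidden)))
        self.Uh = Param(_glorot(rng, (hidden, hidden)))
        self.bh = Param(np.zeros(hidden))

    def params(self):
        return [
            self.Wz, self.Uz, self.bz,
            self.Wr, self.Ur, self.br,
            self.Wh, self.Uh, self.bh,
        ]

    def forward(self, x):
        B, T, _ = x.shape
        h = np.zeros((B, self.H))
        self._cache = []
        self._x = x
        for t in range(T):
            xt = x[:, t, :]
            z = _sigmoid(xt @ self.Wz.value + h @ self.Uz.value + self.bz.value)
            r = _sigmoid(xt @ self.Wr.value + h @ self.Ur.value + self.br.value)
            hh = np.tanh(xt @ self.Wh.value + (r * h) @ self.Uh.value + self.bh.value)
            h_new = (1 - z) * h + z * hh
            self._cache.append((xt, h, z, r, hh))
            h = h_new
        return h

    def backward(self, dout):
        B, T, C = self._x.shape
        dx = np.zeros((B, T, C))
        dh = dout
        for t in reversed(range(T)):
            xt, h_prev, z, r, hh = self._cache[t]
            dz = dh * (hh - h_prev)
            dhh = dh * z
            dh_prev = dh * (1 - z)
            dhh_pre = dhh * (1 - hh * hh)
            self.Wh.grad += xt.T @ dhh_pre
            self.Uh.grad += (r * h_prev).T @ dhh_pre
            self.bh.grad += dhh_pre.sum(axis=0)
            drh = dhh_pre @ self.Uh.value.T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            dz_pre = dz * z * (1 - z)
            dr_pre = dr * r * (1 - r)
            self.Wz.grad += xt.T @ dz_pre
            self.Uz.grad += h_prev.T @ dz_pre
            self.bz.grad += dz_pre.sum(axis=0)
            self.Wr.grad += xt.T @ dr_pre
            self.Ur.grad += h_prev.T @ dr_pre
            self.br.grad += dr_pre.sum(axis=0)
            dh_prev = dh_prev + dz_pre @ self.Uz.value.T + dr_pre @ self.Ur.value.T
            dx[:, t, :] = (
                dz_pre @ self.Wz.value.T
                + dr_pre @ self.Wr.value.T
                + dhh_pre @ self.Wh.value.T
            )
            dh = dh_prev
        return dx


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient."""
    z = logits
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (_sigmoid(z) - y) / len(z)
    return float(loss), dz


class Adam:
    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if not p.trainable:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------


def build_mlp(d_in: int, hidden: tuple[int, ...], rng: np.random.Generator) -> Sequential:
    layers: list[Layer] = []
    d = d_in
    for h in hidden:
        layers += [Dense(d, h, rng), ReLU()]
        d = h
    layers.append(Dense(d, 1, rng))
    return Sequential(layers)


class CNNNet(Sequential):
    """Stack of same-padded 1-D conv layers, global max pool, FC head.

    ``conv_layers`` exposes the conv stack in order for transfer-learning
    freezes.
    """

    def __init__(self, n_conv: int, filters: int, kernel: int, fc: int,
                 rng: np.random.Generator, c_in: int = 4):
        self.conv_layers: list[Conv1D] = []
        layers: list[Layer] = []
        c = c_in
        for _ in range(n_conv):
            conv = Conv1D(c, filters, kernel, rng)
            self.conv_layers.append(conv)
            layers += [conv, ReLU()]
            c = filters
        layers += [GlobalMaxPool1D(), Dense(filters, fc, rng), ReLU(), Dense(fc, 1, rng)]
        super().__init__(layers)

    def freeze_conv(self, n_freeze: int) -> None:
        for conv in self.conv_layers[:n_freeze]:
            for p in conv.params():
                p.trainable = False

    def frozen_param_values(self, n_freeze: int) -> list[np.ndarray]:
        return [
            p.value.copy()
            for conv in self.conv_layers[:n_freeze]
            for p in conv.params()
        ]


def build_gru(hidden: int, rng: np.random.Generator, c_in: int = 4) -> Sequential:
    return Sequential([GRU(c_in, hidden, rng), Dense(hidden, 1, rng)])


def build_transformer(d: int, n_heads: int, n_blocks: int, length: int,
                      rng: np.random.Generator, c_in: int = 4) -> Sequential:
    layers: list[Layer] = [Dense(c_in, d, rng), PositionalEmbedding(length, d, rng)]
    for _ in range(n_blocks):
        layers.append(TransformerBlock(d, n_heads, 2 * d, rng))
    layers += [MeanPool1D(), Dense(d, 1, rng)]
    return Sequential(layers)


# ---------------------------------------------------------------------------
# training harness
# ---------------------------------------------------------------------------


def _rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    from .metrics import rank_auc

    return rank_auc(y, scores)


class NeuralNetClassifier:
    """Mini-batch Adam training with optional validation-AUC early stopping."""

    def __init__(
        self,
        net: Sequential,
        seed: int = 0,
        lr: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 200,
        patience: int = 10,
    ):
        self.net = net
        self.seed = seed
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience

    def fit(self, X, y, X_val=None, y_val=None) -> "NeuralNetClassifier":
        rng = np.random.default_rng(self.seed)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        opt = Adam(self.net.params(), lr=self.lr)
        best_metric = -np.inf
        best_state = None
        bad_epochs = 0
        use_val = X_val is not None and y_val is not None
        for _ in range(self.max_epochs):
            order = rng.permutation(len(X))
            epoch_loss = 0.0
            for start in range(0, len(X), self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.net.forward(X[idx]).ravel()
                loss, dz = bce_with_logits(logits, y[idx])
                epoch_loss += loss * len(idx)
                opt.zero_grad()
                self.net.backward(dz.reshape(-1, 1))
                opt.step()
            if use_val:
                metric = _rank_auc(np.asarray(y_val, dtype=int),
                                   self.predict_proba(X_val))
            else:
                metric = -epoch_loss / len(X)
            if metric > best_metric + 1e-6:
                best_metric = metric
                best_state = self.get_state()
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= self.patience:
                    break
        if best_state is not None:
            self.set_state(best_state)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = []
        for start in range(0, len(X), 512):
            out.append(_sigmoid(self.net.forward(X[start : start + 512]).ravel()))
        return np.concatenate(out)

    # -- parameter state ---------------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.net.params()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        for p, v in zip(self.net.params(), state):
            p.value[...] = v

    def clone(self) -> "NeuralNetClassifier":
        return copy.deepcopy(self)
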