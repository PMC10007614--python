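"""Minimal NumPy neural-network core for sequence regression.

Implements exactly the blocks the attention-based LSTM regressor needs —
an LSTM returning its full hidden sequence, a many-to-one attention block,
dense layers — with hand-written backpropagation and SGD/Adam optimizers.
Each layer exposes ``forward(x) -> y`` and ``backward(dy) -> dx`` plus a
``grads`` dict aligned with ``params``; gradients are validated against
finite differences in the test suite.

Shapes follow the batch-first convention: sequences are (B, T, D).
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if rows < cols:
        q = q.T
    return q[:rows, :cols]


class Layer:
    params: dict
    grads: dict

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class LSTM(Layer):
    """Single LSTM layer returning the full hidden sequence (B, T, H).

    Gate layout in the fused weight matrices is [input, forget, cell,
    output].  Initial hidden and cell states are zero; the forget-gate bias
    starts at 1 so early training does not wash out the cell state.
    """

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        self.n_in, self.n_units = n_in, n_units
        H = n_units
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0
        self.params = {
            "W": glorot_uniform(rng, n_in, 4 * H),
            # recurrent kernel: one orthogonal block per gate
            "U": np.concatenate([orthogonal(rng, H, H) for _ in range(4)],
                                axis=1),
            "b": b,
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        H = self.n_units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        xw = x @ W + b                      # (B, T, 4H), input part precomputed
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = {"x": x, "i": np.empty((B, T, H)), "f": np.empty((B, T, H)),
                       "g": np.empty((B, T, H)), "o": np.empty((B, T, H)),
                       "c": np.empty((B, T, H)), "tc": np.empty((B, T, H)),
                       "h_prev": np.empty((B, T, H)),
                       "c_prev": np.empty((B, T, H))}
        hs = np.empty((B, T, H))
        cc = self._cache
        for t in range(T):
            z = xw[:, t] + h @ U
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            cc["h_prev"][:, t], cc["c_prev"][:, t] = h, c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            cc["i"][:, t], cc["f"][:, t], cc["g"][:, t], cc["o"][:, t] = i, f, g, o
            cc["c"][:, t], cc["tc"][:, t] = c, tc
            hs[:, t] = h
        self._cache["hs"] = hs
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        cc = self._cache
        x = cc["x"]
        B, T, D = x.shape
        H = self.n_units
        U = self.params["U"]
        dW = np.zeros_like(self.params["W"])
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o = cc["i"][:, t], cc["f"][:, t], cc["g"][:, t], cc["o"][:, t]
            tc, c_prev = cc["tc"][:, t], cc["c_prev"][:, t]
            dh = dhs[:, t] + dh_next
            do = dh * tc * o * (1 - o)
            dc = dh * o * (1 - tc ** 2) + dc_next
            di = dc * g * i * (1 - i)
            df = dc * c_prev * f * (1 - f)
            dg = dc * i * (1 - g ** 2)
            dz = np.concatenate([di, df, dg, do], axis=1)   # (B, 4H)
            dW += x[:, t].T @ dz
            dU += cc["h_prev"][:, t].T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.params["W"].T
            dh_next = dz @ U.T
            dc_next = dc * f
        self.grads = {"W": dW, "U": dU, "b": db}
        return dx


def attention_scores_and_weights(hidden: np.ndarray, last: np.ndarray,
                                 W_score: np.ndarray
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Scores <W_score h_t, h_last> and their softmax over the sequence."""
    proj = hidden @ W_score                      # (B, T, H)
    scores = np.einsum("bth,bh->bt", proj, last)
    s = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(s)
    weights = e / e.sum(axis=1, keepdims=True)
    return scores, weights


class Attention(Layer):
    """Many-to-one attention over a hidden-state sequence.

    Every step's hidden state is projected by a bias-free square map and
    dot-scored against the last state; softmax over the steps gives the
    weights; the context (weighted sum of hidden states) is concatenated
    with the last state and passed through a bias-free tanh projection to
    ``n_units`` outputs.  Trainable parameters: H^2 + 2H*A.
    """

    def __init__(self, n_hidden: int, n_units: int, rng: np.random.Generator):
        self.n_hidden, self.n_units = n_hidden, n_units
        self.params = {
            "W_score": glorot_uniform(rng, n_hidden, n_hidden),
            "W_out": glorot_uniform(rng, 2 * n_hidden, n_units),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, hidden: np.ndarray) -> np.ndarray:
        last = hidden[:, -1, :]
        _, a = attention_scores_and_weights(hidden, last,
                                            self.params["W_score"])
        context = np.einsum("bt,bth->bh", a, hidden)
        concat = np.concatenate([context, last], axis=1)
        v = np.tanh(concat @ self.params["W_out"])
        self._cache = (hidden, last, a, context, concat, v)
        return v

    def backward(self, dv: np.ndarray) -> np.ndarray:
        hidden, last, a, context, concat, v = self._cache
        H = self.n_hidden
        Ws, Wo = self.params["W_score"], self.params["W_out"]
        dpre = dv * (1 - v ** 2)
        dWo = concat.T @ dpre
        dconcat = dpre @ Wo.T
        dcontext, dlast = dconcat[:, :H], dconcat[:, H:].copy()

        da = np.einsum("bh,bth->bt", dcontext, hidden)
        dhidden = a[:, :, None] * dcontext[:, None, :]
        # softmax backward
        ds = a * (da - np.sum(a * da, axis=1, keepdims=True))
        proj = hidden @ Ws
        dlast += np.einsum("bt,bth->bh", ds, proj)
        dproj = ds[:, :, None] * last[:, None, :]
        dWs = np.einsum("bth,btk->hk", hidden, dproj)
        dhidden += dproj @ Ws.T
        dhidden[:, -1, :] += dlast
        self.grads = {"W_score": dWs, "W_out": dWo}
        return dhidden


class LastState(Layer):
    """Select the final step of a sequence (ablation of the attention block)."""

    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape)
        dx[:, -1, :] = dy
        return dx


class Flatten(Layer):
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str = "linear"):
        if activation not in ("linear", "relu", "tanh"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.params = {"W": glorot_uniform(rng, n_in, n_out),
                       "b": np.zeros(n_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            y = np.maximum(z, 0.0)
        elif self.activation == "tanh":
            y = np.tanh(z)
        else:
            y = z
        self._cache = (x, z, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, z, y = self._cache
        if self.activation == "relu":
            dz = dy * (z > 0)
        elif self.activation == "tanh":
            dz = dy * (1 - y ** 2)
        else:
            dz = dy
        self.grads = {"W": x.T @ dz, "b": dz.sum(axis=0)}
        return dz @ self.params["W"].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, k) for l in self.layers for k in l.params]


class SGD:
    def __init__(self, model: Sequential, lr: float):
        self.model, self.lr = model, lr

    def step(self) -> None:
        for layer, key in self.model.parameters():
            layer.params[key] -= self.lr * layer.grads[key]


class Adam:
    def __init__(self, model: Sequential, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(l.params[k]) for l, k in model.parameters()]
        self.v = [np.zeros_like(l.params[k]) for l, k in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, key) in enumerate(self.model.parameters()):
            g = layer.grads[key]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
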