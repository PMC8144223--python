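"""Minimal NumPy neural-network layers for the peptide binder.

Implements exactly what the binder architecture needs — stacked
bidirectional LSTM layers, dense layers, inverted dropout, sigmoid output
with binary cross-entropy, and an Adam optimizer — with hand-written
backpropagation. All arithmetic is float64 and fully deterministic given a
seeded :class:`numpy.random.Generator`, so two builds from the same seed
produce bit-identical parameters and training logs.

Tensors are batch-major: sequences are ``(B, T, D)``, dense inputs
``(B, D)``. Gradient correctness is enforced by finite-difference checks in
the test suite rather than trusted by construction.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class LSTM:
    """Single-direction LSTM returning the full hidden sequence.

    Gate layout in the fused weight matrices is ``[i, f, g, o]``. The
    forget-gate bias is initialized to 1, the usual trick to keep memory
    open early in training.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.d_in, self.units = d_in, units
        u = units
        self.params = {
            "Wx": glorot(rng, (d_in, 4 * u)),
            "Wh": glorot(rng, (u, 4 * u)),
            "b": np.zeros(4 * u),
        }
        self.params["b"][u : 2 * u] = 1.0
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray):
        B, T, _ = x.shape
        u = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        hs = np.zeros((B, T, u))
        cache = []
        for t in range(T):
            z = x[:, t] @ Wx + h @ Wh + b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((x[:, t], h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        return hs, cache

    def backward(self, dhs: np.ndarray, cache) -> np.ndarray:
        B, T, _ = dhs.shape
        u = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros((B, T, self.d_in))
        dh_next = np.zeros((B, u))
        dc_next = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.grads["Wx"] += dWx
        self.grads["Wh"] += dWh
        self.grads["b"] += db
        return dx


class BiLSTM:
    """Bidirectional LSTM: forward and reversed passes concatenated per step.

    Output is ``(B, T, 2 * units)`` with the forward features in the first
    half of the last axis and the time-aligned backward features in the
    second half.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.fwd = LSTM(d_in, units, rng)
        self.bwd = LSTM(d_in, units, rng)

    @property
    def sublayers(self):
        return [self.fwd, self.bwd]

    def forward(self, x: np.ndarray):
        out_f, cache_f = self.fwd.forward(x)
        out_b_rev, cache_b = self.bwd.forward(x[:, ::-1])
        out = np.concatenate([out_f, out_b_rev[:, ::-1]], axis=2)
        return out, (cache_f, cache_b)

    def backward(self, dout: np.ndarray, cache) -> np.ndarray:
        cache_f, cache_b = cache
        u = self.units
        dx_f = self.fwd.backward(dout[:, :, :u], cache_f)
        dx_b = self.bwd.backward(dout[:, ::-1, u:], cache_b)
        return dx_f + dx_b[:, ::-1]


class Dense:
    def __init__(self, d_in: int, units: int, activation: str, rng: np.random.Generator):
        if activation not in ("relu", "sigmoid", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.params = {"W": glorot(rng, (d_in, units)), "b": np.zeros(units)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray):
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            a = np.maximum(z, 0.0)
        elif self.activation == "sigmoid":
            a = sigmoid(z)
        else:
            a = z
        return a, (x, z, a)

    def backward(self, da: np.ndarray, cache) -> np.ndarray:
        x, z, a = cache
        if self.activation == "relu":
            dz = da * (z > 0)
        elif self.activation == "sigmoid":
            dz = da * a * (1.0 - a)
        else:
            dz = da
        self.grads["W"] += x.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        return dz @ self.params["W"].T


class Dropout:
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        if not train or self.rate == 0.0:
            return x, None
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * mask, mask

    def backward(self, da: np.ndarray, mask) -> np.ndarray:
        return da if mask is None else da * mask


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class Adam:
    def __init__(self, param_layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [ly for ly in param_layers if hasattr(ly, "params")]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers
        ]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, g in ly.grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**self.t)
                vhat = v[k] / (1 - b2**self.t)
                ly.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for ly in self.layers:
            for k in ly.grads:
                ly.grads[k][:] = 0.0


class BinderNetwork:
    """One-hot input -> BiLSTM x3 -> dense/dropout/dense/dropout -> sigmoid head.

    The recurrent stack returns full sequences; the classifier head reads
    the concatenated final hidden states of the top layer (forward state at
    the last step, backward state at the first aligned step).
    """

    def __init__(self, L: int, d_in: int, lstm_units, dense_units, dropout_rates,
                 rng: np.random.Generator):
        if len(lstm_units) != 3:
            raise ValueError("exactly 3 bidirectional LSTM layers are required")
        if len(dense_units) != 3 or dense_units[-1] != 1:
            raise ValueError("dense_units must be a 3-tuple ending in the 1-unit head")
        if len(dropout_rates) != 2:
            raise ValueError("exactly 2 dropout slots are required")
        self.L = L
        self.lstm_units = tuple(lstm_units)
        self.rnn = []
        d = d_in
        for u in lstm_units:
            self.rnn.append(BiLSTM(d, u, rng))
            d = 2 * u
        self.dense1 = Dense(d, dense_units[0], "relu", rng)
        self.drop1 = Dropout(dropout_rates[0])
        self.dense2 = Dense(dense_units[0], dense_units[1], "relu", rng)
        self.drop2 = Dropout(dropout_rates[1])
        self.head = Dense(dense_units[1], 1, "sigmoid", rng)

    @property
    def param_layers(self):
        layers = []
        for bi in self.rnn:
            layers.extend(bi.sublayers)
        layers.extend([self.dense1, self.dense2, self.head])
        return layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Score a one-hot batch ``(B, L, 20)``; returns probabilities ``(B,)``."""
        caches = []
        out = x
        for bi in self.rnn:
            out, c = bi.forward(out)
            caches.append(c)
        u = self.lstm_units[-1]
        feat = np.concatenate([out[:, -1, :u], out[:, 0, u:]], axis=1)
        a1, c1 = self.dense1.forward(feat)
        d1, m1 = self.drop1.forward(a1, train, rng)
        a2, c2 = self.dense2.forward(d1)
        d2, m2 = self.drop2.forward(a2, train, rng)
        p, ch = self.head.forward(d2)
        cache = (caches, out.shape, c1, m1, c2, m2, ch)
        return p[:, 0], cache

    def backward(self, p: np.ndarray, y: np.ndarray, cache) -> None:
        """Accumulate gradients of mean BCE loss; pairs sigmoid+BCE analytically."""
        caches, out_shape, c1, m1, c2, m2, ch = cache
        B = p.shape[0]
        # d(loss)/d(z_head) = (p - y) / B; bypass head.backward's sigmoid term
        dz = ((p - y) / B)[:, None]
        x_h = ch[0]
        self.head.grads["W"] += x_h.T @ dz
        self.head.grads["b"] += dz.sum(axis=0)
        dd2 = dz @ self.head.params["W"].T
        da2 = self.drop2.backward(dd2, m2)
        dd1 = self.dense2.backward(da2, c2)
        da1 = self.drop1.backward(dd1, m1)
        dfeat = self.dense1.backward(da1, c1)
        u = self.lstm_units[-1]
        dout = np.zeros(out_shape)
        dout[:, -1, :u] = dfeat[:, :u]
        dout[:, 0, u:] = dfeat[:, u:]
        for bi, c in zip(reversed(self.rnn), reversed(caches)):
            dout = bi.backward(dout, c)

    # -- parameter (de)serialization -------------------------------------

    def get_weights(self) -> dict:
        out = {}
        for i, ly in enumerate(self.param_layers):
            for k, v in ly.params.items():
                out[f"layer{i}_{k}"] = v.copy()
        return out

    def set_weights(self, weights: dict) -> None:
        for i, ly in enumerate(self.param_layers):
            for k in ly.params:
                ly.params[k] = weights[f"layer{i}_{k}"].copy()
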