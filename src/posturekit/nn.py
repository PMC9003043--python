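"""A compact NumPy engine for sequence-to-sequence recurrent classifiers.

Implements exactly what the posture models need, nothing more: LSTM layers
(unidirectional and bidirectional), inverted dropout, time-distributed dense
layers, a softmax cross-entropy head emitting one class per frame, manual
backpropagation through time, global-norm gradient clipping and Adam.

Everything is driven by an explicit ``numpy.random.Generator``, so a fixed
seed gives a bit-identical training trajectory on one machine.  Parameters
are float32.

Conventions: batches are ``(N, T, D)`` (sequences, time steps, features);
per-frame targets are ``(N, T)`` integer class indices starting at 0.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigError

_DT = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # exp on clipped input avoids overflow warnings for saturated gates
    # (sentinel 999 inputs drive pre-activations far out)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, (fan_in, fan_out)).astype(_DT)


def orthogonal(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if n < m:
        q = q.T
    return q[:n, :m].astype(_DT)


class Layer:
    """Minimal layer protocol: forward caches, backward consumes them."""

    trainable: bool = True

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


class _LSTMCell:
    """One direction of an LSTM layer; gate order [i, f, g, o]."""

    def __init__(self, rng: np.random.Generator, input_dim: int, hidden: int):
        self.H = hidden
        self.Wx = np.concatenate(
            [glorot_uniform(rng, input_dim, hidden) for _ in range(4)], axis=1
        )
        self.Wh = np.concatenate(
            [orthogonal(rng, hidden, hidden) for _ in range(4)], axis=1
        )
        self.b = np.zeros(4 * hidden, dtype=_DT)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self._cache: list[tuple] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, T, _ = x.shape
        H = self.H
        h = np.zeros((N, H), dtype=_DT)
        c = np.zeros((N, H), dtype=_DT)
        out = np.empty((N, T, H), dtype=_DT)
        self._cache = []
        for t in range(T):
            xt = x[:, t, :]
            a = xt @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((xt, h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, t, :] = h
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, T, H = dout.shape
        dx = np.empty((N, T, self.Wx.shape[0]), dtype=_DT)
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dh_next = np.zeros((N, H), dtype=_DT)
        dc_next = np.zeros((N, H), dtype=_DT)
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dout[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dWx += xt.T @ da
            self.dWh += h_prev.T @ da
            self.db += da.sum(axis=0)
            dx[:, t, :] = da @ self.Wx.T
            dh_next = da @ self.Wh.T
        self._cache = []
        return dx

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.Wx, self.dWx), (self.Wh, self.dWh), (self.b, self.db)]


class LSTM(Layer):
    """Sequence-to-sequence LSTM layer, optionally bidirectional.

    A bidirectional layer runs a second cell over the time-reversed input
    and concatenates both passes per frame, doubling the output width.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        input_dim: int,
        hidden: int,
        bidirectional: bool = False,
    ):
        self.bidirectional = bidirectional
        self.fwd = _LSTMCell(rng, input_dim, hidden)
        self.bwd = _LSTMCell(rng, input_dim, hidden) if bidirectional else None
        self.output_dim = hidden * (2 if bidirectional else 1)

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        out_f = self.fwd.forward(x)
        if self.bwd is None:
            return out_f
        out_b = self.bwd.forward(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([out_f, out_b], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.bwd is None:
            return self.fwd.backward(dout)
        H = self.fwd.H
        dx = self.fwd.backward(np.ascontiguousarray(dout[:, :, :H]))
        dxb = self.bwd.backward(np.ascontiguousarray(dout[:, ::-1, H:]))
        return dx + dxb[:, ::-1, :]

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        pg = self.fwd.params_grads()
        if self.bwd is not None:
            pg += self.bwd.params_grads()
        return pg


class Dropout(Layer):
    """Inverted dropout on layer outputs; identity at inference."""

    trainable = False

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ConfigError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DT) / _DT(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    """Time-distributed affine layer with optional tanh activation."""

    def __init__(
        self, rng: np.random.Generator, input_dim: int, output_dim: int,
        activation: str | None = None,
    ):
        if activation not in (None, "tanh"):
            raise ConfigError(f"unsupported activation {activation!r}")
        self.W = glorot_uniform(rng, input_dim, output_dim)
        self.b = np.zeros(output_dim, dtype=_DT)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.activation = activation
        self.output_dim = output_dim
        self._x: np.ndarray | None = None
        self._a: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        self._x = x
        a = x @ self.W + self.b
        if self.activation == "tanh":
            a = np.tanh(a)
        self._a = a
        return a

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.activation == "tanh":
            dout = dout * (1.0 - self._a * self._a)
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.dW[...] = x2.T @ d2
        self.db[...] = d2.sum(axis=0)
        return dout @ self.W.T

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.W, self.dW), (self.b, self.db)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over all frames; returns (loss, dlogits)."""
    probs = softmax(logits.astype(np.float64))
    n = int(np.prod(targets.shape))
    flat = probs.reshape(n, -1)
    idx = np.arange(n)
    tgt = targets.reshape(n)
    loss = float(-np.mean(np.log(np.maximum(flat[idx, tgt], 1e-12))))
    dlogits = probs
    dflat = dlogits.reshape(n, -1)
    dflat[idx, tgt] -= 1.0
    dlogits = (dlogits / n).astype(_DT)
    return loss, dlogits


class SequenceNet:
    """A stack of layers ending in per-frame class logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        out = x.astype(_DT, copy=False)
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(layer.params_grads())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params_grads())


def clip_global_norm(params_grads: list[tuple[np.ndarray, np.ndarray]], max_norm: float) -> float:
    total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for _, g in params_grads))
    if max_norm > 0 and total > max_norm:
        scale = _DT(max_norm / (total + 1e-12))
        for _, g in params_grads:
            g *= scale
    return float(total)


class Adam:
    """Adam with bias correction, operating on the net's (param, grad) pairs."""

    def __init__(self, net: SequenceNet, lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        pg = net.params_grads()
        self.m = [np.zeros_like(p) for p, _ in pg]
        self.v = [np.zeros_like(p) for p, _ in pg]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for k, (p, g) in enumerate(self.net.params_grads()):
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * (g * g)
            p -= (lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)).astype(_DT)


# ---------------------------------------------------------------------------
# Architecture assembly
# ---------------------------------------------------------------------------

#: The explored sequence-network family.  Naming: a leading 2 = two recurrent
#: layers; B = bidirectional; trailing 2D/1D = number of dropout layers;
#: LSTM2FC = one LSTM layer followed by two fully connected layers.
VARIANTS = ("LSTM", "LSTM2FC", "2LSTM", "BLSTM", "2BLSTM", "2BLSTM2D", "2BLSTM1D")


def build_variant(
    variant: str,
    rng: np.random.Generator,
    input_dim: int,
    n_classes: int,
    hidden1: int,
    hidden2: int,
    dropout: float,
    dropout2: float | None = None,
) -> SequenceNet:
    """Assemble a sequence network of the named family member.

    Single-recurrent-layer variants place one dropout after their LSTM;
    two-layer variants place dropout per their suffix (2BLSTM and 2BLSTM2D:
    one after each recurrent layer; 2BLSTM1D: a single one after the second).
    The head is always a time-distributed dense layer producing one logit
    vector per frame (softmax applied by the loss / at prediction).
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    d2 = dropout if dropout2 is None else dropout2
    L: list[Layer] = []
    if variant == "LSTM":
        lstm = LSTM(rng, input_dim, hidden1)
        L = [lstm, Dropout(dropout), Dense(rng, lstm.output_dim, n_classes)]
    elif variant == "LSTM2FC":
        lstm = LSTM(rng, input_dim, hidden1)
        L = [
            lstm,
            Dropout(dropout),
            Dense(rng, lstm.output_dim, hidden2, activation="tanh"),
            Dense(rng, hidden2, n_classes),
        ]
    elif variant == "2LSTM":
        l1 = LSTM(rng, input_dim, hidden1)
        l2 = LSTM(rng, l1.output_dim, hidden2)
        L = [l1, Dropout(dropout), l2, Dropout(d2), Dense(rng, l2.output_dim, n_classes)]
    elif variant == "BLSTM":
        l1 = LSTM(rng, input_dim, hidden1, bidirectional=True)
        L = [l1, Dropout(dropout), Dense(rng, l1.output_dim, n_classes)]
    elif variant in ("2BLSTM", "2BLSTM2D"):
        l1 = LSTM(rng, input_dim, hidden1, bidirectional=True)
        l2 = LSTM(rng, l1.output_dim, hidden2, bidirectional=True)
        L = [l1, Dropout(dropout), l2, Dropout(d2), Dense(rng, l2.output_dim, n_classes)]
    elif variant == "2BLSTM1D":
        l1 = LSTM(rng, input_dim, hidden1, bidirectional=True)
        l2 = LSTM(rng, l1.output_dim, hidden2, bidirectional=True)
        L = [l1, l2, Dropout(dropout), Dense(rng, l2.output_dim, n_classes)]
    return SequenceNet(L)
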