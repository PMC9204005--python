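"""Minimal NumPy neural-network layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients in ``Parameter.grad`` during ``backward``.
Batched inputs are (batch, positions, features). All randomness (init,
dropout masks) flows through explicitly passed ``numpy.random.Generator``s,
so runs are reproducible from a single seed in single-threaded mode.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit as sigmoid


class Parameter:
    __slots__ = ("name", "value", "grad")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def shape(self):
        return self.value.shape


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear:
    """y = x @ W + b on the trailing axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "linear"):
        self.W = Parameter(glorot_uniform(rng, in_dim, out_dim, (in_dim, out_dim), dtype), f"{name}.W")
        self.b = Parameter(np.zeros(out_dim, dtype=dtype), f"{name}.b")
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return g @ self.W.value.T


class Conv1d:
    """Same-padded 1-D convolution along the position axis.

    With kernel size 5, padding 2, stride 1 the output has exactly as many
    positions as the input, which is what lets downstream layers treat
    feature rows as sequence positions.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int, rng: np.random.Generator, dtype=np.float32,
                 name: str = "conv"):
        if kernel_size < 1 or padding < 0:
            raise ValueError("kernel_size must be >= 1 and padding >= 0")
        self.kernel_size = kernel_size
        self.padding = padding
        self.in_channels = in_channels
        fan_in = kernel_size * in_channels
        self.W = Parameter(
            glorot_uniform(rng, fan_in, out_channels, (fan_in, out_channels), dtype),
            f"{name}.W",
        )
        self.b = Parameter(np.zeros(out_channels, dtype=dtype), f"{name}.b")
        self._cols: np.ndarray | None = None
        self._in_positions = 0

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        K, P = self.kernel_size, self.padding
        if T + 2 * P < K:
            raise ValueError(f"{T} positions with padding {P} cannot fit kernel {K}")
        self._in_positions = T
        xp = np.pad(x, ((0, 0), (P, P), (0, 0))) if P else x
        # (B, T_out, C, K) windows -> (B, T_out, C*K) columns
        win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
        cols = win.reshape(B, win.shape[1], C * K)
        self._cols = cols
        return cols @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, T_out, _ = g.shape
        K, P, C = self.kernel_size, self.padding, self.in_channels
        cols2 = self._cols.reshape(-1, C * K)
        g2 = g.reshape(-1, g.shape[-1])
        self.W.grad += cols2.T @ g2
        self.b.grad += g2.sum(axis=0)
        dcols = (g @ self.W.value.T).reshape(B, T_out, C, K)
        dxp = np.zeros((B, self._in_positions + 2 * P, C), dtype=g.dtype)
        for j in range(K):
            dxp[:, j:j + T_out, :] += dcols[:, :, :, j]
        return dxp[:, P:P + self._in_positions, :] if P else dxp


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0)


class Dropout:
    """Inverted dropout; identity when not training."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1 - self.rate)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


@dataclasses.dataclass
class LSTMParams:
    """The eight weight matrices and four biases of one LSTM direction.

    ``W_x*`` are (input_size, hidden), ``W_h*`` are (hidden, hidden); inputs
    multiply on the left (x @ W).
    """

    W_xf: np.ndarray; W_hf: np.ndarray
    W_xi: np.ndarray; W_hi: np.ndarray
    W_xc: np.ndarray; W_hc: np.ndarray
    W_xo: np.ndarray; W_ho: np.ndarray
    b_f: np.ndarray; b_i: np.ndarray; b_c: np.ndarray; b_o: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_hf.shape[0]


@dataclasses.dataclass
class LSTMState:
    c: np.ndarray
    h: np.ndarray


def lstm_step(x_t: np.ndarray, state: LSTMState, params: LSTMParams) -> LSTMState:
    """One LSTM cell update:

        f = sigmoid(x W_xf + h W_hf + b_f)        (forget gate)
        i = sigmoid(x W_xi + h W_hi + b_i)        (input gate)
        c = f * c_prev + i * tanh(x W_xc + h W_hc + b_c)
        o = sigmoid(x W_xo + h W_ho + b_o)        (output gate)
        h = o * tanh(c)
    """
    x_t, h_prev, c_prev = np.asarray(x_t), state.h, state.c
    f = sigmoid(x_t @ params.W_xf + h_prev @ params.W_hf + params.b_f)
    i = sigmoid(x_t @ params.W_xi + h_prev @ params.W_hi + params.b_i)
    g = np.tanh(x_t @ params.W_xc + h_prev @ params.W_hc + params.b_c)
    o = sigmoid(x_t @ params.W_xo + h_prev @ params.W_ho + params.b_o)
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return LSTMState(c=c, h=h)


# gate stacking order used by the batched implementation (the three sigmoid
# gates first so one vectorised sigmoid covers them)
_GATES = ("f", "i", "o", "c")


class LSTM:
    """One direction of a batched LSTM, unrolled over the position axis."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "lstm"):
        self.input_size = input_size
        self.hidden_size = hidden_size
        H = hidden_size
        self._p: dict[str, Parameter] = {}
        for gate in _GATES:
            self._p[f"W_x{gate}"] = Parameter(
                glorot_uniform(rng, input_size, H, (input_size, H), dtype), f"{name}.W_x{gate}")
            self._p[f"W_h{gate}"] = Parameter(
                glorot_uniform(rng, H, H, (H, H), dtype), f"{name}.W_h{gate}")
            self._p[f"b_{gate}"] = Parameter(np.zeros(H, dtype=dtype), f"{name}.b_{gate}")
        self._cache: dict | None = None

    def parameters(self) -> list[Parameter]:
        return list(self._p.values())

    @property
    def params(self) -> LSTMParams:
        v = {k: p.value for k, p in self._p.items()}
        return LSTMParams(**v)

    def _stacked(self):
        Wx = np.concatenate([self._p[f"W_x{g}"].value for g in _GATES], axis=1)
        Wh = np.concatenate([self._p[f"W_h{g}"].value for g in _GATES], axis=1)
        b = np.concatenate([self._p[f"b_{g}"].value for g in _GATES])
        return Wx, Wh, b

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, LSTMState]:
        """x: (B, T, input_size) -> hidden sequence (B, T, H) and final state."""
        B, T, _ = x.shape
        H = self.hidden_size
        Wx, Wh, b = self._stacked()
        x_proj = x @ Wx + b                     # (B, T, 4H)

        f = np.empty((B, T, H), dtype=x.dtype); i = np.empty_like(f)
        g = np.empty_like(f); o = np.empty_like(f)
        c = np.empty_like(f); h = np.empty_like(f)
        h_t = np.zeros((B, H), dtype=x.dtype)
        c_t = np.zeros((B, H), dtype=x.dtype)
        for t in range(T):
            a = x_proj[:, t] + h_t @ Wh
            gates = sigmoid(a[:, :3 * H])
            f_t, i_t, o_t = gates[:, :H], gates[:, H:2 * H], gates[:, 2 * H:]
            g_t = np.tanh(a[:, 3 * H:])
            c_t = f_t * c_t + i_t * g_t
            h_t = o_t * np.tanh(c_t)
            f[:, t], i[:, t], g[:, t], o[:, t], c[:, t], h[:, t] = f_t, i_t, g_t, o_t, c_t, h_t
        self._cache = {"x": x, "f": f, "i": i, "g": g, "o": o, "c": c, "h": h}
        return h, LSTMState(c=c_t, h=h_t)

    def backward(self, g_h: np.ndarray, g_hn: np.ndarray | None = None,
                 g_cn: np.ndarray | None = None) -> np.ndarray:
        """Backprop through time. ``g_h`` is (B, T, H); optional gradients on
        the final hidden/cell state. Returns the gradient on the input."""
        cch = self._cache
        x, f, i, g, o, c, h = (cch[k] for k in ("x", "f", "i", "g", "o", "c", "h"))
        B, T, H = f.shape
        Wx, Wh, _ = self._stacked()

        dA = np.empty((B, T, 4 * H), dtype=x.dtype)
        dh_next = np.zeros((B, H), dtype=x.dtype) if g_hn is None else g_hn.astype(x.dtype)
        dc_next = np.zeros((B, H), dtype=x.dtype) if g_cn is None else g_cn.astype(x.dtype)
        for t in range(T - 1, -1, -1):
            dh = g_h[:, t] + dh_next
            tanh_c = np.tanh(c[:, t])
            dc = dh * o[:, t] * (1 - tanh_c ** 2) + dc_next
            c_prev = c[:, t - 1] if t > 0 else np.zeros((B, H), dtype=x.dtype)
            dc_next = dc * f[:, t]
            dA_t = dA[:, t]
            dA_t[:, :H] = dc * c_prev * f[:, t] * (1 - f[:, t])
            dA_t[:, H:2 * H] = dc * g[:, t] * i[:, t] * (1 - i[:, t])
            dA_t[:, 2 * H:3 * H] = dh * tanh_c * o[:, t] * (1 - o[:, t])
            dA_t[:, 3 * H:] = dc * i[:, t] * (1 - g[:, t] ** 2)
            dh_next = dA_t @ Wh.T

        h_prev = np.concatenate([np.zeros((B, 1, H), dtype=x.dtype), h[:, :-1]], axis=1)
        dWx = x.reshape(-1, x.shape[-1]).T @ dA.reshape(-1, 4 * H)
        dWh = h_prev.reshape(-1, H).T @ dA.reshape(-1, 4 * H)
        db = dA.reshape(-1, 4 * H).sum(axis=0)
        for j, gate in enumerate(_GATES):
            sl = slice(j * H, (j + 1) * H)
            self._p[f"W_x{gate}"].grad += dWx[:, sl]
            self._p[f"W_h{gate}"].grad += dWh[:, sl]
            self._p[f"b_{gate}"].grad += db[sl]
        return dA @ Wx.T


class BiLSTM:
    """Forward + backward LSTM over positions; per-position outputs merged by
    element-wise sum (default) or concatenation."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 merge: str = "sum", dtype=np.float32, name: str = "bilstm"):
        if merge not in ("sum", "concat"):
            raise ValueError(f"merge must be 'sum' or 'concat', got {merge!r}")
        self.merge = merge
        self.hidden_size = hidden_size
        self.fwd = LSTM(input_size, hidden_size, rng, dtype, f"{name}.fwd")
        self.bwd = LSTM(input_size, hidden_size, rng, dtype, f"{name}.bwd")

    @property
    def output_size(self) -> int:
        return self.hidden_size * (2 if self.merge == "concat" else 1)

    def parameters(self) -> list[Parameter]:
        return self.fwd.parameters() + self.bwd.parameters()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns merged per-position features (B, T, output_size) and the
        merged final hidden state h_n (B, output_size)."""
        h_f, st_f = self.fwd.forward(x)
        h_b_rev, st_b = self.bwd.forward(x[:, ::-1].copy())
        h_b = h_b_rev[:, ::-1]
        if self.merge == "sum":
            return h_f + h_b, st_f.h + st_b.h
        return np.concatenate([h_f, h_b], axis=2), np.concatenate([st_f.h, st_b.h], axis=1)

    def backward(self, g_merged: np.ndarray, g_hn: np.ndarray | None = None) -> np.ndarray:
        H = self.hidden_size
        if self.merge == "sum":
            g_f, g_b = g_merged, g_merged
            g_hn_f = g_hn_b = g_hn
        else:
            g_f, g_b = g_merged[..., :H], g_merged[..., H:]
            g_hn_f = g_hn[..., :H] if g_hn is not None else None
            g_hn_b = g_hn[..., H:] if g_hn is not None else None
        dx = self.fwd.backward(np.ascontiguousarray(g_f), g_hn_f)
        dx_b = self.bwd.backward(np.ascontiguousarray(g_b[:, ::-1]), g_hn_b)
        return dx + dx_b[:, ::-1]


class Attention:
    """Soft attention over positions:

        M = tanh(H),  alpha = softmax(omega^T M),  gamma = H alpha^T,
        h* = tanh(gamma)

    ``omega`` is the single trained attention vector; its dimension equals the
    per-position feature dimension.
    """

    def __init__(self, dim: int, rng: np.random.Generator, dtype=np.float32,
                 name: str = "attention"):
        self.dim = dim
        self.omega = Parameter(glorot_uniform(rng, dim, 1, (dim,), dtype), f"{name}.omega")
        self._cache: dict | None = None

    def parameters(self) -> list[Parameter]:
        return [self.omega]

    def forward(self, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """P: (B, T, dim). Returns context h* (B, dim) and weights alpha (B, T)."""
        M = np.tanh(P)
        scores = M @ self.omega.value                     # (B, T)
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        alpha = e / e.sum(axis=1, keepdims=True)
        gamma = np.einsum("bt,btd->bd", alpha, P)
        h_star = np.tanh(gamma)
        self._cache = {"P": P, "M": M, "alpha": alpha, "h_star": h_star}
        return h_star, alpha

    def backward(self, g_hstar: np.ndarray) -> np.ndarray:
        cch = self._cache
        P, M, alpha, h_star = cch["P"], cch["M"], cch["alpha"], cch["h_star"]
        dgamma = g_hstar * (1 - h_star ** 2)                       # (B, d)
        dalpha = np.einsum("btd,bd->bt", P, dgamma)
        dP = alpha[:, :, None] * dgamma[:, None, :]
        ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        self.omega.grad += np.einsum("btd,bt->d", M, ds)
        dP += ds[:, :, None] * (1 - M ** 2) * self.omega.value[None, None, :]
        return dP


def bce_loss(predictions: np.ndarray, targets: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy; probabilities are clipped to [eps, 1-eps]
    because the loss is undefined at exactly 0 or 1."""
    x = np.clip(np.asarray(predictions, dtype=np.float64), eps, 1 - eps)
    y = np.asarray(targets, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"prediction shape {x.shape} != target shape {y.shape}")
    return float(-np.mean(y * np.log(x) + (1 - y) * np.log(1 - x)))


def bce_grad_wrt_logits(probs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Gradient of mean BCE w.r.t. pre-sigmoid logits: (p - y) / N."""
    probs = np.asarray(probs)
    return (probs - np.asarray(targets, dtype=probs.dtype)) / probs.shape[0]


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, parameters: list[Parameter], learning_rate: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.parameters = parameters
        self.learning_rate = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.value, dtype=np.float64) for p in parameters]
        self._v = [np.zeros_like(p.value, dtype=np.float64) for p in parameters]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad[...] = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self._t
        bias2 = 1 - b2 ** self._t
        for p, m, v in zip(self.parameters, self._m, self._v):
            g = p.grad.astype(np.float64)
            m *= b1; m += (1 - b1) * g
            v *= b2; v += (1 - b2) * g * g
            update = self.learning_rate * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            p.value -= update.astype(p.value.dtype)
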