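"""The TFBS classifier network: CNN feature extractor, bidirectional LSTM,
soft attention, and a sigmoid dense head, plus the two ablation variants
(CNN-BiLSTM without attention; BiLSTM-attention without the CNN).

Default hyperparameters per architecture:

    architecture     cnn layers  kernel  hidden  attention  dense  dropout
    cnn_bilstm_att   2           5       16      16         16     0.2
    cnn_bilstm       2           5       16      -          32     0.2
    bilstm_att       -           -       32      32         32     0.2

with learning rate 0.001, 20 epochs, batch size 64 throughout. Convolutions
use kernel 5 / padding 2 / stride 1, which preserves the number of sequence
positions, so the BiLSTM and attention always see one feature row per k-mer
position.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _nn
from ._nn import (  # noqa: F401  (re-exported building blocks)
    Adam,
    Attention,
    BiLSTM,
    Conv1d,
    Dropout,
    Linear,
    LSTM,
    LSTMParams,
    LSTMState,
    Parameter,
    ReLU,
    bce_loss,
    lstm_step,
    sigmoid,
)

ARCHITECTURES = ("cnn_bilstm_att", "cnn_bilstm", "bilstm_att")

_ARCH_DEFAULTS = {
    "cnn_bilstm_att": dict(bilstm_hidden=16, attention_dim=16, dense_neurons=16),
    "cnn_bilstm": dict(bilstm_hidden=16, attention_dim=None, dense_neurons=32),
    "bilstm_att": dict(bilstm_hidden=32, attention_dim=32, dense_neurons=32),
}


class ConfigurationError(ValueError):
    """Raised for inconsistent model specifications."""


class ContractError(RuntimeError):
    """Raised when an operation is requested from an architecture lacking it."""


@dataclasses.dataclass
class ModelSpec:
    """One validated record of architecture variant plus all hyperparameters."""

    architecture: str = "cnn_bilstm_att"
    cnn_layers: int = 2
    kernel_size: int = 5
    padding: int = 2
    stride: int = 1
    cnn_channels: int = 64
    bilstm_hidden: int | None = None
    attention_dim: int | None = None
    dense_neurons: int | None = None
    dropout: float = 0.2
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 64
    merge: str = "sum"

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(
                f"architecture must be one of {ARCHITECTURES}, got {self.architecture!r}"
            )
        defaults = _ARCH_DEFAULTS[self.architecture]
        if self.bilstm_hidden is None:
            self.bilstm_hidden = defaults["bilstm_hidden"]
        if self.attention_dim is None and self.has_attention:
            self.attention_dim = defaults["attention_dim"]
        if self.dense_neurons is None:
            self.dense_neurons = defaults["dense_neurons"]
        for key in ("cnn_layers", "kernel_size", "cnn_channels", "bilstm_hidden",
                    "dense_neurons", "epochs", "batch_size"):
            if getattr(self, key) is not None and getattr(self, key) < 1:
                raise ConfigurationError(f"{key} must be positive, got {getattr(self, key)}")
        if self.padding < 0:
            raise ConfigurationError(f"padding must be >= 0, got {self.padding}")
        if self.stride != 1:
            raise ConfigurationError("only stride 1 (length-preserving) is supported")
        if not 0 <= self.dropout < 1:
            raise ConfigurationError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.learning_rate <= 0:
            raise ConfigurationError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.merge not in ("sum", "concat"):
            raise ConfigurationError(f"merge must be 'sum' or 'concat', got {self.merge!r}")

    @property
    def has_attention(self) -> bool:
        return self.architecture in ("cnn_bilstm_att", "bilstm_att")

    @property
    def has_cnn(self) -> bool:
        return self.architecture in ("cnn_bilstm_att", "cnn_bilstm")


@dataclasses.dataclass
class AttentionOutput:
    """Per-position attention distribution and the tanh-squashed context vector."""

    alpha: np.ndarray
    context: np.ndarray


def attention_forward(H: np.ndarray, params: Attention) -> AttentionOutput:
    """Soft attention on a single window in the (d_w, T) orientation:
    M = tanh(H); alpha = softmax(omega^T M); gamma = H alpha^T; h* = tanh(gamma)."""
    H = np.asarray(H)
    if H.ndim != 2 or H.shape[0] != params.dim:
        raise ConfigurationError(f"H must be (d_w={params.dim}, T), got {H.shape}")
    h_star, alpha = params.forward(H.T[None])
    return AttentionOutput(alpha=alpha[0], context=h_star[0])


class DeepARCNetwork:
    """The composed network for one embedding variant.

    ``forward`` consumes precomputed static inputs: for the positional
    variant the (B, T, 4^k) k-mer one-hot half plus the raw (B, T, d)
    distributed vectors (reduced to 4^k by the jointly trained width-1
    convolution); for the pure distributed variant the raw vectors alone;
    for one-hot variants the one-hot matrix itself.
    """

    def __init__(self, spec: ModelSpec, embedding_variant: str, input_static_dim: int,
                 vector_dim: int | None = None, k: int = 3,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if embedding_variant not in ("onehot_base", "onehot_kmer", "dna2vec", "positional"):
            raise ConfigurationError(f"unknown embedding variant {embedding_variant!r}")
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        self.embedding_variant = embedding_variant
        self.dtype = dtype
        n4k = 4 ** k

        self.reducer: Linear | None = None
        if embedding_variant in ("dna2vec", "positional"):
            if vector_dim is None:
                raise ConfigurationError("vector_dim required for distributed variants")
            self.reducer = Linear(vector_dim, n4k, rng, dtype, "reducer")
            feat = n4k + (input_static_dim if embedding_variant == "positional" else 0)
        else:
            feat = input_static_dim

        self.cnn: list = []
        if spec.has_cnn:
            in_ch = feat
            for layer in range(spec.cnn_layers):
                self.cnn.append(Conv1d(in_ch, spec.cnn_channels, spec.kernel_size,
                                       spec.padding, rng, dtype, f"conv{layer + 1}"))
                self.cnn.append(ReLU())
                in_ch = spec.cnn_channels
            bilstm_in = spec.cnn_channels
        else:
            bilstm_in = feat

        self.bilstm = BiLSTM(bilstm_in, spec.bilstm_hidden, rng, spec.merge, dtype)
        self.attention: Attention | None = None
        if spec.has_attention:
            if spec.attention_dim != self.bilstm.output_size:
                raise ConfigurationError(
                    f"attention_dim {spec.attention_dim} must equal the merged BiLSTM "
                    f"output size {self.bilstm.output_size} (merge={spec.merge!r})"
                )
            self.attention = Attention(spec.attention_dim, rng, dtype)
        self.dense1 = Linear(self.bilstm.output_size, spec.dense_neurons, rng, dtype, "dense1")
        self.dropout = Dropout(spec.dropout)
        self.dense2 = Linear(spec.dense_neurons, 1, rng, dtype, "dense2")
        self._cache: dict = {}

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        if self.reducer is not None:
            out += self.reducer.parameters()
        for layer in self.cnn:
            out += layer.parameters()
        out += self.bilstm.parameters()
        if self.attention is not None:
            out += self.attention.parameters()
        out += self.dense1.parameters() + self.dropout.parameters() + self.dense2.parameters()
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]

    # -- forward / backward -------------------------------------------------
    def assemble_input(self, x_static: np.ndarray | None,
                       x_vec: np.ndarray | None) -> np.ndarray:
        if self.reducer is not None:
            if x_vec is None:
                raise ConfigurationError("this variant needs distributed vectors")
            reduced = self.reducer.forward(x_vec.astype(self.dtype, copy=False))
            if self.embedding_variant == "positional":
                return np.concatenate(
                    [x_static.astype(self.dtype, copy=False), reduced], axis=2)
            return reduced
        return x_static.astype(self.dtype, copy=False)

    def forward(self, x_static: np.ndarray | None, x_vec: np.ndarray | None = None,
                training: bool = False, rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, np.ndarray | None]:
        """Returns probabilities (B,) and attention weights (B, T) or None."""
        x = self.assemble_input(x_static, x_vec)
        self._cache["static_dim"] = 0 if x_static is None or self.reducer is None \
            else (x_static.shape[2] if self.embedding_variant == "positional" else 0)
        for layer in self.cnn:
            x = layer.forward(x)
        self._cache["T"] = x.shape[1]
        p_seq, h_n = self.bilstm.forward(x)
        if self.attention is not None:
            h, alpha = self.attention.forward(p_seq)
            self._cache["used_attention"] = True
        else:
            h, alpha = h_n, None
            self._cache["used_attention"] = False
        z = self.dense1.forward(h)
        z = self.dropout.forward(z, training=training, rng=rng)
        logits = self.dense2.forward(z)[:, 0]
        probs = sigmoid(logits)
        return probs, alpha

    def backward(self, g_logits: np.ndarray) -> None:
        g = self.dense2.backward(g_logits[:, None])
        g = self.dropout.backward(g)
        g_h = self.dense1.backward(g)
        if self._cache["used_attention"]:
            g_seq = self.attention.backward(g_h)
            g_hn = None
        else:
            # gradient flows only through the final hidden state h_n
            g_seq = np.zeros((g_h.shape[0], self._cache["T"], self.bilstm.output_size),
                             dtype=g_h.dtype)
            g_hn = g_h
        g = self.bilstm.backward(g_seq, g_hn)
        for layer in reversed(self.cnn):
            g = layer.backward(g)
        if self.reducer is not None:
            sd = self._cache["static_dim"]
            self.reducer.backward(g[..., sd:])

    def attention_weights_required(self) -> None:
        if self.attention is None:
            raise ContractError(
                f"architecture {self.spec.architecture!r} has no attention mechanism"
            )
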