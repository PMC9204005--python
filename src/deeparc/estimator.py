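"""Scikit-learn style estimator around the CNN-BiLSTM-attention network.

``DeepARCClassifier`` consumes raw DNA window strings, handles the embedding
variant internally (training its own skip-gram k-mer vectors when needed),
and exposes the usual ``fit`` / ``predict`` / ``predict_proba`` surface plus
``attention`` for per-position interpretability.
"""

from __future__ import annotations

import zlib

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .embedding import (
    EMBEDDING_VARIANTS,
    EmbeddingInputError,
    KmerVectorTable,
    train_kmer_vectors,
)
from .network import Adam, ConfigurationError, DeepARCNetwork, ModelSpec
from .sequences import DNA_ALPHABET

_CODE = np.full(256, -2, dtype=np.int8)
for _i, _c in enumerate(DNA_ALPHABET):
    _CODE[ord(_c)] = _i
_CODE[ord("N")] = -1


def derive_seed(seed: int, component: str) -> int:
    """Fan a single user seed out to per-component seeds (stable across runs)."""
    return (int(seed) ^ zlib.crc32(component.encode())) % (2 ** 31)


def _codes(sequences: list[str], allow_n: bool) -> np.ndarray:
    """(N, L) int8 base codes; A,C,G,T -> 0..3, N -> -1 (if allowed)."""
    if not sequences:
        raise EmbeddingInputError("empty sequence set")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise EmbeddingInputError("all windows must share one length")
    raw = np.frombuffer("".join(sequences).upper().encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw].reshape(len(sequences), L)
    if (codes == -2).any():
        i, j = np.argwhere(codes == -2)[0]
        raise EmbeddingInputError(
            f"illegal character {sequences[i][j]!r} at position {j} of window {i}"
        )
    if not allow_n and (codes == -1).any():
        i, j = np.argwhere(codes == -1)[0]
        raise EmbeddingInputError(
            f"ambiguous base 'N' at position {j} of window {i}; set allow_n=True "
            "to map N-containing k-mers to zero vectors"
        )
    return codes


def _kmer_indices(codes: np.ndarray, k: int) -> np.ndarray:
    """(N, L-k+1) lexicographic k-mer indices; -1 where the k-mer contains N."""
    N, L = codes.shape
    if L < k:
        raise EmbeddingInputError(f"window length {L} < k={k}")
    win = np.lib.stride_tricks.sliding_window_view(codes, k, axis=1)  # (N, T, k)
    powers = 4 ** np.arange(k - 1, -1, -1)
    idx = (np.where(win < 0, 0, win) * powers).sum(axis=2)
    idx[(win < 0).any(axis=2)] = -1
    return idx


def _onehot_from_indices(idx: np.ndarray, size: int, dtype=np.float32) -> np.ndarray:
    out = np.zeros(idx.shape + (size,), dtype=dtype)
    valid = idx >= 0
    n, t = np.nonzero(valid)
    out[n, t, idx[valid]] = 1
    return out


class DeepARCClassifier(ClassifierMixin, BaseEstimator):
    """TFBS window classifier: positional k-mer embedding into a CNN-BiLSTM
    network with soft attention and a sigmoid dense head.

    Parameters follow the reference configuration for this model family: two length-preserving conv+ReLU
    blocks (kernel 5, padding 2, stride 1), BiLSTM hidden size 16, attention
    vector size 16, dense width 16, dropout 0.2 between the two dense layers,
    Adam with learning rate 0.001, 20 epochs, batch size 64. ``architecture``
    selects the ablations (``cnn_bilstm`` drops attention and classifies from
    the final BiLSTM hidden state; ``bilstm_att`` drops the CNN).

    ``embedding`` selects the input representation: ``positional`` (k-mer
    one-hot concatenated with reduced distributed vectors, 2*4^k features per
    position), ``onehot_kmer``, ``onehot_base`` or ``dna2vec``. Distributed
    vectors are trained on the fitting sequences with skip-gram + negative
    sampling unless ``kmer_vectors`` supplies a pretrained table.

    Attributes set by :meth:`fit` (trailing underscore) include ``classes_``,
    ``network_``, ``kmer_table_``, ``history_`` (per-epoch train/validation
    loss) and ``best_epoch_`` (the checkpoint with lowest validation loss,
    restored before prediction).
    """

    _estimator_type = "classifier"

    def __init__(self, architecture: str = "cnn_bilstm_att",
                 embedding: str = "positional", k: int = 3,
                 vector_dim: int = 100, sg_window: int = 5, sg_epochs: int = 3,
                 kmer_vectors: KmerVectorTable | None = None,
                 cnn_layers: int = 2, kernel_size: int = 5, padding: int = 2,
                 stride: int = 1, cnn_channels: int = 64,
                 bilstm_hidden: int | None = None, attention_dim: int | None = None,
                 dense_neurons: int | None = None, dropout: float = 0.2,
                 merge: str = "sum", learning_rate: float = 0.001, epochs: int = 20,
                 batch_size: int = 64, lr_step: int = 20, lr_gamma: float = 0.1,
                 validation_fraction: float = 0.1, threshold: float = 0.5,
                 allow_n: bool = False, random_state: int = 0):
        self.architecture = architecture
        self.embedding = embedding
        self.k = k
        self.vector_dim = vector_dim
        self.sg_window = sg_window
        self.sg_epochs = sg_epochs
        self.kmer_vectors = kmer_vectors
        self.cnn_layers = cnn_layers
        self.kernel_size = kernel_size
        self.padding = padding
        self.stride = stride
        self.cnn_channels = cnn_channels
        self.bilstm_hidden = bilstm_hidden
        self.attention_dim = attention_dim
        self.dense_neurons = dense_neurons
        self.dropout = dropout
        self.merge = merge
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_step = lr_step
        self.lr_gamma = lr_gamma
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.allow_n = allow_n
        self.random_state = random_state

    # -- encoding -----------------------------------------------------------
    def _encode(self, sequences: list[str]) -> tuple[np.ndarray | None, np.ndarray | None]:
        codes = _codes(sequences, self.allow_n)
        if self.embedding == "onehot_base":
            oh = _onehot_from_indices(np.where(codes < 0, -1, codes).astype(np.int64), 4)
            return oh, None
        idx = _kmer_indices(codes, self.k)
        if self.embedding == "onehot_kmer":
            return _onehot_from_indices(idx, 4 ** self.k), None
        vecs = self.kmer_table_.vectors.astype(np.float32)
        x_vec = np.where((idx >= 0)[:, :, None],
                         vecs[np.where(idx < 0, 0, idx)], np.float32(0))
        if self.embedding == "dna2vec":
            return None, x_vec
        return _onehot_from_indices(idx, 4 ** self.k), x_vec

    def _model_spec(self) -> ModelSpec:
        return ModelSpec(
            architecture=self.architecture, cnn_layers=self.cnn_layers,
            kernel_size=self.kernel_size, padding=self.padding, stride=self.stride,
            cnn_channels=self.cnn_channels, bilstm_hidden=self.bilstm_hidden,
            attention_dim=self.attention_dim, dense_neurons=self.dense_neurons,
            dropout=self.dropout, learning_rate=self.learning_rate,
            epochs=self.epochs, batch_size=self.batch_size, merge=self.merge,
        )

    @staticmethod
    def _as_sequences(X) -> list[str]:
        if hasattr(X, "sequences"):
            return list(X.sequences())
        return [str(s) for s in np.asarray(X, dtype=object).ravel()]

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y, validation_data: tuple | None = None) -> "DeepARCClassifier":
        """Fit on DNA window strings ``X`` and binary labels ``y``.

        ``validation_data=(X_val, y_val)`` supplies an explicit validation
        set for epoch checkpointing; otherwise ``validation_fraction`` of the
        training data is held out (stratified).
        """
        if self.embedding not in EMBEDDING_VARIANTS:
            raise ConfigurationError(
                f"embedding must be one of {EMBEDDING_VARIANTS}, got {self.embedding!r}")
        seqs = self._as_sequences(X)
        y = np.asarray(y).astype(np.int64).ravel()
        if len(seqs) != len(y):
            raise ValueError(f"{len(seqs)} sequences but {len(y)} labels")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(seqs[0])

        seed = int(self.random_state)
        init_rng = np.random.default_rng(derive_seed(seed, "init"))
        shuffle_rng = np.random.default_rng(derive_seed(seed, "shuffle"))
        dropout_rng = np.random.default_rng(derive_seed(seed, "dropout"))

        # hold out a validation set before anything is trained on it
        if validation_data is not None:
            val_seqs = self._as_sequences(validation_data[0])
            y_val = np.asarray(validation_data[1]).astype(np.int64).ravel()
            train_seqs, y_train = seqs, y
        elif self.validation_fraction > 0:
            split_rng = np.random.default_rng(derive_seed(seed, "valsplit"))
            val_idx = []
            for cls in (0, 1):
                cls_idx = np.nonzero(y == cls)[0]
                n_val = max(1, int(round(len(cls_idx) * self.validation_fraction)))
                val_idx.append(split_rng.permutation(cls_idx)[:n_val])
            val_mask = np.zeros(len(y), dtype=bool)
            val_mask[np.concatenate(val_idx)] = True
            val_seqs = [s for s, m in zip(seqs, val_mask) if m]
            y_val = y[val_mask]
            train_seqs = [s for s, m in zip(seqs, val_mask) if not m]
            y_train = y[~val_mask]
        else:
            train_seqs, y_train = seqs, y
            val_seqs, y_val = seqs, y

        if self.embedding in ("dna2vec", "positional"):
            if self.kmer_vectors is not None:
                if self.kmer_vectors.vocab.k != self.k:
                    raise ConfigurationError(
                        f"kmer_vectors built for k={self.kmer_vectors.vocab.k}, "
                        f"estimator k={self.k}")
                self.kmer_table_ = self.kmer_vectors
            else:
                self.kmer_table_ = train_kmer_vectors(
                    train_seqs, k=self.k, d=self.vector_dim, window=self.sg_window,
                    epochs=self.sg_epochs, rng_seed=derive_seed(seed, "skipgram"),
                    allow_n=self.allow_n)
        else:
            self.kmer_table_ = None

        x_static, x_vec = self._encode(train_seqs)
        xv_static, xv_vec = self._encode(val_seqs)

        spec = self._model_spec()
        self.network_ = DeepARCNetwork(
            spec, self.embedding,
            input_static_dim=0 if x_static is None else x_static.shape[2],
            vector_dim=None if x_vec is None else x_vec.shape[2],
            k=self.k, rng=init_rng)
        optimizer = Adam(self.network_.parameters(), self.learning_rate)

        n = len(train_seqs)
        train_losses, val_losses = [], []
        best_val, best_state, best_epoch = np.inf, None, -1
        for epoch in range(self.epochs):
            optimizer.learning_rate = self.learning_rate * (
                self.lr_gamma ** (epoch // self.lr_step))
            order = shuffle_rng.permutation(n)
            batch_losses = []
            for lo in range(0, n, self.batch_size):
                sel = order[lo:lo + self.batch_size]
                xb_s = None if x_static is None else x_static[sel]
                xb_v = None if x_vec is None else x_vec[sel]
                yb = y_train[sel]
                probs, _ = self.network_.forward(xb_s, xb_v, training=True,
                                                 rng=dropout_rng)
                batch_losses.append(_nn.bce_loss(probs, yb))
                optimizer.zero_grad()
                self.network_.backward(
                    _nn.bce_grad_wrt_logits(probs.astype(np.float32), yb))
                optimizer.step()
            train_losses.append(float(np.mean(batch_losses)))
            val_probs = self._forward_chunks(xv_static, xv_vec)
            val_loss = _nn.bce_loss(val_probs, y_val)
            val_losses.append(val_loss)
            if val_loss < best_val:
                best_val, best_epoch = val_loss, epoch
                best_state = self.network_.state_dict()

        if best_state is not None:
            self.network_.load_state_dict(best_state)
        self.history_ = {"train_loss": train_losses, "val_loss": val_losses}
        self.best_epoch_ = best_epoch
        return self

    def _forward_chunks(self, x_static, x_vec, chunk: int = 512,
                        collect_alpha: bool = False):
        n = len(x_static) if x_static is not None else len(x_vec)
        probs, alphas = [], []
        for lo in range(0, n, chunk):
            xs = None if x_static is None else x_static[lo:lo + chunk]
            xv = None if x_vec is None else x_vec[lo:lo + chunk]
            p, a = self.network_.forward(xs, xv, training=False)
            probs.append(p)
            if collect_alpha:
                alphas.append(a)
        probs = np.concatenate(probs)
        if collect_alpha:
            return probs, np.concatenate(alphas)
        return probs

    # -- inference ----------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        x_static, x_vec = self._encode(self._as_sequences(X))
        p = self._forward_chunks(x_static, x_vec)
        return np.column_stack([1 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(np.int64)

    def attention(self, X) -> np.ndarray:
        """Per-window attention distributions (n_windows, T); attention-bearing
        architectures only."""
        check_is_fitted(self, "network_")
        self.network_.attention_weights_required()
        x_static, x_vec = self._encode(self._as_sequences(X))
        _, alphas = self._forward_chunks(x_static, x_vec, collect_alpha=True)
        return alphas

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Persist the fitted model: constructor params, the k-mer vector
        table, and every named network parameter array (.npz container)."""
        check_is_fitted(self, "network_")
        import json

        params = {k: v for k, v in self.get_params().items() if k != "kmer_vectors"}
        arrays = {f"net::{k}": v for k, v in self.network_.state_dict().items()}
        if self.kmer_table_ is not None:
            arrays["kmer_vectors"] = self.kmer_table_.vectors
        arrays["meta"] = np.frombuffer(json.dumps({
            "params": params,
            "n_features_in": int(self.n_features_in_),
            "best_epoch": int(self.best_epoch_),
            "history": self.history_,
        }).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "DeepARCClassifier":
        import json

        from .embedding import KmerVocabulary

        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            est = cls(**meta["params"])
            est.classes_ = np.array([0, 1])
            est.n_features_in_ = meta["n_features_in"]
            est.best_epoch_ = meta["best_epoch"]
            est.history_ = meta["history"]
            if "kmer_vectors" in data:
                est.kmer_table_ = KmerVectorTable(KmerVocabulary(est.k),
                                                  data["kmer_vectors"])
            else:
                est.kmer_table_ = None
            state = {k[len("net::"):]: data[k] for k in data.files
                     if k.startswith("net::")}
        spec = est._model_spec()
        static_dim = {"onehot_base": 4, "onehot_kmer": 4 ** est.k,
                      "positional": 4 ** est.k, "dna2vec": 0}[est.embedding]
        vec_dim = est.kmer_table_.d if est.kmer_table_ is not None else None
        est.network_ = DeepARCNetwork(spec, est.embedding, static_dim, vec_dim,
                                      k=est.k)
        est.network_.load_state_dict(state)
        return est
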