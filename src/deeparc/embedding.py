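"""DNA window embeddings: per-base one-hot, k-mer one-hot, distributed k-mer
vectors, and the positional embedding that concatenates both.

A length-L window split into overlapping k-mers (stride 1) yields T = L-k+1
tokens. The positional embedding of a window is the T x (2*4^k) matrix
``[onehot_kmer | reduce(distributed)]``: the one-hot half carries exact
positional identity, the distributed half carries learned k-mer context,
linearly reduced from dimension d to 4^k by a trainable width-1 convolution.

Distributed vectors are trained here with skip-gram + negative sampling over
the k-mer token stream (the word2vec objective applied to DNA words), or
loaded from any word2vec-text-format file.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Sequence
from pathlib import Path

import numpy as np
from scipy.special import expit

from .sequences import DNA_ALPHABET, LabeledSequenceSet

EMBEDDING_VARIANTS = ("onehot_base", "onehot_kmer", "dna2vec", "positional")

_BASE_INDEX = {c: i for i, c in enumerate(DNA_ALPHABET)}


class EmbeddingInputError(ValueError):
    """Raised for sequences or tables the embedding layer cannot encode."""


class VectorFormatError(ValueError):
    """Raised for malformed word2vec text files."""


@dataclasses.dataclass(frozen=True)
class KmerVocabulary:
    """Bijection between the 4^k k-mers over ACGT and [0, 4^k), lexicographic A<C<G<T."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise EmbeddingInputError(f"k must be >= 1, got {self.k}")

    @property
    def size(self) -> int:
        return 4 ** self.k

    def index_of(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise EmbeddingInputError(f"token {kmer!r} is not a {self.k}-mer")
        idx = 0
        for c in kmer:
            if c not in _BASE_INDEX:
                raise EmbeddingInputError(f"token {kmer!r} contains non-ACGT character {c!r}")
            idx = idx * 4 + _BASE_INDEX[c]
        return idx

    def kmer_of(self, index: int) -> str:
        if not 0 <= index < self.size:
            raise EmbeddingInputError(f"index {index} outside [0, {self.size})")
        out = []
        for _ in range(self.k):
            out.append(DNA_ALPHABET[index % 4])
            index //= 4
        return "".join(reversed(out))

    def all_kmers(self) -> list[str]:
        return ["".join(p) for p in itertools.product(DNA_ALPHABET, repeat=self.k)]


@dataclasses.dataclass(frozen=True)
class KmerSequence:
    """The stride-1 k-mer tokens of one window (T = L - k + 1 of them)."""

    tokens: tuple[str, ...]
    source_length: int
    k: int


def kmerize(sequence: str, k: int, allow_n: bool = False) -> KmerSequence:
    """Split a window into its L-k+1 overlapping k-mers (stride 1)."""
    if k < 1:
        raise EmbeddingInputError(f"k must be >= 1, got {k}")
    if len(sequence) < k:
        raise EmbeddingInputError(f"sequence length {len(sequence)} < k={k}")
    if not allow_n:
        pos = sequence.find("N")
        if pos != -1:
            raise EmbeddingInputError(
                f"ambiguous base 'N' at position {pos}; pass allow_n=True to map "
                "N-containing k-mers to zero vectors"
            )
    tokens = tuple(sequence[i:i + k] for i in range(len(sequence) - k + 1))
    return KmerSequence(tokens, len(sequence), k)


def _token_indices(tokens: KmerSequence, vocab: KmerVocabulary, allow_n: bool) -> np.ndarray:
    """Vocabulary index per token; -1 marks N-containing tokens when allowed."""
    idx = np.empty(len(tokens.tokens), dtype=np.int64)
    for i, tok in enumerate(tokens.tokens):
        if "N" in tok:
            if not allow_n:
                raise EmbeddingInputError(f"token {tok!r} at position {i} contains 'N'")
            idx[i] = -1
        else:
            idx[i] = vocab.index_of(tok)
    return idx


def onehot_kmers(tokens: KmerSequence, vocab: KmerVocabulary | None = None,
                 allow_n: bool = False, dtype=np.float64) -> np.ndarray:
    """(T, 4^k) one-hot matrix; N-containing tokens become zero rows if allowed."""
    vocab = vocab or KmerVocabulary(tokens.k)
    if vocab.k != tokens.k:
        raise EmbeddingInputError(f"vocabulary k={vocab.k} does not match tokens k={tokens.k}")
    idx = _token_indices(tokens, vocab, allow_n)
    out = np.zeros((len(idx), vocab.size), dtype=dtype)
    valid = idx >= 0
    out[np.nonzero(valid)[0], idx[valid]] = 1
    return out


def onehot_bases(sequence: str, allow_n: bool = False, dtype=np.float64) -> np.ndarray:
    """(L, 4) per-base one-hot, columns in A<C<G<T order; N rows zero if allowed."""
    out = np.zeros((len(sequence), 4), dtype=dtype)
    for i, c in enumerate(sequence):
        if c == "N":
            if not allow_n:
                raise EmbeddingInputError(f"ambiguous base 'N' at position {i}")
            continue
        if c not in _BASE_INDEX:
            raise EmbeddingInputError(f"illegal character {c!r} at position {i}")
        out[i, _BASE_INDEX[c]] = 1
    return out


@dataclasses.dataclass
class KmerVectorTable:
    """Distributed d-vectors for the full 4^k vocabulary, stored as one array."""

    vocab: KmerVocabulary
    vectors: np.ndarray  # (4^k, d)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != self.vocab.size:
            raise VectorFormatError(
                f"vector table must be ({self.vocab.size}, d), got {v.shape}"
            )
        self.vectors = v

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __getitem__(self, kmer: str) -> np.ndarray:
        return self.vectors[self.vocab.index_of(kmer)]

    def __len__(self) -> int:
        return self.vocab.size


def _skipgram_pairs(token_ids: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for ids in token_ids:
        n = len(ids)
        for off in range(1, window + 1):
            if n <= off:
                continue
            a, b = ids[:-off], ids[off:]
            keep = (a >= 0) & (b >= 0)
            centers.append(a[keep]); contexts.append(b[keep])
            centers.append(b[keep]); contexts.append(a[keep])
    if not centers:
        raise EmbeddingInputError("corpus produced no skip-gram pairs")
    return np.concatenate(centers), np.concatenate(contexts)


def train_kmer_vectors(
    corpus: LabeledSequenceSet | Sequence[str],
    k: int = 3,
    d: int = 100,
    window: int = 5,
    epochs: int = 3,
    rng_seed: int = 0,
    negatives: int = 5,
    learning_rate: float = 0.025,
    batch_size: int = 1024,
    allow_n: bool = False,
) -> KmerVectorTable:
    """Train skip-gram-with-negative-sampling k-mer vectors on a sequence corpus.

    Single-threaded, minibatch SGD with a linearly decaying learning rate;
    negatives are drawn from the unigram^0.75 distribution. Because the
    vocabulary is tiny (4^k), per-batch updates are accumulated through
    dense one-hot matmuls rather than scatter-adds. Fully determined by
    ``rng_seed``; k-mers absent from the corpus keep their seeded random
    initialisation.
    """
    seqs = corpus.sequences() if isinstance(corpus, LabeledSequenceSet) else list(corpus)
    if not seqs:
        raise EmbeddingInputError("empty corpus")
    vocab = KmerVocabulary(k)
    rng = np.random.default_rng(rng_seed)

    token_ids = [_token_indices(kmerize(s, k, allow_n), vocab, allow_n) for s in seqs]
    centers, contexts = _skipgram_pairs(token_ids, window)

    counts = np.bincount(np.concatenate([ids[ids >= 0] for ids in token_ids]),
                         minlength=vocab.size).astype(np.float64)
    noise = counts ** 0.75
    noise_sum = noise.sum()
    if noise_sum == 0:
        raise EmbeddingInputError("corpus contains no unambiguous k-mers")
    noise /= noise_sum

    bound = 0.5 / d
    w_in = rng.uniform(-bound, bound, size=(vocab.size, d))
    w_out = np.zeros((vocab.size, d))
    noise_cdf = np.cumsum(noise)
    noise_cdf[-1] = 1.0

    n_pairs = len(centers)
    total_batches = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    step = 0
    eye = np.eye(vocab.size)
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            sel = order[lo:lo + batch_size]
            c, t = centers[sel], contexts[sel]
            neg = np.searchsorted(noise_cdf, rng.random((len(sel), negatives)))
            lr = learning_rate * max(1.0 - step / total_batches, 1e-4)
            step += 1

            vc = w_in[c]                       # (B, d)
            vt = w_out[t]                      # (B, d)
            vn = w_out[neg]                    # (B, neg, d)

            # positive pair: maximize log sigmoid(vc.vt)
            s_pos = expit(np.sum(vc * vt, axis=1))                    # (B,)
            g_pos = (1.0 - s_pos)[:, None]                            # d/dlogit
            # negatives: maximize log sigmoid(-vc.vn)
            s_neg = expit(np.einsum("bd,bnd->bn", vc, vn))
            g_neg = -s_neg                                            # (B, neg)

            grad_c = g_pos * vt + np.einsum("bn,bnd->bd", g_neg, vn)
            # accumulate row updates with one-hot matmuls (vocab is tiny)
            w_in += lr * (eye[c].T @ grad_c)
            out_rows = np.concatenate([t, neg.ravel()])
            out_grads = np.concatenate(
                [g_pos * vc, (g_neg[:, :, None] * vc[:, None, :]).reshape(-1, d)])
            w_out += lr * (eye[out_rows].T @ out_grads)
    return KmerVectorTable(vocab, w_in)


def save_kmer_vectors(table: KmerVectorTable, path: str | Path) -> None:
    """Write the table in word2vec text format (header line ``count dim``)."""
    with open(path, "w") as fh:
        fh.write(f"{len(table)} {table.d}\n")
        for i in range(len(table)):
            vec = " ".join(repr(float(x)) for x in table.vectors[i])
            fh.write(f"{table.vocab.kmer_of(i)} {vec}\n")


def load_kmer_vectors(path: str | Path, k: int) -> KmerVectorTable:
    """Load word2vec text format; tokens are upper-cased and must cover all 4^k k-mers."""
    vocab = KmerVocabulary(k)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise VectorFormatError(f"{path}: first line must be 'count dim'")
        count, d = int(header[0]), int(header[1])
        vectors = np.full((vocab.size, d), np.nan)
        n_rows = 0
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            token, values = parts[0].upper(), parts[1:]
            if len(token) != k:
                raise VectorFormatError(f"{path}:{lineno}: token {token!r} is not a {k}-mer")
            if len(values) != d:
                raise VectorFormatError(
                    f"{path}:{lineno}: expected {d} values, got {len(values)}"
                )
            vectors[vocab.index_of(token)] = [float(v) for v in values]
            n_rows += 1
    if n_rows != count:
        raise VectorFormatError(f"{path}: header declares {count} rows, found {n_rows}")
    if np.isnan(vectors).any():
        missing = [vocab.kmer_of(i) for i in np.nonzero(np.isnan(vectors).any(axis=1))[0]]
        raise VectorFormatError(f"{path}: vocabulary not covered, missing {missing[:5]}")
    return KmerVectorTable(vocab, vectors)


def embed_distributed(tokens: KmerSequence, table: KmerVectorTable,
                      allow_n: bool = False) -> np.ndarray:
    """(T, d) matrix whose row i is the table vector of token i (zeros for N tokens)."""
    if table.vocab.k != tokens.k:
        raise EmbeddingInputError(f"table k={table.vocab.k} does not match tokens k={tokens.k}")
    idx = _token_indices(tokens, table.vocab, allow_n)
    out = np.zeros((len(idx), table.d))
    valid = idx >= 0
    out[valid] = table.vectors[idx[valid]]
    return out


def reduce_to_4k(z_vec: np.ndarray, k: int, reducer_params) -> np.ndarray:
    """Reduce a (T, d) distributed matrix to (T, 4^k) with the trainable
    width-1 convolution (a shared linear map applied independently per row)."""
    z_vec = np.asarray(z_vec)
    out = reducer_params.forward(z_vec[None])[0]
    if out.shape != (z_vec.shape[0], 4 ** k):
        raise EmbeddingInputError(
            f"reducer produced {out.shape}, expected ({z_vec.shape[0]}, {4 ** k})"
        )
    return out


def positional_embed(sequence: str, k: int, table: KmerVectorTable, reducer_params,
                     allow_n: bool = False) -> np.ndarray:
    """The (L-k+1, 2*4^k) positional embedding: [k-mer one-hot | reduced distributed]."""
    tokens = kmerize(sequence, k, allow_n)
    oh = onehot_kmers(tokens, table.vocab, allow_n)
    red = reduce_to_4k(embed_distributed(tokens, table, allow_n), k, reducer_params)
    return np.concatenate([oh, red], axis=1)
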