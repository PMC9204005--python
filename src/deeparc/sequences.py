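"""Labeled DNA window datasets: FASTA/TSV IO and synthetic ChIP-seq-like generation.

Positives are fixed-length windows (default 101 bp, the usual peak-centred
window size) with a motif implanted; negatives are composition-matched
rearrangements of the positives, so a classifier cannot separate the classes
on nucleotide content alone.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Sequence
from pathlib import Path
from typing import Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = "ACGT"
VALID_CHARS = frozenset("ACGTN")
SPLITS = ("train", "test", "validation")

DEFAULT_WINDOW_LENGTH = 101
DEFAULT_SPLIT_FRACS = (0.6, 0.3, 0.1)


class SequenceInputError(ValueError):
    """Raised for malformed sequence input (bad characters, id mismatches, lengths)."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """One fixed-length DNA window with a binary binding label and split assignment."""

    id: str
    sequence: str
    label: int
    split: str = "train"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise SequenceInputError(f"label for {self.id!r} must be 0 or 1, got {self.label}")
        if self.split not in SPLITS:
            raise SequenceInputError(f"split for {self.id!r} must be one of {SPLITS}, got {self.split!r}")
        bad = [(i, c) for i, c in enumerate(self.sequence) if c not in VALID_CHARS]
        if bad:
            i, c = bad[0]
            raise SequenceInputError(
                f"illegal character {c!r} at position {i} in sequence {self.id!r}"
            )


@dataclasses.dataclass(frozen=True)
class MotifModel:
    """A position probability matrix (PPM) over A, C, G, T.

    ``matrix`` has one row per motif position and columns in A<C<G<T order.
    Motif lengths follow the biological range for TF binding sites (roughly
    4-20 bp).
    """

    matrix: np.ndarray
    name: str = "motif"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise SequenceInputError(f"motif matrix must be (length, 4), got {m.shape}")
        if not 4 <= m.shape[0] <= 20:
            raise SequenceInputError(f"motif length must be in [4, 20], got {m.shape[0]}")
        if (m < 0).any():
            raise SequenceInputError("motif probabilities must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise SequenceInputError("each motif row must sum to 1 (within 1e-9)")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(DNA_ALPHABET[j] for j in self.matrix.argmax(axis=1))

    @classmethod
    def from_consensus(cls, consensus: str, name: str | None = None) -> "MotifModel":
        """Degenerate PPM with probability 1 on each consensus base."""
        consensus = consensus.upper()
        rows = np.zeros((len(consensus), 4))
        for i, c in enumerate(consensus):
            if c not in DNA_ALPHABET:
                raise SequenceInputError(f"consensus base {c!r} at position {i} is not in ACGT")
            rows[i, DNA_ALPHABET.index(c)] = 1.0
        return cls(rows, name=name or consensus)

    def sample(self, rng: np.random.Generator) -> str:
        bases = [rng.choice(4, p=row) for row in self.matrix]
        return "".join(DNA_ALPHABET[int(b)] for b in bases)


# CRE-like 8-bp palindrome used as the default implanted signal: strong,
# biologically plausible, and deterministic (probability 1 on each base).
DEFAULT_MOTIF = MotifModel.from_consensus("TGACGTCA", name="CRE")


@dataclasses.dataclass
class LabeledSequenceSet:
    """An ordered collection of equal-length labeled windows plus provenance metadata."""

    records: list[SequenceRecord]
    window_length: int
    provenance: dict = dataclasses.field(default_factory=dict)
    uniform_length: bool = True  # override for deliberately ragged sets

    def __post_init__(self) -> None:
        if not self.uniform_length:
            return
        bad = [r.id for r in self.records if len(r.sequence) != self.window_length]
        if bad:
            raise SequenceInputError(
                f"records {bad[:5]} do not match window_length={self.window_length}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, split: str) -> "LabeledSequenceSet":
        if split not in SPLITS:
            raise SequenceInputError(f"unknown split {split!r}")
        return LabeledSequenceSet(
            [r for r in self.records if r.split == split],
            self.window_length,
            dict(self.provenance, subset=split),
            uniform_length=self.uniform_length,
        )

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_fasta_labeled(
    fasta_path: str | Path,
    labels_path: str | Path,
    splits_path: str | Path | None = None,
    allow_length_mismatch: bool = False,
) -> LabeledSequenceSet:
    """Read a FASTA of windows plus a sidecar ``id<TAB>label`` table.

    Record order follows the FASTA file. Every FASTA id must appear exactly
    once in the label table and vice versa.
    """
    labels = _read_two_column_tsv(labels_path, "label")
    splits = _read_two_column_tsv(splits_path, "split") if splits_path else {}

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise SequenceInputError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        if rec.id not in labels:
            raise SequenceInputError(f"FASTA id {rec.id!r} missing from label table")
        label = int(labels[rec.id])
        split = str(splits.get(rec.id, "train"))
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), label, split))
    extra = set(labels) - seen
    if extra:
        raise SequenceInputError(f"label table ids absent from FASTA: {sorted(extra)[:5]}")
    if not records:
        raise SequenceInputError(f"no records in {fasta_path}")

    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1 and not allow_length_mismatch:
        raise SequenceInputError(
            f"inconsistent window lengths {sorted(lengths)}; pass allow_length_mismatch=True to override"
        )
    window_length = len(records[0].sequence)
    return LabeledSequenceSet(records, window_length,
                              {"fasta": str(fasta_path), "labels": str(labels_path)},
                              uniform_length=len(lengths) == 1)


def write_fasta_labeled(dataset: LabeledSequenceSet, fasta_path: str | Path, labels_path: str | Path,
                        splits_path: str | Path | None = None) -> None:
    """Write the dataset as wrapped FASTA plus sidecar label (and split) TSVs."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in dataset]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    with open(labels_path, "w") as fh:
        fh.write("id\tlabel\n")
        for r in dataset:
            fh.write(f"{r.id}\t{r.label}\n")
    if splits_path is not None:
        with open(splits_path, "w") as fh:
            fh.write("id\tsplit\n")
            for r in dataset:
                fh.write(f"{r.id}\t{r.split}\n")


def _read_two_column_tsv(path: str | Path, value_name: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2 or header[0] != "id":
            raise SequenceInputError(f"{path}: expected header 'id\\t{value_name}', got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SequenceInputError(f"{path}:{lineno}: expected two tab-separated columns")
            if parts[0] in out:
                raise SequenceInputError(f"{path}:{lineno}: duplicate id {parts[0]!r}")
            out[parts[0]] = parts[1]
    return out


def random_background(length: int, rng: np.random.Generator,
                      base_freqs: Sequence[float] | None = None) -> str:
    """I.i.d. background sequence; uniform over ACGT unless 0-order frequencies given."""
    p = None if base_freqs is None else np.asarray(base_freqs, dtype=float)
    if p is not None:
        if p.shape != (4,) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise SequenceInputError("base_freqs must be 4 probabilities summing to 1")
    idx = rng.choice(4, size=length, p=p)
    return "".join(DNA_ALPHABET[i] for i in idx)


def implant_motif(
    background: str,
    motif: MotifModel,
    position: int | Literal["center", "random"] = "center",
    rng_seed: int | np.random.Generator = 0,
) -> str:
    """Overwrite a slice of ``background`` with a sample from the motif PPM.

    ``"center"`` resolves to ``floor((L - motif_length) / 2)`` so an 8-bp motif
    in a 101-bp window starts at offset 46.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    L, m = len(background), len(motif)
    if m > L:
        raise SequenceInputError(f"motif length {m} exceeds window length {L}")
    if position == "center":
        start = (L - m) // 2
    elif position == "random":
        start = int(rng.integers(0, L - m + 1))
    else:
        start = int(position)
        if start < 0 or start + m > L:
            raise SequenceInputError(f"implant at {start} with length {m} leaves window [0, {L})")
    return background[:start] + motif.sample(rng) + background[start + m:]


def dinucleotide_shuffle(sequence: str, rng_seed: int | np.random.Generator = 0) -> str:
    """Altschul-Erikson shuffle: a uniform random rearrangement preserving all
    dinucleotide (and hence mononucleotide) counts.

    The dinucleotide multigraph (nodes = bases, one edge per adjacent pair) is
    rewired by sampling a uniform Eulerian path with the same start and end
    vertex as the input: for every non-terminal vertex a random outgoing edge
    is designated "last", the designated edges must form a tree into the end
    vertex (rejection sampling), and the remaining edges are permuted.
    """
    if len(sequence) < 2:
        raise SequenceInputError("dinucleotide shuffle requires length >= 2")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)

    verts = sorted(set(sequence))
    edges: dict[str, list[str]] = {v: [] for v in verts}
    for a, b in zip(sequence, sequence[1:]):
        edges[a].append(b)
    start, end = sequence[0], sequence[-1]

    while True:
        last_edge: dict[str, str] = {}
        for v in verts:
            if v != end and edges[v]:
                last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        # The designated last edges must connect every used vertex to the end
        # vertex; otherwise the walk would strand edges (Altschul-Erikson).
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != end:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    remaining: dict[str, list[str]] = {}
    for v in verts:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        remaining[v] = rest

    out = [start]
    cur = start
    counters = {v: 0 for v in verts}
    for _ in range(len(sequence) - 1):
        nxt = remaining[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def mononucleotide_shuffle(sequence: str, rng_seed: int | np.random.Generator = 0) -> str:
    """Plain per-base permutation (preserves mononucleotide counts only)."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    chars = np.array(list(sequence))
    rng.shuffle(chars)
    return "".join(chars)


def _split_counts(n: int, fracs: Sequence[float]) -> tuple[int, int, int]:
    """Floor each fraction's count; the remainder goes to train."""
    if len(fracs) != 3 or not math.isclose(sum(fracs), 1.0, abs_tol=1e-9):
        raise SequenceInputError(f"split fractions must be 3 values summing to 1, got {fracs}")
    n_train = int(n * fracs[0])
    n_test = int(n * fracs[1])
    n_val = int(n * fracs[2])
    n_train += n - (n_train + n_test + n_val)
    return n_train, n_test, n_val


def _evenly_spaced_starts(window_length: int, motif_lengths: Sequence[int]) -> list[int]:
    m = len(motif_lengths)
    starts = []
    for j, ml in enumerate(motif_lengths):
        center = (j + 1) * window_length / (m + 1)
        starts.append(int(math.floor(center - ml / 2)))
    return starts


def generate_dataset(
    n_pos: int,
    motifs: MotifModel | Sequence[MotifModel] = DEFAULT_MOTIF,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    split_fracs: Sequence[float] = DEFAULT_SPLIT_FRACS,
    rng_seed: int = 0,
    n_motifs_per_positive: int = 1,
    negative_mode: Literal["dinucleotide", "mononucleotide"] = "dinucleotide",
    base_freqs: Sequence[float] | None = None,
) -> LabeledSequenceSet:
    """Generate a balanced synthetic TFBS dataset.

    Each positive is an i.i.d. background window with ``n_motifs_per_positive``
    motif instances implanted; one instance goes at the window centre, two or
    more go at fixed evenly spaced non-overlapping loci (the two-TFBS case).
    Each negative is a composition-matched shuffle of one positive and is
    assigned to the same split as its partner, so paired near-duplicates never
    straddle the train/test boundary.
    """
    if n_pos < 1:
        raise SequenceInputError("n_pos must be >= 1")
    motif_list = [motifs] if isinstance(motifs, MotifModel) else list(motifs)
    if n_motifs_per_positive < 1:
        raise SequenceInputError("n_motifs_per_positive must be >= 1")
    chosen = [motif_list[j % len(motif_list)] for j in range(n_motifs_per_positive)]

    if n_motifs_per_positive == 1:
        starts = ["center"]
    else:
        starts = _evenly_spaced_starts(window_length, [len(m) for m in chosen])
        intervals = sorted((s, s + len(m)) for s, m in zip(starts, chosen))
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if b0 < a1:
                raise SequenceInputError(
                    f"cannot place {n_motifs_per_positive} non-overlapping motifs in a "
                    f"{window_length}-bp window"
                )
        if intervals[0][0] < 0 or intervals[-1][1] > window_length:
            raise SequenceInputError("motif placement falls outside the window")

    rng = np.random.default_rng(rng_seed)
    shuffler = dinucleotide_shuffle if negative_mode == "dinucleotide" else mononucleotide_shuffle

    records: list[SequenceRecord] = []
    width = len(str(n_pos))
    positives: list[str] = []
    for i in range(n_pos):
        seq = random_background(window_length, rng, base_freqs)
        for motif, start in zip(chosen, starts):
            seq = implant_motif(seq, motif, start, rng)
        positives.append(seq)

    n_train, n_test, n_val = _split_counts(n_pos, split_fracs)
    split_of = ["train"] * n_train + ["test"] * n_test + ["validation"] * n_val
    for i, seq in enumerate(positives):
        split = split_of[i]
        records.append(SequenceRecord(f"pos_{i:0{width}d}", seq, 1, split))
        records.append(SequenceRecord(f"neg_{i:0{width}d}", shuffler(seq, rng), 0, split))

    provenance = {
        "generator": "deeparc.sequences.generate_dataset",
        "n_pos": n_pos,
        "motifs": [m.name for m in chosen],
        "motif_starts": starts,
        "window_length": window_length,
        "split_fracs": list(split_fracs),
        "rng_seed": rng_seed,
        "n_motifs_per_positive": n_motifs_per_positive,
        "negative_mode": negative_mode,
    }
    return LabeledSequenceSet(records, window_length, provenance)
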