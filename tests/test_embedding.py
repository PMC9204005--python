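"""K-mer tokenization, one-hot and distributed embeddings, and the
positional-embedding construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deeparc import (
    KmerVectorTable,
    KmerVocabulary,
    embed_distributed,
    kmerize,
    load_kmer_vectors,
    onehot_bases,
    onehot_kmers,
    positional_embed,
    reduce_to_4k,
    save_kmer_vectors,
    train_kmer_vectors,
)
from deeparc._nn import Linear
from deeparc.embedding import EmbeddingInputError, VectorFormatError
from deeparc.sequences import random_background

dna = st.text(alphabet="ACGT", min_size=10, max_size=300)


def identity_reducer(d, n4k):
    """Linear reducer wired to the identity (requires d == 4^k)."""
    rng = np.random.default_rng(0)
    lin = Linear(d, n4k, rng, dtype=np.float64)
    lin.W.value[...] = np.eye(d, n4k)
    lin.b.value[...] = 0
    return lin


class TestKmerize:
    def test_definition_example(self):
        assert kmerize("ACGTA", 3).tokens == ("ACG", "CGT", "GTA")

    def test_101bp_k3_gives_99_tokens(self):
        seq = random_background(101, np.random.default_rng(0))
        assert len(kmerize(seq, 3).tokens) == 99

    def test_boundary_single_token(self):
        assert kmerize("AA", 2).tokens == ("AA",)

    def test_n_without_fallback_reports_position(self):
        with pytest.raises(EmbeddingInputError, match="position 3"):
            kmerize("ACGNA", 2)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(dna, st.integers(1, 6))
    def test_token_count_is_L_minus_k_plus_1(self, seq, k):
        toks = kmerize(seq, k)
        assert len(toks.tokens) == len(seq) - k + 1
        for a, b in zip(toks.tokens, toks.tokens[1:]):
            assert a[1:] == b[:-1]  # stride-1 overlap


class TestVocabulary:
    def test_lexicographic_order(self):
        v = KmerVocabulary(3)
        assert v.index_of("AAA") == 0
        assert v.index_of("AAC") == 1
        assert v.index_of("TTT") == 63
        assert v.kmer_of(v.index_of("GAT")) == "GAT"

    def test_bijection(self):
        v = KmerVocabulary(2)
        assert sorted(v.index_of(k) for k in v.all_kmers()) == list(range(16))


class TestOneHot:
    def test_kmer_onehot_shape_and_rowsums(self):
        seq = random_background(101, np.random.default_rng(1))
        m = onehot_kmers(kmerize(seq, 3))
        assert m.shape == (99, 64)
        assert (m.sum(axis=1) == 1).all()

    def test_aaa_hits_column_zero(self):
        m = onehot_kmers(kmerize("AAAA", 3))
        assert m[0, 0] == 1 and m[0, 1:].sum() == 0

    def test_base_onehot_identity_on_acgt(self):
        np.testing.assert_array_equal(onehot_bases("ACGT"), np.eye(4))

    def test_base_onehot_101bp_shape(self):
        seq = random_background(101, np.random.default_rng(2))
        m = onehot_bases(seq)
        assert m.shape == (101, 4) and (m.sum(axis=1) == 1).all()

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(dna, st.integers(1, 6))
    def test_onehot_invertible_to_tokens(self, seq, k):
        toks = kmerize(seq, k)
        vocab = KmerVocabulary(k)
        m = onehot_kmers(toks, vocab)
        recovered = tuple(vocab.kmer_of(int(j)) for j in m.argmax(axis=1))
        assert recovered == toks.tokens


class TestVectorTableIO:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        table = KmerVectorTable(KmerVocabulary(2), rng.standard_normal((16, 7)))
        path = tmp_path / "vec.txt"
        save_kmer_vectors(table, path)
        back = load_kmer_vectors(path, 2)
        np.testing.assert_array_equal(back.vectors, table.vectors)
        assert back.d == 7

    def test_header_row_count_mismatch(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("3 2\nAA 0.0 1.0\nAC 1.0 0.0\n")
        with pytest.raises(VectorFormatError, match="declares 3"):
            load_kmer_vectors(p, 2)

    def test_wrong_token_length_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1 2\nAAA 0.0 1.0\n")
        with pytest.raises(VectorFormatError, match="AAA"):
            load_kmer_vectors(p, 2)

    def test_dim_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("2 3\nAA 0.0 1.0 2.0\nAC 1.0\n")
        with pytest.raises(VectorFormatError, match="expected 3"):
            load_kmer_vectors(p, 2)

    def test_casing_normalized(self, tmp_path):
        rows = "\n".join(f"{k.lower()} 1.0" for k in KmerVocabulary(1).all_kmers())
        p = tmp_path / "lc.txt"
        p.write_text("4 1\n" + rows + "\n")
        assert load_kmer_vectors(p, 1).d == 1


class TestSkipgramTraining:
    def test_full_vocabulary_covered(self):
        seqs = [random_background(40, np.random.default_rng(i)) for i in range(5)]
        table = train_kmer_vectors(seqs, k=3, d=8, epochs=1, rng_seed=0)
        assert len(table) == 64 and table.d == 8

    def test_seed_determinism(self):
        seqs = [random_background(40, np.random.default_rng(i)) for i in range(5)]
        a = train_kmer_vectors(seqs, k=3, d=8, epochs=1, rng_seed=7)
        b = train_kmer_vectors(seqs, k=3, d=8, epochs=1, rng_seed=7)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_cooccurring_kmers_closer_than_disjoint(self):
        # ACG and CGT always co-occur; TTT never appears near either.
        # Random background keeps the embedding space from collapsing.
        rng = np.random.default_rng(99)
        corpus = ([random_background(50, rng) for _ in range(40)]
                  + ["ACGT" * 10] * 20 + ["T" * 40] * 20)
        table = train_kmer_vectors(corpus, k=3, d=16, epochs=3, rng_seed=1)

        def cos(a, b):
            va, vb = table[a], table[b]
            return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))

        assert cos("ACG", "CGT") > cos("ACG", "TTT")

    def test_empty_corpus_rejected(self):
        with pytest.raises(EmbeddingInputError, match="empty"):
            train_kmer_vectors([], k=3)


class TestReduceAndPositional:
    def test_reduction_shape_99x64(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((99, 100))
        red = Linear(100, 64, rng, dtype=np.float64)
        assert reduce_to_4k(z, 3, red).shape == (99, 64)

    def test_identity_configuration(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((10, 16))
        np.testing.assert_allclose(reduce_to_4k(z, 2, identity_reducer(16, 16)), z)

    def test_row_local_width_one_kernel(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal((20, 12))
        red = Linear(12, 16, rng, dtype=np.float64)
        base = reduce_to_4k(z, 2, red)
        z2 = z.copy()
        z2[7] += 1.0
        out = reduce_to_4k(z2, 2, red)
        changed = np.nonzero(np.abs(out - base).sum(axis=1) > 0)[0]
        np.testing.assert_array_equal(changed, [7])

    def test_position_equivariance_row_reversal(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((15, 8))
        red = Linear(8, 16, rng, dtype=np.float64)
        np.testing.assert_allclose(reduce_to_4k(z[::-1], 2, red),
                                   reduce_to_4k(z, 2, red)[::-1])

    def test_embed_distributed_is_row_lookup(self):
        rng = np.random.default_rng(8)
        table = KmerVectorTable(KmerVocabulary(2), rng.standard_normal((16, 5)))
        toks = kmerize("ACGTT", 2)
        m = embed_distributed(toks, table)
        assert m.shape == (4, 5)
        for i, tok in enumerate(toks.tokens):
            np.testing.assert_array_equal(m[i], table[tok])

    def test_positional_shape_and_onehot_half(self):
        rng = np.random.default_rng(9)
        seq = random_background(101, rng)
        table = KmerVectorTable(KmerVocabulary(3), rng.standard_normal((64, 100)))
        red = Linear(100, 64, rng, dtype=np.float64)
        pe = positional_embed(seq, 3, table, red)
        assert pe.shape == (99, 128)
        np.testing.assert_array_equal(pe[:, :64], onehot_kmers(kmerize(seq, 3)))
        assert (pe[:, :64].sum(axis=1) == 1).all()

    def test_zero_table_zeroes_distributed_half_only(self):
        rng = np.random.default_rng(10)
        seq = random_background(31, rng)
        table = KmerVectorTable(KmerVocabulary(3), np.zeros((64, 20)))
        red = Linear(20, 64, rng, dtype=np.float64)
        red.b.value[...] = 0
        pe = positional_embed(seq, 3, table, red)
        assert np.abs(pe[:, 64:]).sum() == 0
        assert pe[:, :64].sum() == 29
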