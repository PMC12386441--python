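"""Sequence encoders: KNF, TPCP, PCPS, tokenization, pooling, embedding,
and their fusion — checked against independent brute-force oracles."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epibesl.config import RunConfig
from epibesl.embedding import (KmerEmbeddingModel, adaptive_pool,
                               encode_dna2vec, tokenize_kmers,
                               train_kmer_embedding)
from epibesl.encoding import (FittedEncoders, PCPSModel, encode_knf,
                              encode_pcps, encode_tpcp, fit_conservation,
                              fit_position_score_matrix, four_encode,
                              load_property_table,
                              select_conserved_positions)
from epibesl.errors import (ConfigError, ModelStateError, ValidationError)

dna = st.text(alphabet="ACGT", min_size=8, max_size=60)
seed_rng = np.random.default_rng(99)


# ---------------------------------------------------------------------------
# KNF
# ---------------------------------------------------------------------------

class TestKnf:
    def test_default_width_and_blocks(self):
        m = encode_knf("ACGTACGTACGT")
        assert m.values.shape[1] == 340
        assert m.block_widths == (4, 16, 64, 256)

    def test_homopolymer_single_k(self):
        m = encode_knf("AAAA", k_list=(1,))
        assert m.values.shape == (4, 4)
        expected = np.zeros((4, 4))
        expected[:, 0] = 1.0          # f_A = 1 at index of A
        assert np.array_equal(m.values, expected)

    def test_acgt_dimers_hand_enumerated(self):
        m = encode_knf("ACGT", k_list=(2,))
        # 3 rows defined, right-padded to L - min(k) + 1 = 3 rows here
        assert m.values.shape == (3, 16)
        # AC=1, CG=6, GT=11 each appear once out of 3 windows
        expected = np.zeros((3, 16))
        expected[0, 1] = expected[1, 6] = expected[2, 11] = 1 / 3
        assert np.allclose(m.values, expected)

    @settings(derandomize=True, max_examples=25)
    @given(dna)
    def test_matches_counter_oracle(self, seq):
        """Every nonzero entry equals the whole-sequence k-mer frequency
        computed independently with a plain Counter."""
        k_list = (1, 2, 3)
        m = encode_knf(seq, k_list=k_list).values
        offset = 0
        alphabet = "ACGT"
        for k in k_list:
            windows = [seq[i:i + k] for i in range(len(seq) - k + 1)]
            counts = Counter(windows)
            total = len(windows)
            for i, w in enumerate(windows):
                idx = sum(alphabet.index(b) * 4 ** (k - 1 - j)
                          for j, b in enumerate(w))
                assert m[i, offset + idx] == pytest.approx(counts[w] / total)
            # rows beyond L-k+1 in this block are all zero
            assert np.all(m[len(windows):, offset:offset + 4 ** k] == 0)
            offset += 4 ** k

    def test_frequencies_form_distribution(self):
        seq = "ACGTAACCGGTTACGT"
        m = encode_knf(seq, k_list=(2,)).values
        present = {}
        for i in range(len(seq) - 1):
            j = np.argmax(m[i])
            present[j] = m[i, j]
        assert sum(present.values()) == pytest.approx(1.0)
        assert all(0 < v <= 1 for v in present.values())

    def test_n_windows_skipped(self):
        m = encode_knf("ANGT", k_list=(2,)).values
        assert np.all(m[0] == 0) and np.all(m[1] == 0)   # AN, NG contain N
        assert m[2].sum() == pytest.approx(1.0)          # GT is the only window

    def test_errors(self):
        with pytest.raises(ValidationError):
            encode_knf("ACG", k_list=(4,))
        with pytest.raises(ValidationError):
            encode_knf("ACGX", k_list=(1,))


# ---------------------------------------------------------------------------
# TPCP
# ---------------------------------------------------------------------------

class TestTpcp:
    def test_default_table_gives_704(self):
        vec = encode_tpcp("ACGTACGTACGT", load_property_table())
        assert vec.values.shape == (704,)

    def test_homopolymer_hits_only_aaa(self):
        table = load_property_table()
        vec = encode_tpcp("AAAAA", table).values
        pc = table.to_numpy()
        assert np.allclose(vec[:11], pc[0] * 1.0)        # f_AAA = 1
        assert np.all(vec[11:] == 0)

    def test_hand_computed_frequencies(self):
        table = load_property_table()
        vec = encode_tpcp("ACGACG", table).values        # ACG,CGA,GAC,ACG
        pc = table.to_numpy()
        tri_index = {t: i for i, t in enumerate(
            a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")}
        for tri, freq in (("ACG", 0.5), ("CGA", 0.25), ("GAC", 0.25)):
            i = tri_index[tri]
            assert np.allclose(vec[i * 11:(i + 1) * 11], pc[i] * freq)

    def test_wrong_shape_table_rejected(self):
        table = load_property_table().iloc[:10]
        with pytest.raises(ValidationError):
            encode_tpcp("ACGACG", table)


# ---------------------------------------------------------------------------
# PCPS
# ---------------------------------------------------------------------------

def conservation_oracle(seqs, k, f_e):
    """Direct definition: sum over all 4^k fragments of (f - f_e)^2 / f_e."""
    out = []
    for i in range(len(seqs[0]) - k + 1):
        frags = [s[i:i + k] for s in seqs if "N" not in s[i:i + k]]
        counts = Counter(frags)
        total = len(frags)
        c = 0.0
        from itertools import product
        for frag in map("".join, product("ACGT", repeat=k)):
            f = counts.get(frag, 0) / total
            c += (f - f_e) ** 2 / f_e
        out.append(c)
    return np.array(out)


class TestConservation:
    def test_unanimous_single_base_is_three(self):
        c = fit_conservation(["A", "A", "A"], k=1)
        assert c[0] == pytest.approx(3.0)

    def test_uniform_usage_is_zero(self):
        c = fit_conservation(["A", "C", "G", "T"], k=1)
        assert c[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(6)]
        for k in (1, 2):
            got = fit_conservation(seqs, k)
            want = conservation_oracle(seqs, k, 1.0 / 4 ** k)
            assert np.allclose(got, want)
            assert np.all(got >= -1e-12)

    def test_majority_replacement_increases_conservation(self):
        base = ["ACGTAC", "ACGTAC", "TTGTAC"]
        more = ["ACGTAC", "ACGTAC", "ACGTAC"]
        c_before = fit_conservation(base, k=2)[0]
        c_after = fit_conservation(more, k=2)[0]
        assert c_after > c_before

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            fit_conservation(["ACGT", "ACG"], k=1)


class TestPositionSelection:
    def test_argmax_order(self):
        assert list(select_conserved_positions(np.array([0.0, 5.0, 3.0]), 2)) == [1, 2]

    def test_tie_break_to_smaller_index(self):
        assert list(select_conserved_positions(np.ones(4), 2)) == [0, 1]

    def test_matches_sort_oracle(self):
        vals = seed_rng.random(40)
        got = select_conserved_positions(vals, 10)
        want = sorted(range(40), key=lambda i: (-vals[i], i))[:10]
        assert list(got) == want

    def test_contract(self):
        with pytest.raises(ValidationError):
            select_conserved_positions(np.ones(3), 0)
        with pytest.raises(ValidationError):
            select_conserved_positions(np.ones(3), 4)


class TestPositionScoreMatrix:
    @pytest.fixture
    def seqs(self):
        rng = np.random.default_rng(6)
        return ["".join(rng.choice(list("ACGT"), 30)) for _ in range(8)]

    def test_columns_are_probability_vectors(self, seqs):
        psm, psf = fit_position_score_matrix(seqs, [0, 3, 7], k=2)
        assert psm.shape == (16, 3)
        assert np.allclose(psm.sum(axis=0), 1.0, atol=1e-9)

    def test_psf_is_bijective_log_transform(self, seqs):
        f0 = 1.0 / 200.0
        psm, psf = fit_position_score_matrix(seqs, [0, 5], k=2, f0=f0)
        assert np.allclose(f0 * np.exp(psf), psm)

    def test_enriched_fragment_scores_positive(self):
        seqs = ["AC" + "GT" * 5] * 6            # AC unanimous at position 0
        psm, psf = fit_position_score_matrix(seqs, [0], k=2)
        ac = 0 * 4 + 1
        assert psf[ac, 0] > 0

    def test_empty_positions_rejected(self, seqs):
        with pytest.raises(ValidationError):
            fit_position_score_matrix(seqs, [], k=2)


class TestEncodePcps:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(10)]
        return PCPSModel.fit(seqs, k=3, m=5), seqs

    def test_vector_is_2m_long(self, model):
        m, seqs = model
        vec = encode_pcps(seqs[0], m)
        assert vec.shape == (10,)

    def test_deterministic(self, model):
        m, seqs = model
        assert np.array_equal(encode_pcps(seqs[1], m), encode_pcps(seqs[1], m))

    def test_n_fragment_scores_zero(self, model):
        m, seqs = model
        pos = int(m.selected_positions[0])
        seq = seqs[0][:pos] + "N" + seqs[0][pos + 1:]
        vec = encode_pcps(seq, m)
        assert vec[5] == 0.0                     # PSF half entry for that position

    def test_unfitted_model_rejected(self, model):
        _, seqs = model
        with pytest.raises(ModelStateError):
            encode_pcps(seqs[0], None)


# ---------------------------------------------------------------------------
# tokenization + pooling + embedding
# ---------------------------------------------------------------------------

class TestTokenize:
    def test_worked_example(self):
        assert tokenize_kmers("AGGTCCA", 5) == ["AGGTC", "GGTCC", "GTCCA"]

    def test_length_equals_k(self):
        assert tokenize_kmers("ACGTA", 5) == ["ACGTA"]

    def test_word_count_is_l_minus_k_plus_one(self):
        seq = "".join(seed_rng.choice(list("ACGT"), 100))
        assert len(tokenize_kmers(seq, 5)) == 96

    def test_short_sequence_yields_empty(self):
        assert tokenize_kmers("ACG", 5) == []


def pooling_oracle(x, p):
    n = x.shape[0]
    rows = []
    for i in range(p):
        lo = (i * n) // p
        hi = -((-(i + 1) * n) // p)
        rows.append(x[lo:hi].mean(axis=0))
    return np.array(rows)


class TestAdaptivePooling:
    def test_constant_input(self):
        x = np.tile([1.0, 2.0], (17, 1))
        out = adaptive_pool(x, 5)
        assert np.allclose(out, np.tile([1.0, 2.0], (5, 1)))

    def test_alternating_rows_average_pairwise(self):
        u, v = np.array([1.0, 0.0]), np.array([0.0, 2.0])
        x = np.array([u, v] * 6)                 # n = 2 * pooled_length
        out = adaptive_pool(x, 6)
        assert np.allclose(out, np.tile((u + v) / 2, (6, 1)))

    def test_mean_preserved_when_divisible(self):
        x = seed_rng.random((40, 3))
        out = adaptive_pool(x, 8)
        assert np.allclose(out.mean(axis=0), x.mean(axis=0), atol=1e-9)

    def test_short_input_repeats_rows(self):
        x = seed_rng.random((3, 2))
        out = adaptive_pool(x, 7)
        assert out.shape == (7, 2)
        assert np.allclose(out, pooling_oracle(x, 7))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(1, 30), st.integers(1, 20))
    def test_matches_bucket_oracle(self, n, p):
        x = np.random.default_rng(n * 100 + p).random((n, 2))
        assert np.allclose(adaptive_pool(x, p), pooling_oracle(x, p))


@pytest.fixture(scope="module")
def corpus():
    rng = np.random.default_rng(8)
    seqs = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(20)]
    return [tokenize_kmers(s, 3) for s in seqs]


class TestEmbedding:
    def test_vectors_have_requested_dim(self, corpus):
        model = train_kmer_embedding(corpus, k=3, dim=8, epochs=1, seed=0)
        assert model.vectors.shape[1] == 8

    def test_same_seed_identical(self, corpus):
        a = train_kmer_embedding(corpus, k=3, dim=4, epochs=1, seed=5)
        b = train_kmer_embedding(corpus, k=3, dim=4, epochs=1, seed=5)
        assert np.array_equal(a.vectors, b.vectors)

    def test_oov_maps_to_zero(self, corpus):
        model = train_kmer_embedding(corpus, k=3, dim=4, epochs=1, seed=0)
        out = model.lookup(["NNN"])
        assert np.array_equal(out, np.zeros((1, 4)))

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValidationError):
            train_kmer_embedding([[]], k=3, dim=4)

    def test_constant_vectors_pool_to_constant(self):
        vocab = {"AAA": 0, "AAC": 1}
        model = KmerEmbeddingModel(k=3, dim=2, vocabulary=vocab,
                                   vectors=np.tile([1.5, -2.0], (2, 1)),
                                   pooled_length=10)
        out = encode_dna2vec("AAAAAC", model)
        assert out.shape == (10, 2)
        assert np.allclose(out, np.tile([1.5, -2.0], (10, 1)))


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted(tiny_dataset):
    pairs, _, _, _ = tiny_dataset
    config = RunConfig.reduced(embed_epochs=1, embed_max_pairs=5000)
    return FittedEncoders.fit(pairs, config, seed=0), pairs, config


class TestFourEncode:
    def test_manifest_widths_cover_blocks(self, fitted):
        encoders, pairs, config = fitted
        enc = four_encode(pairs[0], encoders)
        conv_width = sum(e.width for e in enc.manifest if e.section == "conv")
        dense_width = sum(e.width for e in enc.manifest if e.section == "dense")
        assert enc.enhancer_conv.shape == (config.pooled_length, conv_width)
        assert enc.promoter_conv.shape == (config.pooled_length, conv_width)
        assert enc.enhancer_vec.shape == (dense_width,)

    def test_disabling_encoder_shrinks_by_its_width(self, fitted):
        encoders, pairs, config = fitted
        full = four_encode(pairs[0], encoders)
        knf_width = next(e.width for e in full.manifest if e.encoder == "knf")
        slim_cfg = RunConfig.reduced(
            encoders=("tpcp", "pcps", "dna2vec"),
            embed_epochs=1, embed_max_pairs=5000)
        slim_enc = FittedEncoders(
            config=slim_cfg, property_table=encoders.property_table,
            pcps_enhancer=encoders.pcps_enhancer,
            pcps_promoter=encoders.pcps_promoter,
            embedding=encoders.embedding)
        slim = four_encode(pairs[0], slim_enc)
        assert (full.enhancer_conv.shape[1] - slim.enhancer_conv.shape[1]
                == knf_width)

    def test_bit_identical_on_repeat(self, fitted):
        encoders, pairs, _ = fitted
        a = four_encode(pairs[3], encoders)
        b = four_encode(pairs[3], encoders)
        assert np.array_equal(a.enhancer_conv, b.enhancer_conv)
        assert np.array_equal(a.promoter_conv, b.promoter_conv)
        assert np.array_equal(a.enhancer_vec, b.enhancer_vec)

    def test_encoding_never_mutates_fitted_state(self, fitted):
        """Leakage guard: encoding unseen sequences must not touch models."""
        encoders, pairs, _ = fitted
        before = (encoders.embedding.vectors.copy(),
                  encoders.pcps_enhancer.psm.copy(),
                  encoders.pcps_promoter.psf.copy())
        rng = np.random.default_rng(12)
        from epibesl.io import EPPair
        unseen = EPPair("u", "".join(rng.choice(list("ACGT"), 180)),
                        "".join(rng.choice(list("ACGT"), 140)), label=0)
        four_encode(unseen, encoders)
        assert np.array_equal(before[0], encoders.embedding.vectors)
        assert np.array_equal(before[1], encoders.pcps_enhancer.psm)
        assert np.array_equal(before[2], encoders.pcps_promoter.psf)

    def test_mismatched_k_rejected(self, fitted):
        encoders, pairs, _ = fitted
        bad_cfg = RunConfig.reduced(embed_k=4)
        with pytest.raises(ConfigError):
            four_encode(pairs[0], encoders, bad_cfg)
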