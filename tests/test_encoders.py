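import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calpsite.encoders import (
    ALPHABET,
    N_PAIRS,
    FrequencyProfile,
    decode_binary,
    encode_aac,
    encode_all,
    encode_binary,
    encode_cksaap,
    encode_psfm,
    feature_dims,
    fit_frequency_profile,
)
from calpsite.sequence_io import LabeledDataset

from conftest import random_window


def brute_force_cksaap(window: str, kmax: int) -> np.ndarray:
    """O(W^2) double-loop oracle over all position pairs."""
    out = np.zeros((kmax + 1) * N_PAIRS)
    for i in range(len(window)):
        for j in range(len(window)):
            k = j - i - 1
            if 0 <= k <= kmax:
                pair = ALPHABET.index(window[i]) * 21 + ALPHABET.index(window[j])
                out[k * N_PAIRS + pair] += 1
    return out


def _make_dataset(pos_windows, neg_windows):
    windows = list(pos_windows) + list(neg_windows)
    labels = [1] * len(pos_windows) + [0] * len(neg_windows)
    prov = [("P", i + 1) for i in range(len(windows))]
    return LabeledDataset(windows, np.array(labels), prov)


class TestAAC:
    def test_homopolymer(self):
        v = encode_aac("A" * 30)
        assert v[0] == 1.0 and v[1:].sum() == 0

    def test_two_residues(self):
        v = encode_aac("A" * 15 + "C" * 15)
        assert v[0] == 0.5 and v[1] == 0.5 and v.sum() == 1.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_dimension_and_normalization(self, seed):
        v = encode_aac(random_window(np.random.default_rng(seed)))
        assert v.shape == (21,)
        assert np.isclose(v.sum(), 1.0)

    def test_unknown_symbol(self):
        with pytest.raises(ValueError):
            encode_aac("B" * 30)


class TestBinary:
    def test_alanine_bit_pattern(self):
        v = encode_binary("A" + "C" * 29)
        assert list(v[:21]) == [1] + [0] * 20

    def test_pad_bit_pattern(self):
        v = encode_binary("-" + "C" * 29)
        assert list(v[:21]) == [0] * 20 + [1]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_length_one_hot_and_roundtrip(self, seed):
        w = random_window(np.random.default_rng(seed))
        v = encode_binary(w)
        assert v.shape == (630,)
        assert v.sum() == 30
        assert all(v.reshape(30, 21).sum(axis=1) == 1)
        assert decode_binary(v) == w


class TestFrequencyProfile:
    def test_unanimous_position(self):
        pos = ["A" * 14 + "L" + "A" * 15] * 2
        neg = ["C" * 30]
        prof = fit_frequency_profile(_make_dataset(pos, neg))
        assert prof.pos_freq[14, ALPHABET.index("L")] == 1.0

    def test_split_position_hand_count(self):
        base = "A" * 30
        pos = [base[:15] + r + base[16:] for r in "KKRR"]
        prof = fit_frequency_profile(_make_dataset(pos, ["C" * 30]))
        assert prof.pos_freq[15, ALPHABET.index("K")] == 0.5
        assert prof.pos_freq[15, ALPHABET.index("R")] == 0.5

    def test_rows_sum_to_one(self, synth_dataset):
        prof = fit_frequency_profile(synth_dataset)
        assert np.allclose(prof.pos_freq.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(prof.neg_freq.sum(axis=1), 1.0, atol=1e-9)

    def test_permutation_invariance(self, synth_dataset):
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(synth_dataset))
        a = fit_frequency_profile(synth_dataset)
        b = fit_frequency_profile(synth_dataset.subset(perm))
        assert np.array_equal(a.pos_freq, b.pos_freq)
        assert np.array_equal(a.neg_freq, b.neg_freq)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_frequency_profile(_make_dataset(["A" * 30], []))

    def test_tsv_roundtrip_bit_exact(self, synth_dataset, tmp_path):
        prof = fit_frequency_profile(synth_dataset)
        prof.to_tsv(tmp_path / "p.tsv")
        back = FrequencyProfile.from_tsv(tmp_path / "p.tsv")
        assert np.array_equal(back.pos_freq, prof.pos_freq)
        assert np.array_equal(back.neg_freq, prof.neg_freq)


class TestPSFM:
    def test_exact_match_of_single_positive(self):
        pos = ["ACDEFGHIKLMNPQRSTVWY" + "A" * 10]
        prof = fit_frequency_profile(_make_dataset(pos, ["C" * 30]))
        v = encode_psfm(pos[0], prof)
        assert np.all(v[:30] == 1.0)

    def test_unseen_residue_scores_zero(self):
        prof = fit_frequency_profile(_make_dataset(["A" * 30], ["C" * 30]))
        v = encode_psfm("W" + "A" * 29, prof)
        assert v[30] == 0.0  # W never at position 1 in negatives

    def test_dimension_and_range(self, synth_dataset):
        prof = fit_frequency_profile(synth_dataset)
        v = encode_psfm(synth_dataset.windows[0], prof)
        assert v.shape == (60,)
        assert np.all((v >= 0) & (v <= 1))

    def test_length_mismatch(self):
        prof = fit_frequency_profile(_make_dataset(["A" * 30], ["C" * 30]))
        with pytest.raises(ValueError):
            encode_psfm("A" * 20, prof)


class TestCKSAAP:
    def test_adjacent_pairs_hand_counted(self):
        w = "AAA" + "-" * 27
        v = encode_cksaap(w, kmax=3)
        k0 = v[:N_PAIRS]
        assert k0[ALPHABET.index("A") * 21 + ALPHABET.index("A")] == 2
        assert k0[ALPHABET.index("A") * 21 + ALPHABET.index("-")] == 1

    def test_spaced_pairs_hand_counted(self):
        # k=1 pairs of "AAA----...": (A,A) at i=1; (A,-) at i=2 and i=3
        w = "AAA" + "-" * 27
        k1 = encode_cksaap(w, kmax=3)[N_PAIRS : 2 * N_PAIRS]
        assert k1[ALPHABET.index("A") * 21 + ALPHABET.index("A")] == 1
        assert k1[ALPHABET.index("A") * 21 + ALPHABET.index("-")] == 2

    def test_total_dimension(self):
        assert encode_cksaap("A" * 30, kmax=3).shape == (1764,)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_double_loop_oracle(self, seed):
        w = random_window(np.random.default_rng(seed))
        assert np.array_equal(encode_cksaap(w, 3), brute_force_cksaap(w, 3))

    @given(seed=st.integers(0, 10_000), k=st.integers(0, 3))
    @settings(max_examples=50, deadline=None)
    def test_block_sums_equal_pair_slots(self, seed, k):
        w = random_window(np.random.default_rng(seed))
        v = encode_cksaap(w, 3)
        assert v[k * N_PAIRS : (k + 1) * N_PAIRS].sum() == 30 - (k + 1)

    def test_kmax_too_large(self):
        with pytest.raises(ValueError):
            encode_cksaap("A" * 30, kmax=29)


class TestEncodeAll:
    def test_bundle_lengths(self, synth_dataset):
        prof = fit_frequency_profile(synth_dataset)
        b = encode_all(synth_dataset.windows[0], prof)
        assert [len(x) for x in b.as_list()] == [21, 630, 60, 1764]

    def test_determinism_bitwise(self, synth_dataset):
        prof = fit_frequency_profile(synth_dataset)
        w = synth_dataset.windows[3]
        b1, b2 = encode_all(w, prof), encode_all(w, prof)
        for x, y in zip(b1.as_list(), b2.as_list()):
            assert np.array_equal(x, y)

    def test_all_pad_window_aac(self, synth_dataset):
        prof = fit_frequency_profile(synth_dataset)
        b = encode_all("-" * 30, prof)
        assert b.aac[-1] == 1.0

    def test_dims_scale_with_flank(self):
        assert feature_dims(15, 3) == (21, 630, 60, 1764)
        assert feature_dims(10, 3) == (21, 420, 40, 1764)
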