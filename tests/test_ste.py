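"""Tercile symbolization, word embedding and transfer-entropy estimation."""

import numpy as np
import pytest

from brainfingerprint.preprocess import DifferencedSegment
from brainfingerprint.ste import (
    STEMatrix,
    TercileThresholds,
    embed,
    pooled_thresholds,
    ste_matrix,
    ste_pair,
    symbolize,
    symbolic_words,
    unembed,
)
from .conftest import brute_force_transfer_entropy


def _seg(data):
    return DifferencedSegment(participant_id=1, task=1, event=1, data=np.atleast_2d(data))


class TestTercileThresholds:
    def test_nine_point_pool(self):
        thr = pooled_thresholds(np.arange(-4.0, 5.0)[None, :])
        assert (thr.t_low, thr.t_high) == (-2.0, 1.0)

    def test_two_channel_pool(self):
        thr = pooled_thresholds(np.array([[1.0, 2, 3], [4, 5, 6]]))
        assert (thr.t_low, thr.t_high) == (2.0, 4.0)

    def test_degenerate_pool(self):
        thr = pooled_thresholds(np.full((2, 5), 3.3))
        assert thr.t_low == thr.t_high == 3.3

    def test_short_pool_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            pooled_thresholds(np.array([[1.0, 2.0]]))

    def test_symbolization_is_length_preserving_and_balanced(self, rng):
        data = rng.standard_normal(3000)
        thr = pooled_thresholds(data[None, :])
        sym = symbolize(data, thr)
        assert sym.shape == data.shape
        # pooled terciles split a continuous sample into near-equal thirds
        counts = np.bincount(sym, minlength=4)[1:]
        assert counts.min() > 0.9 * len(data) / 3


class TestSymbolize:
    def test_band_membership(self):
        thr = TercileThresholds(t_low=-2.0, t_high=1.0, pooled_length=9)
        np.testing.assert_array_equal(symbolize(np.array([-3.0, 0.0, 2.0]), thr), [1, 2, 3])

    def test_threshold_values_go_to_upper_band(self):
        thr = TercileThresholds(t_low=-2.0, t_high=1.0, pooled_length=9)
        np.testing.assert_array_equal(symbolize(np.array([-2.0, 1.0]), thr), [2, 3])

    def test_constant_channel_single_band(self):
        thr = TercileThresholds(t_low=0.0, t_high=1.0, pooled_length=10)
        np.testing.assert_array_equal(symbolize(np.full(5, -1.0), thr), 1)


def _de_bruijn_ternary_triples() -> np.ndarray:
    """Cyclic sequence over {1,2,3} containing every length-3 word once
    (standard prefer-largest construction), linearized to 29 symbols."""
    seq = []
    a = [0] * 4

    def db(t, p):
        if t > 3:
            if 3 % p == 0:
                seq.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, 3):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    cyc = np.array(seq) + 1
    return np.concatenate([cyc, cyc[:2]])


class TestEmbedding:
    def test_constant_sequence(self):
        words = embed(np.array([1, 1, 1, 1]), m=3, tau=1)
        assert len(words) == 2 and words[0] == words[1]

    def test_single_word_round_trips(self):
        words = embed(np.array([1, 2, 3]), m=3)
        assert len(words) == 1
        assert unembed(int(words[0]), m=3) == (1, 2, 3)

    def test_de_bruijn_sequence_covers_all_27_words(self):
        seq = _de_bruijn_ternary_triples()
        assert len(seq) == 29
        words = embed(seq, m=3, tau=1)
        assert sorted(set(int(w) for w in words)) == list(range(1, 28))

    def test_length_reduction(self, rng):
        sym = rng.integers(1, 4, 100)
        for m, tau in [(1, 1), (2, 1), (3, 1), (3, 2)]:
            assert len(embed(sym, m=m, tau=tau)) == 100 - (m - 1) * tau

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            embed(np.array([1, 2]), m=3, tau=1)


class TestStePair:
    def test_constant_sequences_zero(self):
        assert ste_pair(np.ones(50, int), np.full(50, 2)) == 0.0

    def test_copy_coupling_approaches_log2_3(self, rng):
        n = 10_000
        x = rng.integers(1, 4, n)
        y = np.empty(n, dtype=int)
        y[0] = 1
        y[1:] = x[:-1]  # target reproduces the source's fresh symbol one step later
        te = ste_pair(x, y)
        assert abs(te - np.log2(3)) < 0.05

    def test_independent_sequences_near_zero(self, rng):
        te = ste_pair(rng.integers(1, 4, 10_000), rng.integers(1, 4, 10_000))
        assert te < 0.05

    def test_matches_brute_force_counter(self, rng):
        for _ in range(20):
            src = rng.integers(1, 28, 60)
            tgt = rng.integers(1, 28, 60)
            assert ste_pair(src, tgt) == pytest.approx(
                brute_force_transfer_entropy(src, tgt), abs=1e-12
            )

    def test_eight_word_toy_pair(self):
        src = np.array([1, 2, 1, 2, 1, 2, 1, 2])
        tgt = np.array([2, 1, 2, 1, 2, 1, 2, 1])
        assert ste_pair(src, tgt) == pytest.approx(
            brute_force_transfer_entropy(src, tgt), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ste_pair(np.ones(5, int), np.ones(6, int))

    def test_surrogate_permutation_destroys_coupling(self, rng):
        n = 5000
        x = rng.integers(1, 4, n)
        y = np.empty(n, dtype=int)
        y[0] = 1
        y[1:] = x[:-1]
        coupled = ste_pair(x, y)
        shuffled = ste_pair(rng.permutation(x), y)
        assert shuffled < 0.05 < coupled


class TestSteMatrix:
    def test_matches_pairwise_estimates(self, rng):
        data = rng.standard_normal((5, 300))
        seg = _seg(data)
        mat = ste_matrix(seg)
        words = symbolic_words(seg)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else ste_pair(words[i], words[j])
                assert mat.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_independent_channels_small_offdiagonal(self, rng):
        seg = _seg(rng.standard_normal((64, 5001)))
        mat = ste_matrix(seg)
        off = mat.values[~np.eye(64, dtype=bool)]
        assert off.mean() < 0.05

    def test_duplicated_channel_symmetry(self, rng):
        row = rng.standard_normal(400)
        seg = _seg(np.stack([row, row, rng.standard_normal(400)]))
        mat = ste_matrix(seg)
        assert mat.values[0, 1] == pytest.approx(mat.values[1, 0], abs=1e-12)

    def test_channel_permutation_equivariance(self, rng):
        data = rng.standard_normal((6, 500))
        perm = rng.permutation(6)
        m1 = ste_matrix(_seg(data)).values
        m2 = ste_matrix(_seg(data[perm])).values
        np.testing.assert_allclose(m2, m1[np.ix_(perm, perm)], atol=1e-12)

    def test_word_level_estimation_supported(self, rng):
        seg = _seg(rng.standard_normal((4, 600)))
        mat = ste_matrix(seg, m=3)
        assert mat.values.shape == (4, 4)
        assert np.all(mat.values >= 0)

    def test_tsv_round_trip(self, tmp_path, rng):
        data = rng.standard_normal((4, 300))
        mat = ste_matrix(DifferencedSegment(participant_id=7, task=2, event=3, data=data))
        path = tmp_path / "m.tsv"
        mat.to_tsv(path)
        back = STEMatrix.from_tsv(path)
        np.testing.assert_allclose(back.values, mat.values, rtol=1e-9)
        assert (back.participant_id, back.task, back.event) == (7, 2, 3)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="diagonal"):
            STEMatrix(np.eye(3))
        with pytest.raises(ValueError, match="non-negative"):
            STEMatrix(np.array([[0, -1.0], [0, 0]]))
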