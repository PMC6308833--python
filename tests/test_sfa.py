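import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mboss import (
    MCBTable,
    SFAParams,
    count_possible_words,
    dft_coefficients,
    discretize,
    fit_mcb,
    mft_sliding_coefficients,
    sliding_coefficients,
)
from mboss.sfa import symbol_indices


def raw_params(w, l, drop=False):
    return SFAParams(
        window_size=w,
        word_length=l,
        alphabet_size=4,
        drop_first_coeff=drop,
        normalize_windows=False,
    )


class TestDFT:
    def test_constant_window_keeps_only_dc(self):
        out = dft_coefficients([5.0, 5.0, 5.0, 5.0], raw_params(4, 4))
        np.testing.assert_allclose(out, [5.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_four_point_closed_form(self):
        out = dft_coefficients([1.0, 2.0, 3.0, 4.0], raw_params(4, 4))
        np.testing.assert_allclose(out, [2.5, 0.0, -0.5, 0.5], atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_dc_real_part_is_the_mean(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=32)
        out = dft_coefficients(x, raw_params(32, 8))
        assert out[0] == pytest.approx(x.mean(), abs=1e-12)
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            dft_coefficients(np.ones(8), SFAParams(window_size=18, word_length=8))


class TestMFT:
    def test_window_count(self):
        params = SFAParams(window_size=30, word_length=8)
        out = mft_sliding_coefficients(np.random.default_rng(0).normal(size=256), params)
        assert out.shape == (227, 8)

    def test_single_window_equals_direct_dft(self):
        params = raw_params(16, 8)
        x = np.random.default_rng(1).normal(size=16)
        out = mft_sliding_coefficients(x, params)
        np.testing.assert_allclose(out[0], dft_coefficients(x, params), atol=1e-12)

    def test_matches_per_window_dft_oracle(self):
        """Recursive sliding coefficients agree elementwise with the direct
        per-window DFT within 1e-8."""
        params = raw_params(16, 8, drop=True)
        rng = np.random.default_rng(42)
        x = rng.normal(size=64)
        got = mft_sliding_coefficients(x, params)
        want = np.array(
            [dft_coefficients(x[i : i + 16], params) for i in range(64 - 16 + 1)]
        )
        assert np.abs(got - want).max() < 1e-8


class TestMCB:
    def test_equi_depth_split_of_four_values(self):
        table = fit_mcb(np.array([[1.0], [2.0], [3.0], [4.0]]), c=2)
        assert table.breakpoints[1, 0] == 3.0
        idx = symbol_indices(np.array([[1.0], [2.0], [3.0], [4.0]]), table)
        assert idx.ravel().tolist() == [0, 0, 1, 1]

    def test_c_distinct_values_one_per_bin(self):
        col = np.arange(4.0).reshape(-1, 1)
        table = fit_mcb(col, c=4)
        idx = symbol_indices(col, table).ravel()
        assert idx.tolist() == [0, 1, 2, 3]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_mcb(np.ones((2, 3)), c=4)
        with pytest.raises(ValueError):
            fit_mcb(np.empty((0, 3)), c=4)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(10, 80))
    @settings(deadline=None, max_examples=50)
    def test_equi_depth_occupancy(self, seed, c, n_rows):
        """On tie-free columns every bin holds between floor(N/c) and
        ceil(N/c) training values."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(n_rows, 4))
        table = fit_mcb(A, c=c)
        idx = symbol_indices(A, table)
        for j in range(4):
            occ = np.bincount(idx[:, j], minlength=c)
            assert occ.min() >= n_rows // c
            assert occ.max() <= -(-n_rows // c)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_monotone_quantization(self, seed):
        """Within a column a larger coefficient never maps to an earlier symbol."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(40, 2))
        table = fit_mcb(A, c=4)
        vals = np.sort(rng.normal(size=100))
        idx = symbol_indices(np.column_stack([vals, vals]), table)
        assert np.all(np.diff(idx[:, 0].astype(int)) >= 0)
        assert np.all(np.diff(idx[:, 1].astype(int)) >= 0)


class TestDiscretize:
    def _table(self):
        bp = np.array(
            [
                [-np.inf, -np.inf],
                [0.0, 1.0],
                [2.0, 3.0],
                [np.inf, np.inf],
            ]
        )
        return MCBTable(bp, "abc")

    def test_boundary_joins_upper_interval(self):
        assert discretize([0.0, 1.0], self._table()) == "bb"
        assert discretize([2.0, 3.0], self._table()) == "cc"
        assert discretize([-0.1, 0.9], self._table()) == "aa"

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=40)
    def test_agrees_with_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(30, 6))
        table = fit_mcb(A, c=5)
        v = rng.normal(size=6)
        word = discretize(v, table)
        # independent linear interval scan
        expect = []
        for j in range(6):
            col = table.breakpoints[:, j]
            a = 0
            while not (col[a] <= v[j] < col[a + 1]):
                a += 1
            expect.append(table.alphabet[a])
        assert word == "".join(expect)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            discretize([0.0], self._table())


class TestMCBSerialization:
    def test_json_round_trip_with_infinity_sentinels(self):
        rng = np.random.default_rng(21)
        table = fit_mcb(rng.normal(size=(30, 6)), c=4)
        loaded = MCBTable.from_json(table.to_json())
        assert loaded.alphabet == table.alphabet
        np.testing.assert_array_equal(loaded.breakpoints, table.breakpoints)
        assert '"-inf"' in table.to_json() and '"inf"' in table.to_json()


class TestWordSpace:
    @pytest.mark.parametrize(
        "l,c,expected", [(16, 4, 4294967296), (1, 1, 1), (4, 6, 1296)]
    )
    def test_counts(self, l, c, expected):
        assert count_possible_words(l, c) == expected

    def test_overflow_guard(self):
        with pytest.raises(OverflowError):
            count_possible_words(16, 26)


class TestOffsetInvariance:
    @given(st.integers(0, 2**31 - 1), st.floats(-100.0, 100.0))
    @settings(deadline=None, max_examples=25)
    def test_dropping_dc_makes_words_offset_invariant(self, seed, offset):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=64)
        params = SFAParams(
            window_size=20, word_length=8, drop_first_coeff=True,
            normalize_windows=False,
        )
        base = sliding_coefficients(x, params)
        shifted = sliding_coefficients(x + offset, params)
        # quantizer fitted on an independent series, so breakpoints do not
        # coincide with the compared coefficients
        table = fit_mcb(sliding_coefficients(rng.normal(size=64), params), c=4)
        np.testing.assert_array_equal(
            symbol_indices(base, table), symbol_indices(shifted, table)
        )
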