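import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meripvar.models import GeneModel, WindowGrid
from meripvar.winscore import (
    amalgamate_peaks,
    build_window_grid,
    compute_winscore,
    peak_ratio_matrix,
    quantile_normalize,
)


def _grid(tx_len):
    return build_window_grid(GeneModel("g", "c", "+", exons=[(0, tx_len)]))


class TestWindowGrid:
    @pytest.mark.parametrize(
        "tx_len,expected",
        [
            (300, [(0, 100), (50, 150), (100, 200), (150, 250), (200, 300)]),
            (100, [(0, 100)]),
            (130, [(0, 100), (50, 130)]),
            (50, [(0, 50)]),
        ],
    )
    def test_window_layout(self, tx_len, expected):
        assert _grid(tx_len).windows == expected

    def test_too_short_transcript_rejected(self):
        with pytest.raises(ValueError, match="skipped"):
            _grid(49)

    @given(st.integers(min_value=50, max_value=5000))
    @settings(max_examples=60, deadline=None)
    def test_windows_tile_transcript(self, tx_len):
        g = _grid(tx_len)
        assert g.windows[0][0] == 0
        assert g.windows[-1][1] == tx_len
        for i, (s, e) in enumerate(g.windows):
            assert s == 50 * i
            assert e - s >= 50 or len(g.windows) == 1
            assert e - s <= 100


class TestWinscore:
    def test_threshold_is_strict(self):
        # RPKM_ip 3, RPKM_input 1 -> (3+1)/(1+1) = 2.0 exactly: not a peak
        grid = WindowGrid("g", 100, [(0, 100)])
        q = compute_winscore(np.array([3]), np.array([1]), grid, lib_ip=10**7, lib_input=10**7)
        assert q.rpkm_ip[0] == pytest.approx(3.0)
        assert q.winscore[0] == pytest.approx(2.0)
        assert not q.is_peak[0]

    def test_zero_counts_give_unit_winscore(self):
        grid = WindowGrid("g", 100, [(0, 100)])
        q = compute_winscore(np.array([0]), np.array([0]), grid, 10**6, 10**6)
        assert q.winscore[0] == pytest.approx(1.0)
        assert not q.is_peak[0]

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(42)
        grid = WindowGrid("g", 50 * 1001, [(50 * i, 50 * i + 100) for i in range(1000)])
        ip = rng.integers(0, 500, 1000)
        inp = rng.integers(0, 500, 1000)
        lib_ip, lib_in = 3_000_000, 2_000_000
        q = compute_winscore(ip, inp, grid, lib_ip, lib_in)
        # independent two-line implementation
        oracle = (ip * 1e9 / (100 * lib_ip) + 1) / (inp * 1e9 / (100 * lib_in) + 1)
        assert np.max(np.abs(q.winscore - oracle)) < 1e-12

    def test_library_scale_invariance(self):
        # scaling counts and library size together leaves RPKM and winscore fixed
        rng = np.random.default_rng(1)
        grid = WindowGrid("g", 50 * 21, [(50 * i, 50 * i + 100) for i in range(20)])
        ip = rng.integers(0, 100, 20)
        inp = rng.integers(0, 100, 20)
        q1 = compute_winscore(ip, inp, grid, 10**6, 10**6)
        q2 = compute_winscore(ip * 7, inp * 7, grid, 7 * 10**6, 7 * 10**6)
        assert np.allclose(q1.winscore, q2.winscore, atol=1e-12)

    def test_length_mismatch_errors(self):
        grid = WindowGrid("g", 100, [(0, 100)])
        with pytest.raises(ValueError, match="mismatch"):
            compute_winscore(np.array([1, 2]), np.array([1, 2]), grid, 10, 10)


class TestAmalgamate:
    def _grids(self, n=40):
        return {"g1": WindowGrid("g1", 50 * (n + 1), [(50 * i, 50 * i + 100) for i in range(n)])}

    def _flags(self, idx, n=40):
        v = np.zeros(n, dtype=bool)
        v[list(idx)] = True
        return {"g1": v}

    def test_union_across_samples_merges_adjacent(self):
        peaks = amalgamate_peaks({"a": self._flags({1, 2}), "b": self._flags({3})}, self._grids())
        assert len(peaks) == 1
        assert (peaks[0].window_start, peaks[0].window_end) == (1, 3)

    def test_long_run_split_five_plus_two(self):
        peaks = amalgamate_peaks({"a": self._flags(range(3, 10))}, self._grids())
        assert [(p.window_start, p.window_end) for p in peaks] == [(3, 7), (8, 9)]

    def test_no_flags_gives_empty_list(self):
        assert amalgamate_peaks({"a": self._flags(set())}, self._grids()) == []

    @pytest.mark.parametrize("run_len", range(1, 21))
    def test_every_run_partitioned_into_chunks_of_at_most_five(self, run_len):
        peaks = amalgamate_peaks({"a": self._flags(range(run_len))}, self._grids())
        covered = [w for p in peaks for w in p.window_indices]
        assert covered == list(range(run_len))
        assert all(1 <= p.n_windows <= 5 for p in peaks)

    def test_inconsistent_grids_error(self):
        with pytest.raises(ValueError, match="inconsistent"):
            amalgamate_peaks({"a": self._flags({1}, n=10)}, self._grids(40))

    def test_flagged_windows_conserved_on_random_input(self):
        rng = np.random.default_rng(5)
        flags = {s: {"g1": rng.random(40) < 0.3} for s in "abcd"}
        peaks = amalgamate_peaks(flags, self._grids())
        union = set(np.nonzero(np.any([flags[s]["g1"] for s in "abcd"], axis=0))[0])
        covered = {w for p in peaks for w in p.window_indices}
        assert covered == union


class TestPeakRatioMatrix:
    def _quant(self, rpkm_ip, rpkm_input):
        from meripvar.winscore import WindowQuant

        n = len(rpkm_ip)
        grid = WindowGrid("g1", 50 * (n + 1), [(50 * i, 50 * i + 100) for i in range(n)])
        r_ip, r_in = np.asarray(rpkm_ip, float), np.asarray(rpkm_input, float)
        score = (r_ip + 1) / (r_in + 1)
        return WindowQuant(grid, r_ip, r_in, score, score > 2)

    def test_max_rule_with_na_floor(self):
        from meripvar.models import Peak

        q = self._quant([20, 30, 40], [10, 5, 4])
        mat, _ = peak_ratio_matrix([Peak("p", "g1", 0, 2)], {"s": {"g1": q}}, majority_na_drop=False)
        # candidates 2.0, 6.0, NA -> 6.0 (input RPKM 5.0 exactly is kept)
        assert mat.loc["p", "s"] == pytest.approx(6.0)

    def test_all_low_input_gives_na(self):
        from meripvar.models import Peak

        q = self._quant([20, 20], [4.9, 4.9])
        mat, _ = peak_ratio_matrix([Peak("p", "g1", 0, 1)], {"s": {"g1": q}}, majority_na_drop=False)
        assert np.isnan(mat.loc["p", "s"])

    @pytest.mark.parametrize("n_samples", range(2, 9))
    def test_majority_na_rule_is_strict(self, n_samples):
        from meripvar.models import Peak

        for n_na in range(n_samples + 1):
            quants = {}
            for i in range(n_samples):
                if i < n_na:
                    quants[f"s{i}"] = {"g1": self._quant([20], [1])}  # input < 5 -> NA
                else:
                    quants[f"s{i}"] = {"g1": self._quant([20], [10])}
            mat, report = peak_ratio_matrix([Peak("p", "g1", 0, 0)], quants)
            if n_na > n_samples / 2:
                assert len(mat) == 0 and report["reason"].tolist() == ["na_majority"]
            else:
                assert len(mat) == 1

    def test_empty_peak_list_gives_empty_matrix(self):
        mat, _ = peak_ratio_matrix([], {"s": {}})
        assert mat.empty


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m.astype(float))

    def test_textbook_two_columns(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_column_sorted_values_identical_on_complete_matrix(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.gamma(2.0, 2.0, size=(200, 6)), columns=list("abcdef"))
        out = quantile_normalize(m)
        ref = np.sort(out["a"].to_numpy())
        for c in "bcdef":
            assert np.max(np.abs(np.sort(out[c].to_numpy()) - ref)) < 1e-12

    def test_na_mask_preserved(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.gamma(2.0, 2.0, size=(50, 4)), columns=list("abcd"))
        mask = rng.random((50, 4)) < 0.2
        m = m.mask(mask)
        out = quantile_normalize(m)
        assert (out.isna() == m.isna()).all().all()

    def test_ties_share_the_mean_reference_value(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_too_few_values_error_names_sample(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [np.nan, np.nan, 1.0]})
        with pytest.raises(ValueError, match="b"):
            quantile_normalize(m)
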