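import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meripvar.heterogeneity import (
    cv_fold_change,
    differential_methylation,
    sample_correlation,
    select_specific_sites,
    site_cv,
)


def _matrix(rows, columns=None):
    arr = np.asarray(rows, dtype=float)
    columns = columns or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])], columns=columns)


class TestSiteCV:
    def test_constant_values_have_zero_cv(self):
        cv = site_cv(_matrix([[1, 1, 1]]), {"s0": "g", "s1": "g", "s2": "g"})
        assert cv["cv"].iloc[0] == 0.0

    def test_two_value_arithmetic_with_sample_sd(self):
        cv = site_cv(_matrix([[2, 4]]), {"s0": "g", "s1": "g"}, min_n=2)
        assert cv["cv"].iloc[0] == pytest.approx(np.sqrt(2) / 3, abs=1e-4)

    def test_na_aware_computation(self):
        cv = site_cv(_matrix([[2, 4, np.nan, 6]]), {f"s{i}": "g" for i in range(4)})
        row = cv.iloc[0]
        assert (row["n_nonNA"], row["mean"], row["sd"], row["cv"]) == (3, 4.0, 2.0, 0.5)

    def test_too_few_values_give_na(self):
        cv = site_cv(_matrix([[2, 4, np.nan]]), {f"s{i}": "g" for i in range(3)})
        assert np.isnan(cv["cv"].iloc[0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(3, 2, size=(20, 6))
        groups = {f"s{i}": "g" for i in range(6)}
        cv1 = site_cv(_matrix(vals), groups)["cv"].to_numpy()
        cv2 = site_cv(_matrix(vals * 37.5), groups)["cv"].to_numpy()
        assert np.max(np.abs(cv1 - cv2)) < 1e-12

    def test_unknown_sample_in_group_map_errors(self):
        with pytest.raises(ValueError, match="absent"):
            site_cv(_matrix([[1, 2, 3]]), {"nope": "g"})


class TestSpecificSites:
    def test_threshold_is_strict(self):
        tab = pd.DataFrame(
            {"peak_id": ["a", "b"], "group_id": ["g", "g"], "cv": [0.30, 0.31]}
        )
        sel = select_specific_sites(tab)
        assert sel == {"g": {"b"}}

    def test_site_may_be_specific_to_several_groups(self):
        tab = pd.DataFrame(
            {"peak_id": ["a", "a"], "group_id": ["g1", "g2"], "cv": [0.5, 0.6]}
        )
        sel = select_specific_sites(tab)
        assert sel == {"g1": {"a"}, "g2": {"a"}}


class TestCVFoldChange:
    def _tab(self, cvs, group):
        return pd.DataFrame({"peak_id": [f"p{i}" for i in range(len(cvs))],
                             "group_id": group, "cv": cvs})

    def test_identical_groups_fc_one(self):
        a = self._tab([0.2, 0.4], "cancer")
        per_peak, _ = cv_fold_change(a, self._tab([0.2, 0.4], "normal"))
        assert np.allclose(per_peak["fc"], 1.0)

    def test_fc_arithmetic(self):
        per_peak, _ = cv_fold_change(self._tab([0.45], "c"), self._tab([0.15], "n"))
        assert per_peak["fc"].iloc[0] == pytest.approx(3.0)

    def test_na_propagates(self):
        per_peak, _ = cv_fold_change(self._tab([np.nan], "c"), self._tab([0.15], "n"))
        assert np.isnan(per_peak["fc"].iloc[0])

    def test_segment_medians(self):
        a = self._tab([0.6, 0.6, 0.2], "c")
        b = self._tab([0.2, 0.2, 0.2], "n")
        seg = pd.Series(["start_codon", "start_codon", "stop_codon"], index=["p0", "p1", "p2"])
        _, summary = cv_fold_change(a, b, segments=seg)
        med = summary.set_index("segment")["median_fc"]
        assert med["start_codon"] == pytest.approx(3.0)
        assert med["stop_codon"] == pytest.approx(1.0)


class TestDifferentialMethylation:
    def _cond(self, n_cancer, n_normal):
        cols = [f"c{i}" for i in range(n_cancer)] + [f"n{i}" for i in range(n_normal)]
        return cols, {c: ("cancer" if c.startswith("c") else "normal") for c in cols}

    def test_identical_groups_t_zero_p_one(self):
        cols, cond = self._cond(3, 3)
        m = pd.DataFrame([[2.0, 2.0, 2.0, 2.0, 2.0, 2.0]], index=["p0"], columns=cols)
        dm = differential_methylation(m, cond)
        assert np.isnan(dm["t_statistic"].iloc[0]) or dm["t_statistic"].iloc[0] == 0.0
        assert dm["p_value"].iloc[0] == 1.0 or np.isnan(dm["p_value"].iloc[0])

    def test_welch_agrees_with_pooled_t_on_equal_design(self):
        rng = np.random.default_rng(1)
        cols, cond = self._cond(8, 8)
        X = rng.normal(0, 1, (50, 16))
        m = pd.DataFrame(X, index=[f"p{i}" for i in range(50)], columns=cols)
        dm = differential_methylation(m, cond)
        pooled = stats.ttest_ind(X[:, :8], X[:, 8:], axis=1, equal_var=True).statistic
        assert np.max(np.abs(dm["t_statistic"].to_numpy() - pooled)) < 1e-9

    def test_skip_rule_reported_and_bh_over_tested_universe(self):
        cols, cond = self._cond(4, 4)
        X = np.random.default_rng(2).normal(0, 1, (10, 8))
        m = pd.DataFrame(X, index=[f"p{i}" for i in range(10)], columns=cols)
        m.iloc[0, :3] = np.nan  # only 1 cancer value left -> skipped
        dm = differential_methylation(m, cond).set_index("peak_id")
        assert not dm.loc["p0", "tested"]
        assert np.isnan(dm.loc["p0", "fdr"])
        assert dm.loc[dm["tested"], "fdr"].notna().all()

    def test_bh_monotone_in_rank_and_bounded(self):
        cols, cond = self._cond(6, 6)
        X = np.random.default_rng(3).normal(0, 1, (200, 12))
        X[:20, :6] += 1.5
        m = pd.DataFrame(X, index=[f"p{i}" for i in range(200)], columns=cols)
        dm = differential_methylation(m, cond)
        sorted_fdr = dm.sort_values("p_value")["fdr"].to_numpy()
        assert (np.diff(sorted_fdr) >= -1e-12).all()
        assert (dm["fdr"] <= 1).all()
        assert (dm["fdr"] >= dm["p_value"] - 1e-12).all()

    def test_missing_condition_errors(self):
        cols, _ = self._cond(3, 0)
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p0"], columns=cols)
        with pytest.raises(ValueError, match="both conditions"):
            differential_methylation(m, {c: "cancer" for c in cols})


class TestSampleCorrelation:
    def test_duplicate_columns_perfectly_correlated(self):
        rng = np.random.default_rng(4)
        v = rng.normal(0, 1, 30)
        m = pd.DataFrame({"a": v, "b": v, "c": rng.normal(0, 1, 30)})
        corr, order, Z = sample_correlation(m)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert set(order) == {"a", "b", "c"}

    def test_anticorrelated_pair(self):
        v = np.arange(10.0)
        m = pd.DataFrame({"a": v, "b": -v, "c": v + np.random.default_rng(0).normal(0, 0.1, 10)})
        corr, _, _ = sample_correlation(m)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_sparse_pair_excluded_with_warning(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 1.0, 4.0, 3.0],
                          "c": [np.nan, np.nan, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="excluded"):
            corr, order, _ = sample_correlation(m)
        assert "c" not in order
        assert np.isnan(corr.loc["a", "c"])
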