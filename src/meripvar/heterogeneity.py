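"""CV-based heterogeneity, cancer-specific site selection, differential
methylation and sample-level correlation clustering.

The coefficient of variation (CV = SD / mean, sample SD with the n-1
denominator) of the normalized m6A ratio across a group's samples measures
how variable a site is; sites with CV strictly above 0.3 within a cancer
group are flagged as specific to that cancer type. Differential methylation
is a per-site Welch t-test (two-sided, unpaired, unequal variance) between
conditions with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

CV_THRESHOLD = 0.3
MIN_GROUP_N = 3


def site_cv(matrix: pd.DataFrame, groups: dict[str, str], min_n: int = MIN_GROUP_N) -> pd.DataFrame:
    """Per (peak, group) mean, SD and CV over non-NA entries.

    CV is NA when fewer than ``min_n`` non-NA values are available or the
    mean is not positive (the ratio scale is positive, so a non-positive
    mean marks a degenerate group).
    """
    unknown = set(groups.values())
    rows = []
    for group in sorted(unknown):
        cols = [s for s, g in groups.items() if g == group]
        missing = [c for c in cols if c not in matrix.columns]
        if missing:
            raise ValueError(f"group {group}: sample(s) absent from matrix: {missing}")
        sub = matrix[cols]
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = sd / mean
        cv[(n < min_n) | (mean <= 0)] = np.nan
        rows.append(
            pd.DataFrame(
                {"peak_id": matrix.index, "group_id": group, "n_nonNA": n.to_numpy(),
                 "mean": mean.to_numpy(), "sd": sd.to_numpy(), "cv": cv.to_numpy()}
            )
        )
    return pd.concat(rows, ignore_index=True)


def select_specific_sites(cv_table: pd.DataFrame, threshold: float = CV_THRESHOLD) -> dict[str, set[str]]:
    """Sites with CV strictly above ``threshold`` per group (a site may be
    specific to several groups)."""
    out: dict[str, set[str]] = {}
    hit = cv_table[cv_table["cv"] > threshold]
    for group, sub in hit.groupby("group_id"):
        out[str(group)] = set(sub["peak_id"])
    return out


def cv_fold_change(
    cv_cancer: pd.DataFrame, cv_normal: pd.DataFrame, segments: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peak CV fold change (cancer / normal) and per-segment median FC.

    Inputs are single-group slices of a CV table indexed compatibly by
    ``peak_id``. FC is NA wherever either CV is NA. Returns
    ``(per_peak, per_segment_summary)``.
    """
    a = cv_cancer.set_index("peak_id")["cv"]
    b = cv_normal.set_index("peak_id")["cv"]
    common = a.index.intersection(b.index)
    fc = a.loc[common] / b.loc[common]
    per_peak = pd.DataFrame({"peak_id": common, "cv_cancer": a.loc[common].to_numpy(),
                             "cv_normal": b.loc[common].to_numpy(), "fc": fc.to_numpy()})
    if segments is not None:
        per_peak["segment"] = per_peak["peak_id"].map(segments)
        summary = (
            per_peak.dropna(subset=["fc"]).groupby("segment", observed=True)["fc"].median().rename("median_fc").reset_index()
        )
        empty = [s for s in segments.dropna().unique() if s not in set(summary["segment"])]
        if empty:
            warnings.warn(f"segment(s) with no scoreable peaks: {empty}")
    else:
        summary = pd.DataFrame({"segment": ["all"], "median_fc": [float(np.nanmedian(fc))]})
    return per_peak, summary


def differential_methylation(
    matrix: pd.DataFrame, condition_map: dict[str, str], min_n: int = MIN_GROUP_N, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch t-test per site between cancer and normal, BH-adjusted.

    Sites with fewer than ``min_n`` non-NA values in either condition are
    skipped and reported with ``tested = False``; BH runs over the tested
    universe only.
    """
    cancer = [s for s, c in condition_map.items() if c == "cancer" and s in matrix.columns]
    normal = [s for s, c in condition_map.items() if c == "normal" and s in matrix.columns]
    if not cancer or not normal:
        raise ValueError("both conditions must be present among the matrix samples")
    rows = []
    for pid, row in matrix.iterrows():
        x = row[cancer].dropna().to_numpy(dtype=float)
        y = row[normal].dropna().to_numpy(dtype=float)
        rec = {"peak_id": pid, "n_cancer": len(x), "n_normal": len(y),
               "mean_cancer": np.mean(x) if len(x) else np.nan,
               "mean_normal": np.mean(y) if len(y) else np.nan,
               "t_statistic": np.nan, "df": np.nan, "p_value": np.nan, "tested": False}
        if len(x) >= min_n and len(y) >= min_n:
            res = stats.ttest_ind(x, y, equal_var=False)
            rec.update(t_statistic=float(res.statistic), df=float(res.df), p_value=float(res.pvalue), tested=True)
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p_value"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < alpha
    return out


def sample_correlation(matrix: pd.DataFrame, min_common: int = 3):
    """Pairwise-complete Pearson correlation between samples plus an
    average-linkage dendrogram order on distance 1 - r.

    Pairs sharing fewer than ``min_common`` non-NA sites get an NA entry and
    the offending samples are excluded from clustering with a warning.
    Returns ``(corr_matrix, leaf_order, linkage_matrix)``.
    """
    corr = matrix.corr(method="pearson", min_periods=min_common)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    ok = corr.index[corr.notna().all(axis=1)]
    dropped = [s for s in corr.index if s not in set(ok)]
    if dropped:
        warnings.warn(f"sample(s) excluded from clustering (too few common sites): {dropped}")
    sub = corr.loc[ok, ok]
    if len(ok) < 2:
        return corr, list(ok), None
    dist = 1.0 - sub.to_numpy()
    iu = np.triu_indices(len(ok), k=1)
    linkage = hierarchy.linkage(np.maximum(dist[iu], 0.0), method="average")
    order = [ok[i] for i in hierarchy.leaves_list(linkage)]
    return corr, order, linkage
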