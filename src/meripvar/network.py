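"""Regulator-expression vs m6A-level correlation and network construction.

Each candidate edge correlates one regulator's log2(TPM + 1) expression with
one cancer-specific site's normalized m6A ratio across the samples of a
group (pairwise-complete). Regulator classes (classical writers/erasers/
readers vs additional cell-specific trans-factors) come from user-supplied
lists. The network keeps edges passing an |r| floor after BH adjustment
across all candidates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_R_MIN = 0.6
DEFAULT_FDR_MAX = 0.05
MIN_PAIRS = 5


def regulator_site_correlation(
    expression: pd.DataFrame,
    matrix: pd.DataFrame,
    specific_sites: dict[str, set[str]],
    regulator_classes: dict[str, str],
    group_samples: dict[str, list[str]] | None = None,
    min_pairs: int = MIN_PAIRS,
) -> pd.DataFrame:
    """Pearson r and p per (regulator, specific site, group).

    ``specific_sites`` maps group_id -> site ids; ``group_samples`` maps
    group_id -> the samples to correlate over (defaults to all shared
    samples, i.e. pooled). Constant vectors yield an undefined r and the
    edge is dropped with a reason; regulators absent from the expression
    table are skipped with a warning.
    """
    if group_samples is None:
        group_samples = {g: [s for s in matrix.columns] for g in specific_sites}
    rows = []
    for group, sites in specific_sites.items():
        samples = [s for s in group_samples[group] if s in matrix.columns and s in expression.columns]
        if len(samples) < min_pairs:
            warnings.warn(f"group {group}: fewer than {min_pairs} shared samples, skipped")
            continue
        for reg, klass in regulator_classes.items():
            if reg not in expression.index:
                warnings.warn(f"regulator {reg} absent from expression table, skipped")
                continue
            x_full = np.log2(expression.loc[reg, samples].to_numpy(dtype=float) + 1.0)
            for site in sorted(sites):
                if site not in matrix.index:
                    continue
                y_full = matrix.loc[site, samples].to_numpy(dtype=float)
                ok = ~np.isnan(y_full)
                x, y = x_full[ok], y_full[ok]
                if len(x) < min_pairs:
                    continue
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    rows.append({"regulator_id": reg, "regulator_class": klass, "peak_id": site,
                                 "group_id": group, "r": np.nan, "p_value": np.nan,
                                 "n_pairs": len(x), "status": "dropped_constant"})
                    continue
                r, p = stats.pearsonr(x, y)
                rows.append({"regulator_id": reg, "regulator_class": klass, "peak_id": site,
                             "group_id": group, "r": float(r), "p_value": float(p),
                             "n_pairs": len(x), "status": "ok"})
    edges = pd.DataFrame(rows, columns=["regulator_id", "regulator_class", "peak_id", "group_id",
                                        "r", "p_value", "n_pairs", "status"])
    return edges.sort_values("r", key=lambda s: -s.abs(), kind="stable").reset_index(drop=True)


def permuted_null_edges(
    expression: pd.DataFrame,
    matrix: pd.DataFrame,
    specific_sites: dict[str, set[str]],
    regulator_classes: dict[str, str],
    seed: int,
    group_samples: dict[str, list[str]] | None = None,
    min_pairs: int = MIN_PAIRS,
) -> pd.DataFrame:
    """Edges recomputed after permuting the matrix's sample labels (seeded)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(matrix.shape[1])
    permuted = pd.DataFrame(matrix.to_numpy()[:, perm], index=matrix.index, columns=matrix.columns)
    out = regulator_site_correlation(
        expression, permuted, specific_sites, regulator_classes, group_samples, min_pairs
    )
    out["regulator_class"] = "permuted_null"
    return out


def class_comparison(edges: pd.DataFrame, null_edges: pd.DataFrame | None = None, min_edges: int = 10):
    """Cumulative |r| curves per regulator class (plus the permuted null)
    and a two-sided rank-sum test between the two real classes.

    Returns ``(curves, test_stat, test_p)`` where ``curves`` holds the
    empirical CDF of |r| per class as a long-format table.
    """
    ok = edges[edges["status"] == "ok"].copy()
    classes = sorted(ok["regulator_class"].unique())
    if len(classes) < 2:
        raise ValueError("class comparison needs >= 2 regulator classes")
    groups = {}
    for klass in classes:
        vals = ok.loc[ok["regulator_class"] == klass, "r"].abs().to_numpy()
        if len(vals) < min_edges:
            raise ValueError(f"class {klass}: fewer than {min_edges} edges")
        groups[klass] = vals
    if null_edges is not None:
        nv = null_edges.loc[null_edges["status"] == "ok", "r"].abs().to_numpy()
        if len(nv):
            groups["permuted_null"] = nv
    curves = []
    for klass, vals in groups.items():
        v = np.sort(vals)
        cdf = np.arange(1, len(v) + 1) / len(v)
        curves.append(pd.DataFrame({"regulator_class": klass, "abs_r": v, "cum_fraction": cdf}))
    stat, p = stats.mannwhitneyu(groups[classes[0]], groups[classes[1]], alternative="two-sided")
    return pd.concat(curves, ignore_index=True), float(stat), float(p)


def build_network(
    edges: pd.DataFrame, r_min: float = DEFAULT_R_MIN, fdr_max: float = DEFAULT_FDR_MAX
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Threshold edges by |r| and BH-adjusted p; emit Sankey-ready tables.

    BH runs across all candidate edges with a defined p-value. Returns
    ``(edge_table, node_table)``; an empty network is valid (warned).
    """
    ok = edges[edges["status"] == "ok"].copy()
    if ok.empty:
        warnings.warn("no candidate edges; network is empty")
        return ok.assign(fdr=np.nan), pd.DataFrame(columns=["node_id", "node_type"])
    ok["fdr"] = multipletests(ok["p_value"], method="fdr_bh")[1]
    kept = ok[(ok["r"].abs() >= r_min) & (ok["fdr"] < fdr_max)].copy()
    kept["sign"] = np.sign(kept["r"]).astype(int)
    if kept.empty:
        warnings.warn("no edge passes the |r| and FDR thresholds; network is empty")
    nodes = pd.concat(
        [
            pd.DataFrame({"node_id": kept["regulator_id"].unique(), "node_type": "regulator"}),
            pd.DataFrame({"node_id": kept["group_id"].unique(), "node_type": "group"}),
            pd.DataFrame({"node_id": kept["peak_id"].unique(), "node_type": "site"}),
        ],
        ignore_index=True,
    )
    return kept.reset_index(drop=True), nodes
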