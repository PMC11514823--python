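"""Peak annotation onto the mega-gene frame and distribution statistics.

The mega gene is a composite transcript whose 5'UTR, CDS and 3'UTR are each
scaled to 10 bins (30 bins total); a peak's ``metagene_coord`` in [0, 3) is
its region index plus the fraction of the way through that region. Start-
and stop-codon "segments" are the +/- ``flank`` nt neighborhoods of the
codon's first base (default one window width, 100 nt).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModel, Peak, WindowGrid

SEGMENTS = ("5UTR", "start_codon", "CDS", "stop_codon", "3UTR")
DEFAULT_FLANK = 100


def annotate_peak_segment(
    peak: Peak, gene_model: GeneModel, grid: WindowGrid, flank: int = DEFAULT_FLANK
) -> dict:
    """Segment, mega-gene coordinate and host-exon class of one peak.

    The peak midpoint (transcript coordinates) decides everything. Midpoints
    within ``flank`` nt of the start (stop) codon's first base are labeled
    ``start_codon`` (``stop_codon``), the nearer codon winning ties;
    otherwise the pure 5UTR/CDS/3UTR partition applies. ``metagene_coord``
    always uses the pure partition. Non-coding genes get NA segment and
    coordinate (they have no UTR/CDS frame).
    """
    t_start = grid.windows[peak.window_start][0]
    t_end = grid.windows[peak.window_end][1]
    mid = (t_start + t_end) / 2.0
    row = {
        "peak_id": peak.peak_id,
        "gene_id": peak.gene_id,
        "tx_midpoint": mid,
        "segment": pd.NA,
        "metagene_coord": np.nan,
        "host_exon_length": np.nan,
        "exon_position": pd.NA,
    }
    # host exon of the midpoint
    off = 0
    n_ex = len(gene_model.exons)
    for k, (s, e) in enumerate(gene_model.exons):
        n = e - s
        if mid < off + n or k == n_ex - 1:
            row["host_exon_length"] = float(n)
            row["exon_position"] = (
                "single" if n_ex == 1 else "first" if k == 0 else "last" if k == n_ex - 1 else "internal"
            )
            break
        off += n
    if not gene_model.is_coding:
        return row

    u5, cds, u3 = gene_model.utr5_len, gene_model.cds_len, gene_model.utr3_len
    start_tx, stop_tx = gene_model.cds_start_tx, gene_model.cds_end_tx
    d_start, d_stop = abs(mid - start_tx), abs(mid - stop_tx)
    if flank > 0 and d_start <= flank and d_start <= d_stop:
        row["segment"] = "start_codon"
    elif flank > 0 and d_stop <= flank:
        row["segment"] = "stop_codon"
    elif mid < u5:
        row["segment"] = "5UTR"
    elif mid < u5 + cds:
        row["segment"] = "CDS"
    else:
        row["segment"] = "3UTR"
    if mid < u5:
        row["metagene_coord"] = mid / u5
    elif mid < u5 + cds:
        row["metagene_coord"] = 1.0 + (mid - u5) / cds
    else:
        row["metagene_coord"] = 2.0 + (mid - u5 - cds) / u3 if u3 > 0 else 3.0 - 1e-9
    return row


def annotate_peaks(
    peaks: list[Peak],
    gene_models: dict[str, GeneModel],
    grids: dict[str, WindowGrid],
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    rows = [annotate_peak_segment(p, gene_models[p.gene_id], grids[p.gene_id], flank) for p in peaks]
    return pd.DataFrame(rows)


def metagene_profile(annotations: pd.DataFrame) -> pd.DataFrame:
    """30-bin mega-gene density (10 bins per region), normalized to mean 1."""
    coords = annotations["metagene_coord"].dropna().to_numpy(dtype=float)
    if coords.size == 0:
        raise ValueError("metagene profile needs at least one coding-gene annotation")
    counts, edges = np.histogram(coords, bins=np.linspace(0.0, 3.0, 31))
    density = counts / counts.mean() if counts.mean() > 0 else counts.astype(float)
    region = np.repeat(["5UTR", "CDS", "3UTR"], 10)
    return pd.DataFrame(
        {"bin": np.arange(30), "region": region, "bin_start": edges[:-1], "count": counts, "density": density}
    )


def submotif_chisq(count_table: pd.DataFrame):
    """Pearson chi-squared on a motif x group contingency table.

    All-zero motif rows are dropped with a warning (df adjusts); a group
    with zero total is an error. Returns
    ``(statistic, p_value, expected, standardized_residuals)``.
    """
    tab = count_table.astype(float)
    if (tab.to_numpy() < 0).any():
        raise ValueError("contingency table must be nonnegative")
    if tab.shape[1] < 2:
        raise ValueError("need at least 2 groups")
    zero_groups = tab.columns[tab.sum(axis=0) == 0]
    if len(zero_groups):
        raise ValueError(f"group(s) with zero total: {list(zero_groups)}")
    zero_rows = tab.index[tab.sum(axis=1) == 0]
    if len(zero_rows):
        warnings.warn(f"dropping all-zero motif row(s): {list(zero_rows)}")
        tab = tab.drop(index=zero_rows)
    stat, p, dof, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
    exp_df = pd.DataFrame(expected, index=tab.index, columns=tab.columns)
    resid = (tab - exp_df) / np.sqrt(exp_df)
    return float(stat), float(p), exp_df, resid


def exon_length_comparison(annotations_a: pd.DataFrame, annotations_b: pd.DataFrame):
    """Two-sided rank-sum test on log10 host-exon length, internal exons only.

    First, last and single exons are excluded (terminal exons confound
    length with UTR content). Returns
    ``(statistic, p_value, median_a, median_b)`` with medians on the raw
    nucleotide scale.
    """

    def _lengths(ann: pd.DataFrame) -> np.ndarray:
        sub = ann[ann["exon_position"] == "internal"]
        return sub["host_exon_length"].dropna().to_numpy(dtype=float)

    a, b = _lengths(annotations_a), _lengths(annotations_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"need >= 3 internal-exon peaks per group (got {len(a)} and {len(b)})")
    stat, p = stats.mannwhitneyu(np.log10(a), np.log10(b), alternative="two-sided")
    return float(stat), float(p), float(np.median(a)), float(np.median(b))
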