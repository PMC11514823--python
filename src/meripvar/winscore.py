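"""Window-based m6A quantification.

The engine scans each gene with 100-nt sliding windows overlapping by 50 nt,
computes IP and input RPKM per window, calls windows with
``winscore = (RPKM_IP + 1) / (RPKM_input + 1) > 2`` as peaks, merges flagged
windows across samples into amalgamated peaks of at most five windows, and
summarizes each peak per sample as the maximum per-window IP/input RPKM
ratio (the m6A ratio). Ratios whose defining input RPKM is below 5 are NA;
peaks NA in a strict majority of samples are dropped. The ratio matrix is
then quantile-normalized across samples.

The +1 pseudocount applies only to peak calling; the reported m6A ratio is
the plain RPKM ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import GeneModel, Peak, WindowGrid

WINDOW_NT = 100
STEP_NT = 50
WINSCORE_THRESHOLD = 2.0
PSEUDOCOUNT = 1.0
INPUT_RPKM_FLOOR = 5.0
MAX_PEAK_WINDOWS = 5


def build_window_grid(gene_model: GeneModel, window: int = WINDOW_NT, step: int = STEP_NT) -> WindowGrid:
    """Sliding windows over the transcript; terminal partial window kept if >= step nt.

    Raises ``ValueError`` for transcripts shorter than ``step`` (callers skip
    such genes with a warning).
    """
    L = gene_model.tx_length
    if L < step:
        raise ValueError(f"gene {gene_model.gene_id}: transcript length {L} < {step}, skipped")
    n = max(1, math.ceil((L - step) / step))
    windows = [(step * i, min(step * i + window, L)) for i in range(n)]
    return WindowGrid(gene_id=gene_model.gene_id, tx_length=L, windows=windows)


def rpkm(counts: np.ndarray, window_lengths: np.ndarray, library_size: int) -> np.ndarray:
    """Reads per kilobase of window per million mapped library reads."""
    if library_size <= 0:
        raise ValueError("library size must be > 0")
    return counts * 1e9 / (window_lengths * library_size)


@dataclass
class WindowQuant:
    """Per-window quantification of one sample over one gene's grid."""

    grid: WindowGrid
    rpkm_ip: np.ndarray
    rpkm_input: np.ndarray
    winscore: np.ndarray
    is_peak: np.ndarray


def compute_winscore(
    counts_ip: np.ndarray,
    counts_input: np.ndarray,
    grid: WindowGrid,
    lib_ip: int,
    lib_input: int,
    threshold: float = WINSCORE_THRESHOLD,
    pseudocount: float = PSEUDOCOUNT,
) -> WindowQuant:
    counts_ip = np.asarray(counts_ip, dtype=float)
    counts_input = np.asarray(counts_input, dtype=float)
    if counts_ip.shape != (grid.n_windows,) or counts_input.shape != (grid.n_windows,):
        raise ValueError(
            f"gene {grid.gene_id}: counts length mismatch with grid of {grid.n_windows} windows"
        )
    wlen = np.array([e - s for s, e in grid.windows], dtype=float)
    r_ip = rpkm(counts_ip, wlen, lib_ip)
    r_in = rpkm(counts_input, wlen, lib_input)
    score = (r_ip + pseudocount) / (r_in + pseudocount)
    return WindowQuant(grid=grid, rpkm_ip=r_ip, rpkm_input=r_in, winscore=score, is_peak=score > threshold)


def _split_run(start: int, end: int, max_len: int = MAX_PEAK_WINDOWS) -> list[tuple[int, int]]:
    """Greedy left-to-right split of an inclusive index run into <= max_len chunks."""
    chunks = []
    i = start
    while i <= end:
        j = min(i + max_len - 1, end)
        chunks.append((i, j))
        i = j + 1
    return chunks


def amalgamate_peaks(
    flags_by_sample: dict[str, dict[str, np.ndarray]],
    grids: dict[str, WindowGrid],
    max_windows: int = MAX_PEAK_WINDOWS,
) -> list[Peak]:
    """Union per-sample peak-window flags, merge adjacent windows, split long runs.

    ``flags_by_sample`` maps sample_id -> gene_id -> boolean vector aligned
    to the gene's grid. Runs longer than ``max_windows`` are split greedily
    left to right; peak ids are ``gene:runStart:chunk`` and stable.
    """
    union: dict[str, np.ndarray] = {}
    for sample_id, per_gene in flags_by_sample.items():
        for gid, flags in per_gene.items():
            if gid not in grids or len(flags) != grids[gid].n_windows:
                raise ValueError(f"sample {sample_id}: flags for gene {gid} inconsistent with grid")
            if gid in union:
                union[gid] |= np.asarray(flags, dtype=bool)
            else:
                union[gid] = np.asarray(flags, dtype=bool).copy()
    peaks: list[Peak] = []
    for gid in sorted(union):
        idx = np.nonzero(union[gid])[0]
        if idx.size == 0:
            continue
        run_start = idx[0]
        prev = idx[0]
        runs = []
        for i in idx[1:]:
            if i != prev + 1:
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))
        for rs, re in runs:
            for k, (cs, ce) in enumerate(_split_run(int(rs), int(re), max_windows)):
                peaks.append(Peak(peak_id=f"{gid}:{int(rs)}:{k}", gene_id=gid, window_start=cs, window_end=ce))
    return peaks


def peak_ratio_matrix(
    peaks: list[Peak],
    quants_by_sample: dict[str, dict[str, WindowQuant]],
    input_floor: float = INPUT_RPKM_FLOOR,
    majority_na_drop: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """m6A ratio per (peak, sample): max over the peak's windows of IP/input RPKM.

    A window's candidate ratio is NA when its input RPKM is below
    ``input_floor`` (exactly 5.0 is kept); the peak is NA when every
    candidate is NA. Peaks NA in strictly more than half of the samples are
    dropped. Returns ``(matrix, dropped_report)``; the matrix has peaks as
    rows and samples as columns.
    """
    samples = list(quants_by_sample)
    values = np.full((len(peaks), len(samples)), np.nan)
    for pi, pk in enumerate(peaks):
        for si, sid in enumerate(samples):
            q = quants_by_sample[sid].get(pk.gene_id)
            if q is None:
                raise ValueError(f"sample {sid} lacks quantification for gene {pk.gene_id}")
            sl = slice(pk.window_start, pk.window_end + 1)
            r_ip, r_in = q.rpkm_ip[sl], q.rpkm_input[sl]
            ok = r_in >= input_floor
            if ok.any():
                values[pi, si] = np.max(r_ip[ok] / r_in[ok])
    mat = pd.DataFrame(values, index=[p.peak_id for p in peaks], columns=samples)
    if not majority_na_drop or mat.empty:
        return mat, pd.DataFrame(columns=["peak_id", "n_na", "n_samples", "reason"])
    n_na = mat.isna().sum(axis=1)
    drop = n_na > len(samples) / 2  # strict majority; an exact half is kept
    report = pd.DataFrame(
        {
            "peak_id": mat.index[drop],
            "n_na": n_na[drop].to_numpy(),
            "n_samples": len(samples),
            "reason": "na_majority",
        }
    )
    return mat.loc[~drop], report


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rank-based quantile normalization across columns, NA-aware.

    The reference distribution is the mean of the per-column order
    statistics, each interpolated onto a common grid of quantile positions
    so columns with unequal non-NA counts contribute comparably. Ties within
    a column receive the mean of the reference values at their tied ranks;
    NA entries are untouched.
    """
    counts = matrix.notna().sum(axis=0)
    too_few = counts[counts < 2]
    if len(too_few):
        raise ValueError(f"quantile normalization needs >= 2 non-NA values per sample; offending: {list(too_few.index)}")
    n_ref = int(counts.max())
    grid = np.linspace(0.0, 1.0, n_ref)
    ref = np.zeros(n_ref)
    for col in matrix.columns:
        v = np.sort(matrix[col].dropna().to_numpy(dtype=float))
        ref += np.interp(grid, np.linspace(0.0, 1.0, v.size), v)
    ref /= matrix.shape[1]

    out = matrix.copy().astype(float)
    for col in matrix.columns:
        mask = matrix[col].notna().to_numpy()
        v = matrix[col].to_numpy(dtype=float)[mask]
        n = v.size
        # reference order statistics for this column's sample size
        ref_n = np.interp(np.linspace(0.0, 1.0, n), grid, ref)
        order = np.argsort(v, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref_n
        # average the assigned reference values over tied observations
        df_t = pd.DataFrame({"v": v, "a": assigned})
        assigned = df_t.groupby("v")["a"].transform("mean").to_numpy()
        col_out = np.full(len(matrix), np.nan)
        col_out[mask] = assigned
        out[col] = col_out
    return out
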