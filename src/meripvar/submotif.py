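"""Sub-motif permutation analysis.

For each of the four m6A sub-motifs (GGACA, AGACU, GGACU, GAACU) the
observed statistic is the number of peak windows containing at least one
match on the transcript sense strand. The null shuffles the nucleotides
within each peak sequence (composition-preserving), rescans, and recounts;
repeating ``n_iter`` times yields the expected-value distribution and an
empirical p-value ``(1 + #{null >= observed}) / (n_iter + 1)``. For
cross-sample display the per-motif percentages are mean-centered.

An alternative null that permutes motif labels among the fixed occurrence
positions is available via ``mode="label_permute"`` but is not the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import GeneModel, Peak, WindowGrid

SUBMOTIFS = ("GGACA", "AGACU", "GGACU", "GAACU")


@dataclass
class PeakSequence:
    """Spliced sense-strand sequence of one peak plus its window offsets."""

    peak_id: str
    seq: str
    window_bounds: list[tuple[int, int]]  # offsets within seq, one per grid window


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _transcript_seq(gm: GeneModel, sequences: dict[str, str]) -> str:
    parts = []
    for s, e in gm.exons:
        block = sequences[gm.chrom][s:e]
        parts.append(block if gm.strand == "+" else block.translate(_COMPLEMENT)[::-1])
    return "".join(parts)


def peak_sequences(
    peaks: list[Peak],
    grids: dict[str, WindowGrid],
    gene_models: dict[str, GeneModel],
    sequences: dict[str, str],
) -> list[PeakSequence]:
    """Extract each peak's spliced transcript sequence from the genome."""
    tx_cache: dict[str, str] = {}
    out = []
    for pk in peaks:
        gm = gene_models[pk.gene_id]
        if pk.gene_id not in tx_cache:
            tx_cache[pk.gene_id] = _transcript_seq(gm, sequences)
        grid = grids[pk.gene_id]
        t0 = grid.windows[pk.window_start][0]
        t1 = grid.windows[pk.window_end][1]
        bounds = [(grid.windows[w][0] - t0, grid.windows[w][1] - t0) for w in pk.window_indices]
        out.append(PeakSequence(peak_id=pk.peak_id, seq=tx_cache[pk.gene_id][t0:t1], window_bounds=bounds))
    return out


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _match_matrix(arr2d: np.ndarray, motif: np.ndarray) -> np.ndarray:
    """Boolean matrix of motif match-start positions; rows are sequences."""
    L, k = arr2d.shape[1], motif.size
    if L < k:
        return np.zeros((arr2d.shape[0], 0), dtype=bool)
    m = arr2d[:, : L - k + 1] == motif[0]
    for j in range(1, k):
        m &= arr2d[:, j : L - k + 1 + j] == motif[j]
    return m


def _count_windows(match: np.ndarray, bounds: list[tuple[int, int]]) -> np.ndarray:
    """Per row: number of windows with >= 1 match starting inside them."""
    n = match.shape[1]
    total = np.zeros(match.shape[0], dtype=np.int64)
    for ws, we in bounds:
        lo, hi = max(0, ws), min(we, n)
        if lo < hi:
            total += match[:, lo:hi].any(axis=1)
    return total


def submotif_shuffle_test(
    peak_seqs: list[PeakSequence],
    n_iter: int = 10_000,
    seed: int = 0,
    motifs: tuple[str, ...] = SUBMOTIFS,
    mode: str = "shuffle",
) -> pd.DataFrame:
    """Composition-preserving permutation test for sub-motif enrichment.

    Returns one row per motif: ``observed`` window count, null ``expected``
    mean and sd, ``pct`` of total observed, mean-``centered_pct``, and
    ``empirical_p``.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if mode not in ("shuffle", "label_permute"):
        raise ValueError(f"unknown mode {mode!r}")
    usable = []
    for ps in peak_seqs:
        if len(ps.seq) < 5:
            warnings.warn(f"peak {ps.peak_id}: sequence shorter than 5 nt, excluded")
        else:
            usable.append(ps)
    if not usable:
        raise ValueError("no peak sequence of at least 5 nt")
    rng = np.random.default_rng(seed)
    dna = [np.frombuffer(m.replace("U", "T").encode(), dtype=np.uint8) for m in motifs]

    observed = np.zeros(len(motifs), dtype=np.int64)
    arrs = [_encode(ps.seq) for ps in usable]
    for arr, ps in zip(arrs, usable):
        row = arr[None, :]
        for mi, mot in enumerate(dna):
            observed[mi] += _count_windows(_match_matrix(row, mot), ps.window_bounds)[0]

    null = np.zeros((n_iter, len(motifs)), dtype=np.int64)
    if mode == "shuffle":
        for arr, ps in zip(arrs, usable):
            tiled = np.tile(arr, (n_iter, 1))
            shuffled = rng.permuted(tiled, axis=1)
            for mi, mot in enumerate(dna):
                null[:, mi] += _count_windows(_match_matrix(shuffled, mot), ps.window_bounds)
    else:
        null += _label_permute_null(arrs, usable, dna, n_iter, rng)

    p = (1 + (null >= observed[None, :]).sum(axis=0)) / (n_iter + 1)
    total = observed.sum()
    pct = 100.0 * observed / total if total > 0 else np.zeros(len(motifs))
    return pd.DataFrame(
        {
            "motif": list(motifs),
            "observed": observed,
            "expected_mean": null.mean(axis=0),
            "expected_sd": null.std(axis=0, ddof=1),
            "pct": pct,
            "centered_pct": pct - pct.mean(),
            "empirical_p": p,
        }
    )


def _label_permute_null(arrs, usable, dna, n_iter, rng) -> np.ndarray:
    """Permute motif labels among the pooled observed occurrence positions."""
    occ = []  # (peak_index, position, motif_index)
    for pi, (arr, ps) in enumerate(zip(arrs, usable)):
        row = arr[None, :]
        for mi, mot in enumerate(dna):
            for pos in np.nonzero(_match_matrix(row, mot)[0])[0]:
                occ.append((pi, int(pos), mi))
    null = np.zeros((n_iter, len(dna)), dtype=np.int64)
    if not occ:
        return null
    labels = np.array([mi for _, _, mi in occ])
    for it in range(n_iter):
        perm = rng.permutation(labels)
        seen: dict[tuple[int, int, int], bool] = {}
        for (pi, pos, _), lab in zip(occ, perm):
            for wi, (ws, we) in enumerate(usable[pi].window_bounds):
                if ws <= pos < we:
                    seen[(pi, wi, int(lab))] = True
        for (_pi, _wi, lab) in seen:
            null[it, lab] += 1
    return null
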