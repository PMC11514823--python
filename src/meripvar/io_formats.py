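"""Readers and writers for the standard formats the pipeline touches.

Conventions
-----------
* GTF input is 1-based inclusive (per the GTF standard) and is converted to
  0-based half-open at this boundary; BED output is natively 0-based.
* A gene's CDS features are taken to span the start codon through the stop
  codon inclusive; the stop codon therefore lies inside the annotated CDS.
* Ratio matrices are TSV with row index ``peak_id``, columns ``sample_id``
  and the literal ``NA`` for missing values.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .models import GeneModel, Peak, SampleRecord, WindowGrid

logger = logging.getLogger(__name__)

SAMPLE_SHEET_REQUIRED = ("sample_id", "tissue", "condition", "batch")


class GtfParseError(ValueError):
    pass


def _validate_gtf_lines(gtf_path: str | Path) -> None:
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{gtf_path}: malformed GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"{gtf_path}: malformed GTF line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GtfParseError(f"{gtf_path}: malformed GTF line {lineno}: bad interval {start}..{end}")


def read_gene_models(gtf_path: str | Path) -> list[GeneModel]:
    """Load one :class:`GeneModel` per gene from a GTF file.

    The longest annotated transcript (by summed exon length) represents each
    gene. Genes without CDS features are retained as non-coding (UTR and CDS
    lengths 0). A transcript whose CDS falls outside its exons is skipped
    with a warning.
    """
    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # transcript_id -> (gene_id, strand, chrom, exons, cds_intervals)
    tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [None])[0]
        if tid is None or gid is None:
            raise GtfParseError(f"{gtf_path}: {feat.featuretype} feature lacking gene_id/transcript_id")
        rec = tx.setdefault(tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exon": [], "CDS": []})
        rec[feat.featuretype].append((feat.start - 1, feat.end))  # to 0-based half-open

    by_gene: dict[str, list[tuple[str, dict]]] = {}
    for tid, rec in tx.items():
        by_gene.setdefault(rec["gene_id"], []).append((tid, rec))

    models: list[GeneModel] = []
    for gid in sorted(by_gene):
        candidates = by_gene[gid]
        tid, rec = max(candidates, key=lambda item: (sum(e - s for s, e in item[1]["exon"]), item[0]))
        exons = sorted(rec["exon"], reverse=(rec["strand"] == "-"))
        gm = GeneModel(gene_id=gid, chrom=rec["chrom"], strand=rec["strand"], exons=exons)
        if rec["CDS"]:
            cds = sorted(rec["CDS"])
            first, last = cds[0][0], cds[-1][1] - 1  # genomic extremes of the CDS span
            five_prime, three_prime = (first, last) if rec["strand"] == "+" else (last, first)
            try:
                gm.cds_start = five_prime
                # first base of the stop codon, computed in transcript space so
                # a junction-spanning stop codon projects correctly
                gm.cds_end = gm.tx_to_genome(gm.genome_to_tx(three_prime) - 2)
                gm.validate_cds()
            except ValueError as exc:
                warnings.warn(f"gene {gid} skipped: {exc}")
                continue
        models.append(gm)
    return models


def write_gene_models_gtf(models: list[GeneModel], path: str | Path) -> None:
    """Serialize gene models back to GTF (exon + CDS features, stop codon in CDS)."""
    with open(path, "w") as fh:
        for gm in models:
            attrs = f'gene_id "{gm.gene_id}"; transcript_id "{gm.gene_id}.t1";'
            for s, e in sorted(gm.exons):
                fh.write(f"{gm.chrom}\tmeripvar\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t{attrs}\n")
            if gm.is_coding:
                t0, t1 = gm.cds_start_tx, gm.cds_end_tx + 3
                for s, e in gm.tx_interval_to_blocks(t0, t1):
                    fh.write(f"{gm.chrom}\tmeripvar\tCDS\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t{attrs}\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_sample_sheet(tsv_path: str | Path) -> list[SampleRecord]:
    """Parse and validate the experiment manifest."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{tsv_path}: sample sheet missing required column(s): {', '.join(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{tsv_path}: duplicate sample_id(s): {', '.join(sorted(set(dup)))}")
    bad = sorted(set(df["condition"]) - set(SampleRecord.VALID_CONDITIONS))
    if bad:
        raise ValueError(
            f"{tsv_path}: invalid condition value(s) {bad}; allowed values are {list(SampleRecord.VALID_CONDITIONS)}"
        )
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                tissue=row["tissue"],
                condition=row["condition"],
                batch=row["batch"],
                ip_counts_source=row.get("ip_counts_source", "") or "",
                input_counts_source=row.get("input_counts_source", "") or "",
                ip_library_size=int(row["ip_library_size"]) if "ip_library_size" in df.columns else 0,
                input_library_size=int(row["input_library_size"]) if "input_library_size" in df.columns else 0,
            )
        )
    for rec in records:
        if rec.ip_library_size < 0 or rec.input_library_size < 0:
            raise ValueError(f"sample {rec.sample_id}: library sizes must be positive")
    return records


def write_sample_sheet(records: list[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "tissue": [r.tissue for r in records],
            "condition": [r.condition for r in records],
            "batch": [r.batch for r in records],
            "ip_counts_source": [r.ip_counts_source for r in records],
            "input_counts_source": [r.input_counts_source for r in records],
            "ip_library_size": [r.ip_library_size for r in records],
            "input_library_size": [r.input_library_size for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_window_counts(
    source: str | Path,
    grids: dict[str, WindowGrid],
    mode: str = "tsv",
    gene_models: dict[str, GeneModel] | None = None,
    read_length: int = 50,
) -> dict[str, np.ndarray]:
    """Read per-window integer read counts for every gene of the grid.

    ``tsv`` mode expects columns (gene_id, window_index, count); missing
    windows densify to 0. ``bedgraph`` mode sums per-base genomic coverage
    over each window's spliced projection and divides by ``read_length`` —
    an explicit approximation of fragment counts from coverage.
    """
    if mode == "tsv":
        df = pd.read_csv(source, sep="\t", dtype={"gene_id": str, "window_index": int, "count": int})
        out = {gid: np.zeros(g.n_windows, dtype=int) for gid, g in grids.items()}
        for gid, sub in df.groupby("gene_id"):
            if gid not in out:
                logger.warning("counts for unknown gene %s ignored", gid)
                continue
            idx = sub["window_index"].to_numpy()
            if (idx < 0).any() or (idx >= grids[gid].n_windows).any():
                raise ValueError(f"{source}: window_index outside grid for gene {gid}")
            out[gid][idx] = sub["count"].to_numpy()
        return out
    if mode == "bedgraph":
        if gene_models is None:
            raise ValueError("bedgraph mode requires gene_models for genomic projection")
        cov = pd.read_csv(source, sep="\t", header=None, names=["chrom", "start", "end", "value"])
        by_chrom = {c: sub.sort_values("start") for c, sub in cov.groupby("chrom")}
        known = {gm.chrom for gm in gene_models.values()}
        for c in by_chrom:
            if c not in known:
                warnings.warn(f"{source}: bedGraph interval(s) on unknown chrom {c} ignored")
        out = {}
        for gid, grid in grids.items():
            gm = gene_models[gid]
            sub = by_chrom.get(gm.chrom)
            counts = np.zeros(grid.n_windows, dtype=int)
            if sub is not None:
                starts = sub["start"].to_numpy()
                ends = sub["end"].to_numpy()
                vals = sub["value"].to_numpy(dtype=float)
                for i, (ws, we) in enumerate(grid.windows):
                    total = 0.0
                    for bs, be in gm.tx_interval_to_blocks(ws, we):
                        lo = np.searchsorted(ends, bs, side="right")
                        hi = np.searchsorted(starts, be, side="left")
                        for j in range(lo, hi):
                            total += vals[j] * max(0, min(ends[j], be) - max(starts[j], bs))
                    counts[i] = int(round(total / read_length))
            out[gid] = counts
        return out
    raise ValueError(f"unknown counts mode {mode!r} (expected 'tsv' or 'bedgraph')")


def write_window_counts(counts: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-window counts as sparse (gene_id, window_index, count) TSV."""
    rows = []
    for gid in sorted(counts):
        vec = counts[gid]
        for i in np.nonzero(vec)[0]:
            rows.append((gid, int(i), int(vec[i])))
    pd.DataFrame(rows, columns=["gene_id", "window_index", "count"]).to_csv(path, sep="\t", index=False)


def write_peaks_bed(
    peaks: list[Peak],
    gene_models: dict[str, GeneModel],
    path: str | Path,
    grids: dict[str, WindowGrid] | None = None,
    mean_winscore: dict[str, float] | None = None,
) -> None:
    """Emit peaks as BED6 genomic spans, one row per exon block.

    Spliced peaks produce several rows sharing the peak name. Score is the
    peak's mean winscore scaled by 100 and capped at 1000.
    """
    lines = []
    for pk in peaks:
        gm = gene_models.get(pk.gene_id)
        if gm is None:
            raise ValueError(f"peak {pk.peak_id} references unknown gene {pk.gene_id}")
        tx_len = gm.tx_length
        t_start = 50 * pk.window_start
        t_end = min(50 * pk.window_end + 100, tx_len)
        if grids is not None:
            g = grids[pk.gene_id]
            t_start, t_end = g.windows[pk.window_start][0], g.windows[pk.window_end][1]
        score = 0
        if mean_winscore is not None and pk.peak_id in mean_winscore:
            score = min(1000, int(round(100 * mean_winscore[pk.peak_id])))
        for bs, be in gm.tx_interval_to_blocks(t_start, t_end):
            lines.append((gm.chrom, bs, be, pk.peak_id, score, gm.strand))
    lines.sort()
    with open(path, "w") as fh:
        for chrom, bs, be, name, score, strand in lines:
            fh.write(f"{chrom}\t{bs}\t{be}\t{name}\t{score}\t{strand}\n")


def write_ratio_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="peak_id")


def read_ratio_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="peak_id", na_values="NA")
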