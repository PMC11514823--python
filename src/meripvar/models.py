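"""Core domain types shared across the pipeline.

All internal coordinates are 0-based, half-open. Genomic coordinates follow
the reference strand; transcript coordinates run 5'->3' in transcript
orientation (so for minus-strand genes transcript position 0 maps to the
highest genomic exon base).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneModel:
    """One representative transcript per gene.

    ``exons`` are genomic ``(start, end)`` intervals ordered 5'->3' in
    transcript orientation: ascending genomic start for plus-strand genes,
    descending for minus-strand. ``cds_start`` / ``cds_end`` are the genomic
    positions of the first base of the start and stop codon respectively
    (in transcript orientation); both are ``None`` for non-coding genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons {(s1, e1)} and {(s2, e2)}")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon {(s, e)}")

    @property
    def tx_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    # -- coordinate projection ------------------------------------------------

    def genome_to_tx(self, gpos: int) -> int:
        """Map a genomic base (must lie in an exon) to its transcript offset."""
        off = 0
        for s, e in self.exons:
            if s <= gpos < e:
                return off + (gpos - s if self.strand == "+" else e - 1 - gpos)
            off += e - s
        raise ValueError(f"{self.gene_id}: genomic position {gpos} not exonic")

    def tx_to_genome(self, tpos: int) -> int:
        """Map a transcript offset to the genomic base it sits on."""
        if not 0 <= tpos < self.tx_length:
            raise ValueError(f"{self.gene_id}: transcript position {tpos} outside [0, {self.tx_length})")
        off = 0
        for s, e in self.exons:
            n = e - s
            if tpos < off + n:
                d = tpos - off
                return s + d if self.strand == "+" else e - 1 - d
            off += n
        raise AssertionError("unreachable")

    def tx_interval_to_blocks(self, t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Project a transcript interval to genomic blocks (one per exon hit).

        Returns 0-based half-open genomic intervals sorted by genomic start.
        """
        if not (0 <= t_start < t_end <= self.tx_length):
            raise ValueError(
                f"{self.gene_id}: transcript interval [{t_start}, {t_end}) outside [0, {self.tx_length})"
            )
        blocks: list[tuple[int, int]] = []
        off = 0
        for s, e in self.exons:
            n = e - s
            lo = max(t_start, off)
            hi = min(t_end, off + n)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((s + (lo - off), s + (hi - off)))
                else:
                    blocks.append((e - (hi - off), e - (lo - off)))
            off += n
        return sorted(blocks)

    # -- CDS frame ------------------------------------------------------------

    @property
    def cds_start_tx(self) -> int | None:
        """Transcript offset of the first base of the start codon."""
        return self.genome_to_tx(self.cds_start) if self.is_coding else None

    @property
    def cds_end_tx(self) -> int | None:
        """Transcript offset of the first base of the stop codon."""
        return self.genome_to_tx(self.cds_end) if self.is_coding else None

    @property
    def utr5_len(self) -> int:
        return self.cds_start_tx if self.is_coding else 0

    @property
    def cds_len(self) -> int:
        # CDS runs from the start codon through the stop codon (inclusive).
        return (self.cds_end_tx - self.cds_start_tx + 3) if self.is_coding else 0

    @property
    def utr3_len(self) -> int:
        return self.tx_length - self.utr5_len - self.cds_len if self.is_coding else 0

    def validate_cds(self) -> None:
        if not self.is_coding:
            return
        s, e = self.cds_start_tx, self.cds_end_tx  # raises if not exonic
        if not (0 <= s <= e and e + 3 <= self.tx_length):
            raise ValueError(f"{self.gene_id}: CDS frame [{s}, {e}+3) outside transcript")


@dataclass
class SampleRecord:
    """One MeRIP-seq sample: a matched IP and input library pair."""

    sample_id: str
    tissue: str
    condition: str
    batch: str
    ip_counts_source: str = ""
    input_counts_source: str = ""
    ip_library_size: int = 0
    input_library_size: int = 0

    VALID_CONDITIONS = ("cancer", "normal")

    def __post_init__(self) -> None:
        if self.condition not in self.VALID_CONDITIONS:
            raise ValueError(
                f"sample {self.sample_id}: condition {self.condition!r} not in {list(self.VALID_CONDITIONS)}"
            )

    @property
    def group_id(self) -> str:
        return f"{self.tissue}.{self.condition}"


@dataclass
class WindowGrid:
    """Ordered 100-nt / 50-nt-step sliding windows over one transcript.

    Window i covers transcript coordinates [50*i, min(50*i + 100, tx_length));
    a terminal partial window is kept when it is at least 50 nt.
    """

    gene_id: str
    tx_length: int
    windows: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_length(self, i: int) -> int:
        s, e = self.windows[i]
        return e - s


@dataclass
class Peak:
    """An amalgamated m6A peak: a run of 1-5 consecutive grid windows."""

    peak_id: str
    gene_id: str
    window_start: int
    window_end: int  # inclusive window index

    def __post_init__(self) -> None:
        n = self.window_end - self.window_start + 1
        if not 1 <= n <= 5:
            raise ValueError(f"peak {self.peak_id}: spans {n} windows (must be 1-5)")

    @property
    def n_windows(self) -> int:
        return self.window_end - self.window_start + 1

    @property
    def window_indices(self) -> range:
        return range(self.window_start, self.window_end + 1)
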