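"""Synthetic MeRIP-seq generator with planted ground truth.

The generator emulates the structure of a multi-tissue m6A-seq experiment:

* a random genome and a one-transcript-per-gene annotation (5'UTR / CDS /
  3'UTR partition, 1-4 exons, both strands);
* planted methylated windows of two classes — *constitutive* sites near stop
  codons with high, stable stoichiometry, and *variable* sites over the
  CDS / start-codon region whose logit-stoichiometry is driven by regulator
  expression, tissue identity and condition (cancer vs normal);
* negative-binomial IP and input read counts per 100-nt window, where the
  IP mean is ``input_mean * (background + ip_efficiency * enrichment_fold *
  stoichiometry)``. The per-sample IP efficiency models antibody/batch
  differences: a more efficient IP shifts read *composition* toward
  methylated windows (sequencing depth itself is set by the sequencer), so
  the confounder survives library-size normalization and is only removable
  by distribution-level normalization;
* one m6A sub-motif (GGACA / AGACU / GGACU / GAACU) patched into the genome
  at each planted site so sequence-level analyses have signal.

Everything is deterministic under a fixed (config, seed) pair, including
output file bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    write_fasta,
    write_gene_models_gtf,
    write_sample_sheet,
    write_window_counts,
)
from .models import GeneModel, SampleRecord, WindowGrid
from .winscore import build_window_grid

SUBMOTIFS = ("GGACA", "AGACU", "GGACU", "GAACU")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults define the study conditions."""

    # genome / annotation
    n_genes: int = 200
    utr5_range: tuple[int, int] = (60, 300)
    cds_codon_range: tuple[int, int] = (100, 500)  # CDS length = 3 * codons
    utr3_range: tuple[int, int] = (150, 600)
    exon_count_range: tuple[int, int] = (1, 4)
    intron_range: tuple[int, int] = (60, 300)
    contig_pad: int = 100
    gc_content: float = 0.5

    # experiment design
    tissues: tuple[str, ...] = ("liver", "lung")
    conditions: tuple[str, ...] = ("cancer", "normal")
    replicates: int = 3  # per tissue x condition
    batches: tuple[str, ...] = ("A", "B")
    batch_ip_efficiency: dict = field(default_factory=lambda: {"A": 1.0, "B": 2.0})

    # methylation truth
    n_constitutive: int = 180
    n_variable: int = 60
    constitutive_beta: tuple[float, float] = (160.0, 40.0)  # mean 0.8, tight
    variable_baseline_logit: float = -0.9  # sigmoid -> ~0.29
    driver_effect: float = 2.2
    noise_logit_sd: float = 0.5
    tissue_effect_sd: float = 0.7
    condition_logit_shift: float = 0.6
    condition_noise_mult: float = 1.5
    n_regulators: int = 6
    n_drivers: int = 2
    submotif_props: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    # sequencing
    depth: float = 300.0  # expected input reads per 100-nt window at reference TPM
    enrichment_fold: float = 8.0
    background: float = 1.0
    nb_size: float = 500.0  # NB dispersion: var = m + m^2 / nb_size
    expression_log_sd: float = 0.2  # per-sample log-normal wobble around gene base TPM
    base_tpm: float = 30.0
    regulator_base_tpm: float = 25.0
    regulator_log_sd: float = 0.6
    library_background: int = 20_000_000  # mapped reads outside the simulated genes

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if abs(sum(self.submotif_props) - 1.0) > 1e-9:
            raise ValueError("submotif_props must sum to 1")
        if self.n_drivers > self.n_regulators:
            raise ValueError("n_drivers cannot exceed n_regulators")
        for b in self.batches:
            if self.batch_ip_efficiency.get(b, 0) <= 0:
                raise ValueError(f"batch {b}: ip_efficiency must be > 0")


@dataclass
class TruthSet:
    """Ground truth of one simulated dataset."""

    sites: pd.DataFrame  # site_id, gene_id, window_index, class, submotif
    stoichiometry: pd.DataFrame  # site_id x sample_id, values in [0, 1]
    ip_efficiency: pd.Series  # sample_id -> multiplier
    regulator_effects: pd.DataFrame  # regulator x site_id coefficients
    expression: pd.DataFrame  # gene (and regulator) x sample TPM

    def site_windows(self) -> set[tuple[str, int]]:
        return set(zip(self.sites["gene_id"], self.sites["window_index"]))


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    sequences: dict[str, str]
    gene_models: list[GeneModel]
    grids: dict[str, WindowGrid]
    samples: list[SampleRecord]
    truth: TruthSet
    ip_counts: dict[str, dict[str, np.ndarray]]  # sample -> gene -> counts
    input_counts: dict[str, dict[str, np.ndarray]]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def generate_genome_and_annotation(
    config: SimulationConfig, seed: int | np.random.Generator
) -> tuple[dict[str, str], list[GeneModel]]:
    """One contig per gene; random exon/intron structure on either strand."""
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    models: list[GeneModel] = []
    for gi in range(config.n_genes):
        gid = f"g{gi:04d}"
        utr5 = int(rng.integers(*config.utr5_range, endpoint=True))
        cds = 3 * int(rng.integers(*config.cds_codon_range, endpoint=True))
        utr3 = int(rng.integers(*config.utr3_range, endpoint=True))
        tx_len = utr5 + cds + utr3
        n_exons = int(rng.integers(*config.exon_count_range, endpoint=True))
        n_exons = min(n_exons, max(1, tx_len // 120))
        # cut the transcript into n_exons pieces, each >= 100 nt
        cuts = np.sort(rng.choice(np.arange(100, tx_len - 99, 10), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
        while len(cuts) > 1 and np.diff(np.concatenate([[0], cuts, [tx_len]])).min() < 100:
            cuts = np.sort(rng.choice(np.arange(100, tx_len - 99, 10), size=n_exons - 1, replace=False))
        bounds = np.concatenate([[0], cuts, [tx_len]])
        exon_lens = np.diff(bounds)
        introns = rng.integers(*config.intron_range, endpoint=True, size=len(exon_lens) - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        contig_len = config.contig_pad * 2 + int(exon_lens.sum() + introns.sum())
        chrom = f"ctg_{gid}"
        sequences[chrom] = _random_seq(rng, contig_len, config.gc_content)
        # lay exons along the genome; for minus-strand genes the transcript
        # 5'->3' order corresponds to descending genomic coordinates
        order = range(len(exon_lens)) if strand == "+" else range(len(exon_lens) - 1, -1, -1)
        pos = config.contig_pad
        genomic: dict[int, tuple[int, int]] = {}
        for k, ei in enumerate(order):
            genomic[ei] = (pos, pos + int(exon_lens[ei]))
            pos += int(exon_lens[ei])
            if k < len(exon_lens) - 1:
                pos += int(introns[k])
        exons = [genomic[ei] for ei in range(len(exon_lens))]
        gm = GeneModel(gene_id=gid, chrom=chrom, strand=strand, exons=exons)
        gm.cds_start = gm.tx_to_genome(utr5)
        gm.cds_end = gm.tx_to_genome(utr5 + cds - 3)
        gm.validate_cds()
        models.append(gm)
    return sequences, models


def _transcript_seq(gm: GeneModel, sequences: dict[str, str]) -> str:
    contig = sequences[gm.chrom]
    parts = []
    for s, e in gm.exons:
        block = contig[s:e]
        parts.append(block if gm.strand == "+" else block.translate(_COMPLEMENT)[::-1])
    return "".join(parts)


def _patch_transcript(gm: GeneModel, sequences: dict[str, str], t_start: int, motif_dna: str) -> None:
    """Write ``motif_dna`` (sense strand) into the genome at transcript offset t_start."""
    contig = list(sequences[gm.chrom])
    for k, base in enumerate(motif_dna):
        gpos = gm.tx_to_genome(t_start + k)
        contig[gpos] = base if gm.strand == "+" else base.translate(_COMPLEMENT)
    sequences[gm.chrom] = "".join(contig)


def make_sample_sheet(config: SimulationConfig) -> list[SampleRecord]:
    """tissue x condition x replicate design, batches interleaved across it."""
    records = []
    i = 0
    for tissue in config.tissues:
        for condition in config.conditions:
            for rep in range(config.replicates):
                batch = config.batches[i % len(config.batches)]
                records.append(
                    SampleRecord(
                        sample_id=f"{tissue}_{condition}_{rep + 1}",
                        tissue=tissue,
                        condition=condition,
                        batch=batch,
                    )
                )
                i += 1
    return records


def simulate_methylation_truth(
    config: SimulationConfig,
    seed: int | np.random.Generator,
    gene_models: list[GeneModel],
    grids: dict[str, WindowGrid],
    sequences: dict[str, str],
    samples: list[SampleRecord],
) -> TruthSet:
    """Plant methylated windows, draw stoichiometries, patch sub-motifs.

    Constitutive sites take the window nearest the stop codon and draw
    stoichiometry i.i.d. from a tight Beta (mean 0.8). Variable sites sit in
    the CDS / start-codon region, away from the stop codon, and follow
    ``logit(stoich) = baseline + tissue effect + condition shift +
    coeff * z(driver log2 TPM) + noise``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sites = config.n_constitutive + config.n_variable
    coding = [gm for gm in gene_models if gm.is_coding and gm.gene_id in grids]
    if config.n_constitutive > len(coding) or config.n_variable > len(coding):
        raise ValueError(
            f"requested {n_sites} sites but only {len(coding)} usable genes "
            "(at most one site per class per gene)"
        )
    sample_ids = [s.sample_id for s in samples]
    n_samples = len(sample_ids)

    # regulator expression (TPM) and standardized log2 scores
    reg_ids = [f"REG{r + 1}" for r in range(config.n_regulators)]
    log_tpm = np.log(config.regulator_base_tpm) + config.regulator_log_sd * rng.standard_normal(
        (config.n_regulators, n_samples)
    )
    reg_tpm = np.exp(log_tpm)
    z = np.log2(reg_tpm + 1)
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)

    # gene expression TPM: per-gene base, mild per-sample wobble
    gene_ids = [gm.gene_id for gm in gene_models]
    base = config.base_tpm * np.exp(0.3 * rng.standard_normal(len(gene_ids)))
    tpm = base[:, None] * np.exp(
        config.expression_log_sd * rng.standard_normal((len(gene_ids), n_samples))
    )
    expression = pd.DataFrame(
        np.vstack([tpm, reg_tpm]), index=gene_ids + reg_ids, columns=sample_ids
    )

    # constitutive sites sit near stop codons; variable sites in the CDS /
    # start-codon region. The two classes may share a gene (their windows are
    # several window-widths apart), so each class draws its own gene subset.
    perm = rng.permutation(len(coding))
    const_genes = perm[: config.n_constitutive]
    var_genes = rng.permutation(len(coding))[: config.n_variable]
    chosen = np.concatenate([const_genes, var_genes]).astype(int)
    used_windows: dict[str, set[int]] = {}
    site_rows = []
    stoich_rows = []
    motif_idx = rng.choice(len(SUBMOTIFS), size=n_sites, p=np.asarray(config.submotif_props))
    effects = np.zeros((config.n_regulators, n_sites))
    drivers = rng.integers(0, config.n_drivers, size=config.n_variable) if config.n_drivers else None

    is_cancer = np.array([s.condition == "cancer" for s in samples], dtype=float)
    tissue_index = {t: k for k, t in enumerate(config.tissues)}
    tissue_of = np.array([tissue_index[s.tissue] for s in samples])

    for si in range(n_sites):
        gm = coding[chosen[si]]
        grid = grids[gm.gene_id]
        mids = np.array([(s + e) / 2 for s, e in grid.windows])
        stop_tx = gm.cds_end_tx
        start_tx = gm.cds_start_tx
        if si < config.n_constitutive:
            klass = "constitutive"
            widx = int(np.argmin(np.abs(mids - stop_tx)))
            a, b = config.constitutive_beta
            stoich = rng.beta(a, b, size=n_samples)
        else:
            klass = "variable"
            candidates = np.nonzero((mids >= start_tx - 100) & (mids <= stop_tx - 200))[0]
            if candidates.size == 0:
                candidates = np.nonzero(mids <= stop_tx - 200)[0]
            if candidates.size == 0:
                candidates = np.array([0])
            taken = used_windows.get(gm.gene_id, set())
            free = [c for c in candidates if all(abs(c - t) > 1 for t in taken)]
            widx = int(rng.choice(free if free else candidates))
            vi = si - config.n_constitutive
            logit = np.full(n_samples, config.variable_baseline_logit)
            logit += rng.normal(0.0, config.tissue_effect_sd, size=len(config.tissues))[tissue_of]
            logit += config.condition_logit_shift * is_cancer
            if drivers is not None:
                d = drivers[vi]
                effects[d, si] = config.driver_effect
                logit += config.driver_effect * z[d]
            noise_sd = config.noise_logit_sd * (
                1.0 + (config.condition_noise_mult - 1.0) * is_cancer
            )
            logit += rng.normal(0.0, 1.0, size=n_samples) * noise_sd
            stoich = 1.0 / (1.0 + np.exp(-logit))
        used_windows.setdefault(gm.gene_id, set()).add(widx)
        motif = SUBMOTIFS[motif_idx[si]]
        ws, we = grid.windows[widx]
        patch_at = ws + (we - ws - 5) // 2
        _patch_transcript(gm, sequences, patch_at, motif.replace("U", "T"))
        site_rows.append((f"{gm.gene_id}:{widx}", gm.gene_id, widx, klass, motif))
        stoich_rows.append(stoich)

    sites = pd.DataFrame(site_rows, columns=["site_id", "gene_id", "window_index", "class", "submotif"])
    stoich_df = pd.DataFrame(np.vstack(stoich_rows), index=sites["site_id"], columns=sample_ids)
    eff = pd.Series(
        {s.sample_id: float(config.batch_ip_efficiency[s.batch]) for s in samples}, name="ip_efficiency"
    )
    regulator_effects = pd.DataFrame(effects, index=reg_ids, columns=sites["site_id"])
    return TruthSet(
        sites=sites,
        stoichiometry=stoich_df,
        ip_efficiency=eff,
        regulator_effects=regulator_effects,
        expression=expression,
    )


def expected_counts(
    truth: TruthSet,
    sample: SampleRecord,
    config: SimulationConfig,
    grids: dict[str, WindowGrid],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Expected (mean) IP and input counts per window for one sample.

    ``E[input] = depth * (TPM / base_tpm) * window_len / 100`` and
    ``E[IP] = E[input] * (background + efficiency * fold * stoichiometry)``.
    Exposed separately so expectation-level properties are testable without
    Monte-Carlo noise.
    """
    eff = float(truth.ip_efficiency[sample.sample_id])
    stoich_lookup = {
        (g, w): float(truth.stoichiometry.at[sid, sample.sample_id])
        for sid, g, w in zip(truth.sites["site_id"], truth.sites["gene_id"], truth.sites["window_index"])
    }
    exp_ip: dict[str, np.ndarray] = {}
    exp_in: dict[str, np.ndarray] = {}
    for gid, grid in grids.items():
        rel = float(truth.expression.at[gid, sample.sample_id]) / config.base_tpm
        wlen = np.array([e - s for s, e in grid.windows], dtype=float)
        m_in = config.depth * rel * wlen / 100.0
        enrich = np.full(grid.n_windows, config.background)
        for w in range(grid.n_windows):
            st = stoich_lookup.get((gid, w))
            if st is not None:
                enrich[w] += eff * config.enrichment_fold * st
        exp_in[gid] = m_in
        exp_ip[gid] = m_in * enrich
    return exp_ip, exp_in


def simulate_sample_counts(
    truth: TruthSet,
    sample: SampleRecord,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    grids: dict[str, WindowGrid],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], int, int]:
    """Draw NB counts for one sample; returns (ip, input, lib_ip, lib_input)."""
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exp_ip, exp_in = expected_counts(truth, sample, config, grids)

    def draw(means: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for gid in sorted(means):
            m = np.maximum(means[gid], 1e-9)
            p = config.nb_size / (config.nb_size + m)
            out[gid] = rng.negative_binomial(config.nb_size, p)
        return out

    ip = draw(exp_ip)
    inp = draw(exp_in)
    lib_ip = int(sum(v.sum() for v in ip.values())) + config.library_background
    lib_in = int(sum(v.sum() for v in inp.values())) + config.library_background
    return ip, inp, lib_ip, lib_in


def simulate_dataset(config: SimulationConfig, seed: int) -> SyntheticDataset:
    """Full in-memory dataset: genome, annotation, samples, truth, counts."""
    rng = np.random.default_rng(seed)
    sequences, gene_models = generate_genome_and_annotation(config, rng)
    grids = {}
    for gm in gene_models:
        grids[gm.gene_id] = build_window_grid(gm)
    samples = make_sample_sheet(config)
    truth = simulate_methylation_truth(config, rng, gene_models, grids, sequences, samples)
    ip_counts: dict[str, dict[str, np.ndarray]] = {}
    input_counts: dict[str, dict[str, np.ndarray]] = {}
    for rec in samples:
        ip, inp, lib_ip, lib_in = simulate_sample_counts(truth, rec, config, rng, grids)
        rec.ip_library_size = lib_ip
        rec.input_library_size = lib_in
        ip_counts[rec.sample_id] = ip
        input_counts[rec.sample_id] = inp
    return SyntheticDataset(
        config=config,
        sequences=sequences,
        gene_models=gene_models,
        grids=grids,
        samples=samples,
        truth=truth,
        ip_counts=ip_counts,
        input_counts=input_counts,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, str]:
    """Serialize a dataset; returns a name -> path manifest."""
    out = Path(out_dir)
    (out / "counts").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    write_fasta(ds.sequences, out / "genome.fa")
    write_gene_models_gtf(ds.gene_models, out / "genes.gtf")
    for rec in ds.samples:
        rec.ip_counts_source = str(out / "counts" / f"{rec.sample_id}.ip.tsv")
        rec.input_counts_source = str(out / "counts" / f"{rec.sample_id}.input.tsv")
        write_window_counts(ds.ip_counts[rec.sample_id], rec.ip_counts_source)
        write_window_counts(ds.input_counts[rec.sample_id], rec.input_counts_source)
    write_sample_sheet(ds.samples, out / "sample_sheet.tsv")
    ds.truth.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
    ds.truth.sites.to_csv(out / "truth" / "sites.tsv", sep="\t", index=False)
    ds.truth.stoichiometry.to_csv(out / "truth" / "stoichiometry.tsv", sep="\t", index_label="site_id")
    ds.truth.ip_efficiency.to_frame().to_csv(out / "truth" / "ip_efficiency.tsv", sep="\t", index_label="sample_id")
    ds.truth.regulator_effects.to_csv(out / "truth" / "regulator_effects.tsv", sep="\t", index_label="regulator")
    return {
        "genome": str(out / "genome.fa"),
        "annotation": str(out / "genes.gtf"),
        "sample_sheet": str(out / "sample_sheet.tsv"),
        "expression": str(out / "expression.tsv"),
        "truth_dir": str(out / "truth"),
        "counts_dir": str(out / "counts"),
    }
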