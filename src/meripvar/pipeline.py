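"""End-to-end pipeline orchestration.

``run_pipeline`` executes the analysis stages in order — callpeaks,
quantify, normalize, annotate, metagene, cv, diffmeth, submotif, corrnet —
over a configured input set, writing each stage's tables under ``out_dir``
and a machine-readable manifest at the end. Every stage draws randomness
from its own stream derived from the master seed and the stage name, so a
stage rerun in isolation reproduces its in-pipeline result.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import heterogeneity, io_formats, metagene, network, submotif, winscore
from .models import GeneModel, SampleRecord
from .simulate import SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

STAGES = (
    "callpeaks",
    "quantify",
    "normalize",
    "annotate",
    "metagene",
    "cv",
    "diffmeth",
    "submotif",
    "corrnet",
)


class PipelineError(RuntimeError):
    pass


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent per-stage seed derived from the master seed and stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All paths and scalar parameters of one pipeline run.

    Parameter defaults are the pipeline's canonical values: 100-nt windows
    stepped by 50 nt, winscore threshold 2 with a +1 RPKM pseudocount,
    input-RPKM NA floor 5, peaks of at most 5 windows, CV threshold 0.3,
    10,000 shuffle iterations, 100-nt codon flanks.
    """

    annotation: str = ""
    genome: str = ""
    sample_sheet: str = ""
    counts_dir: str = ""
    expression: str = ""
    out_dir: str = "meripvar_out"
    seed: int = 0

    window: int = 100
    step: int = 50
    winscore_thr: float = 2.0
    pseudocount: float = 1.0
    input_floor: float = 5.0
    max_windows: int = 5
    cv_thr: float = 0.3
    min_group_n: int = 3
    n_iter: int = 10_000
    flank: int = 100
    r_min: float = 0.6
    fdr_max: float = 0.05
    min_pairs: int = 5
    read_length: int = 50
    cv_grouping: str = "condition"  # or "tissue_condition"
    regulator_prefix: str = "REG"  # expression rows treated as regulators
    classical_regulators: list = field(default_factory=list)
    cell_specific_regulators: list = field(default_factory=list)

    simulate: dict = field(default_factory=dict)

    def validate(self) -> None:
        checks = {
            "window": self.window > 0,
            "step": 0 < self.step <= self.window,
            "winscore_thr": self.winscore_thr > 0,
            "pseudocount": self.pseudocount >= 0,
            "input_floor": self.input_floor >= 0,
            "max_windows": self.max_windows >= 1,
            "cv_thr": self.cv_thr >= 0,
            "n_iter": self.n_iter >= 100,
            "flank": self.flank >= 0,
            "r_min": 0 <= self.r_min <= 1,
            "fdr_max": 0 < self.fdr_max <= 1,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid configuration parameter(s): {', '.join(bad)}")
        if self.cv_grouping not in ("condition", "tissue_condition"):
            raise ValueError("cv_grouping must be 'condition' or 'tissue_condition'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path))
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


@dataclass
class PipelineState:
    config: RunConfig
    gene_models: dict[str, GeneModel]
    grids: dict
    samples: list[SampleRecord]
    sequences: dict[str, str] | None = None
    expression: pd.DataFrame | None = None
    quants: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    peaks: list = field(default_factory=list)
    matrix: pd.DataFrame | None = None
    normalized: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None
    cv_table: pd.DataFrame | None = None
    specific: dict = field(default_factory=dict)
    ip_counts: dict | None = None  # in-memory counts bypassing count files
    input_counts: dict | None = None


def load_state(cfg: RunConfig) -> PipelineState:
    models = io_formats.read_gene_models(cfg.annotation)
    gene_models, grids = {}, {}
    for gm in models:
        try:
            grids[gm.gene_id] = winscore.build_window_grid(gm, cfg.window, cfg.step)
            gene_models[gm.gene_id] = gm
        except ValueError as exc:
            logger.warning("%s", exc)
    samples = io_formats.read_sample_sheet(cfg.sample_sheet)
    state = PipelineState(config=cfg, gene_models=gene_models, grids=grids, samples=samples)
    if cfg.genome:
        state.sequences = _read_fasta(cfg.genome)
    if cfg.expression:
        state.expression = pd.read_csv(cfg.expression, sep="\t", index_col="gene_id")
    return state


def _counts_for(state: PipelineState, rec: SampleRecord, which: str) -> dict[str, np.ndarray]:
    mem = state.ip_counts if which == "ip" else state.input_counts
    if mem is not None:
        return mem[rec.sample_id]
    src = rec.ip_counts_source if which == "ip" else rec.input_counts_source
    if not src:
        src = str(Path(state.config.counts_dir) / f"{rec.sample_id}.{which}.tsv")
    return io_formats.read_window_counts(src, state.grids, mode="tsv")


def state_from_dataset(ds, cfg: RunConfig | None = None) -> PipelineState:
    """Build a pipeline state directly from an in-memory synthetic dataset."""
    cfg = cfg or RunConfig()
    return PipelineState(
        config=cfg,
        gene_models={gm.gene_id: gm for gm in ds.gene_models},
        grids=ds.grids,
        samples=ds.samples,
        sequences=ds.sequences,
        expression=ds.truth.expression,
        ip_counts=ds.ip_counts,
        input_counts=ds.input_counts,
    )


def call_and_quantify(ds, cfg: RunConfig | None = None) -> PipelineState:
    """Convenience: callpeaks + quantify + normalize on an in-memory dataset.

    Writes nothing; the returned state carries peaks, the raw and
    normalized ratio matrices and per-sample window quantifications.
    """
    state = state_from_dataset(ds, cfg)
    cfg = state.config
    for rec in state.samples:
        quants, flags = {}, {}
        ip, inp = state.ip_counts[rec.sample_id], state.input_counts[rec.sample_id]
        for gid, grid in state.grids.items():
            q = winscore.compute_winscore(
                ip[gid], inp[gid], grid, rec.ip_library_size, rec.input_library_size,
                threshold=cfg.winscore_thr, pseudocount=cfg.pseudocount,
            )
            quants[gid] = q
            flags[gid] = q.is_peak
        state.quants[rec.sample_id] = quants
        state.flags[rec.sample_id] = flags
    state.peaks = winscore.amalgamate_peaks(state.flags, state.grids, cfg.max_windows)
    state.matrix, _ = winscore.peak_ratio_matrix(state.peaks, state.quants, cfg.input_floor)
    state.normalized = winscore.quantile_normalize(state.matrix)
    return state


# ---------------------------------------------------------------------------
# stage implementations; each returns a list of output files


def _stage_callpeaks(state: PipelineState, out: Path) -> list[str]:
    cfg = state.config
    for rec in state.samples:
        ip = _counts_for(state, rec, "ip")
        inp = _counts_for(state, rec, "input")
        quants, flags = {}, {}
        for gid, grid in state.grids.items():
            q = winscore.compute_winscore(
                ip[gid], inp[gid], grid, rec.ip_library_size, rec.input_library_size,
                threshold=cfg.winscore_thr, pseudocount=cfg.pseudocount,
            )
            quants[gid] = q
            flags[gid] = q.is_peak
        state.quants[rec.sample_id] = quants
        state.flags[rec.sample_id] = flags
    state.peaks = winscore.amalgamate_peaks(state.flags, state.grids, cfg.max_windows)
    mean_ws = {}
    for pk in state.peaks:
        vals = [
            float(np.mean(state.quants[s][pk.gene_id].winscore[pk.window_start : pk.window_end + 1]))
            for s in state.quants
        ]
        mean_ws[pk.peak_id] = float(np.mean(vals))
    bed = out / "peaks.bed"
    io_formats.write_peaks_bed(state.peaks, state.gene_models, bed, state.grids, mean_ws)
    return [str(bed)]


def _stage_quantify(state: PipelineState, out: Path) -> list[str]:
    mat, dropped = winscore.peak_ratio_matrix(state.peaks, state.quants, state.config.input_floor)
    state.matrix = mat
    io_formats.write_ratio_matrix(mat, out / "ratio_matrix.tsv")
    dropped.to_csv(out / "dropped_peaks.tsv", sep="\t", index=False)
    return [str(out / "ratio_matrix.tsv"), str(out / "dropped_peaks.tsv")]


def _stage_normalize(state: PipelineState, out: Path) -> list[str]:
    state.normalized = winscore.quantile_normalize(state.matrix)
    io_formats.write_ratio_matrix(state.normalized, out / "ratio_matrix.normalized.tsv")
    return [str(out / "ratio_matrix.normalized.tsv")]


def _stage_annotate(state: PipelineState, out: Path) -> list[str]:
    state.annotations = metagene.annotate_peaks(
        state.peaks, state.gene_models, state.grids, state.config.flank
    )
    state.annotations.to_csv(out / "peak_annotations.tsv", sep="\t", index=False)
    return [str(out / "peak_annotations.tsv")]


def _stage_metagene(state: PipelineState, out: Path) -> list[str]:
    profile = metagene.metagene_profile(state.annotations)
    profile.to_csv(out / "metagene_profile.tsv", sep="\t", index=False)
    return [str(out / "metagene_profile.tsv")]


def _group_map(state: PipelineState) -> dict[str, str]:
    if state.config.cv_grouping == "condition":
        return {s.sample_id: s.condition for s in state.samples}
    return {s.sample_id: s.group_id for s in state.samples}


def _stage_cv(state: PipelineState, out: Path) -> list[str]:
    groups = _group_map(state)
    state.cv_table = heterogeneity.site_cv(state.normalized, groups, state.config.min_group_n)
    cancer_groups = {g for g in state.cv_table["group_id"].unique() if "cancer" in g}
    cancer_cv = state.cv_table[state.cv_table["group_id"].isin(cancer_groups)]
    state.specific = heterogeneity.select_specific_sites(cancer_cv, state.config.cv_thr)
    state.cv_table.to_csv(out / "cv_table.tsv", sep="\t", index=False)
    rows = [(g, s) for g, sites in state.specific.items() for s in sorted(sites)]
    pd.DataFrame(rows, columns=["group_id", "peak_id"]).to_csv(
        out / "specific_sites.tsv", sep="\t", index=False
    )
    return [str(out / "cv_table.tsv"), str(out / "specific_sites.tsv")]


def _stage_diffmeth(state: PipelineState, out: Path) -> list[str]:
    cond = {s.sample_id: s.condition for s in state.samples}
    dm = heterogeneity.differential_methylation(
        state.normalized, cond, state.config.min_group_n, state.config.fdr_max
    )
    dm.to_csv(out / "differential_methylation.tsv", sep="\t", index=False)
    corr, order, _ = heterogeneity.sample_correlation(state.normalized)
    corr.to_csv(out / "sample_correlation.tsv", sep="\t", index_label="sample_id")
    pd.Series(order, name="sample_id").to_csv(out / "sample_order.tsv", sep="\t", index=False)
    return [
        str(out / "differential_methylation.tsv"),
        str(out / "sample_correlation.tsv"),
        str(out / "sample_order.tsv"),
    ]


def _stage_submotif(state: PipelineState, out: Path) -> list[str]:
    if state.sequences is None:
        raise PipelineError("submotif stage requires a genome FASTA in the configuration")
    seqs = submotif.peak_sequences(state.peaks, state.grids, state.gene_models, state.sequences)
    res = submotif.submotif_shuffle_test(
        seqs, n_iter=state.config.n_iter, seed=stage_seed(state.config.seed, "submotif")
    )
    res.to_csv(out / "submotif_results.tsv", sep="\t", index=False)
    return [str(out / "submotif_results.tsv")]


def _stage_corrnet(state: PipelineState, out: Path) -> list[str]:
    cfg = state.config
    if state.expression is None:
        raise PipelineError("corrnet stage requires an expression table in the configuration")
    classes = {}
    for reg in cfg.classical_regulators:
        classes[reg] = "classical"
    for reg in cfg.cell_specific_regulators:
        classes[reg] = "cell_specific"
    if not classes:
        classes = {
            r: "classical" for r in state.expression.index if str(r).startswith(cfg.regulator_prefix)
        }
    cancer_samples = [s.sample_id for s in state.samples if s.condition == "cancer"]
    group_samples = {g: cancer_samples for g in state.specific}
    edges = network.regulator_site_correlation(
        state.expression, state.normalized, state.specific, classes, group_samples, cfg.min_pairs
    )
    full, nodes = network.build_network(edges, cfg.r_min, cfg.fdr_max)
    edges.to_csv(out / "correlation_edges.tsv", sep="\t", index=False)
    full.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    nodes.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
    return [
        str(out / "correlation_edges.tsv"),
        str(out / "network_edges.tsv"),
        str(out / "network_nodes.tsv"),
    ]


_STAGE_FUNCS = {
    "callpeaks": _stage_callpeaks,
    "quantify": _stage_quantify,
    "normalize": _stage_normalize,
    "annotate": _stage_annotate,
    "metagene": _stage_metagene,
    "cv": _stage_cv,
    "diffmeth": _stage_diffmeth,
    "submotif": _stage_submotif,
    "corrnet": _stage_corrnet,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in canonical order; returns the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = load_state(cfg)
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": []}
    ordered = [s for s in STAGES if s in stages]
    for name in ordered:
        t0 = time.monotonic()
        try:
            outputs = _STAGE_FUNCS[name](state, out)
        except Exception as exc:
            failed = out / "failed"
            failed.mkdir(exist_ok=True)
            manifest["failed_stage"] = name
            with open(failed / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        manifest["stages"].append(
            {"stage": name, "outputs": outputs, "elapsed_s": round(time.monotonic() - t0, 3)}
        )
        logger.info("stage %s done (%d output file(s))", name, len(outputs))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_simulation(cfg: RunConfig) -> dict[str, str]:
    """Generate a synthetic dataset under ``out_dir`` and point the run
    configuration's input paths at it."""
    sim_cfg = SimulationConfig(**cfg.simulate) if cfg.simulate else SimulationConfig()
    ds = simulate_dataset(sim_cfg, stage_seed(cfg.seed, "simulate"))
    paths = write_dataset(ds, cfg.out_dir)
    cfg.annotation = paths["annotation"]
    cfg.genome = paths["genome"]
    cfg.sample_sheet = paths["sample_sheet"]
    cfg.expression = paths["expression"]
    cfg.counts_dir = paths["counts_dir"]
    return paths
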