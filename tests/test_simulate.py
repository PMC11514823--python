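import warnings

import numpy as np
import pytest

from meripvar.io_formats import write_fasta, write_gene_models_gtf
from meripvar.simulate import (
    SUBMOTIFS,
    SimulationConfig,
    expected_counts,
    generate_genome_and_annotation,
    make_sample_sheet,
    simulate_dataset,
    simulate_methylation_truth,
    simulate_sample_counts,
)
from meripvar.submotif import peak_sequences
from meripvar.models import Peak
from meripvar.winscore import build_window_grid


def _small_cfg(**kw):
    base = dict(n_genes=30, n_constitutive=8, n_variable=6, depth=150.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenomeAnnotation:
    def test_deterministic_bytes(self, tmp_path):
        for sub in ("r1", "r2"):
            seqs, models = generate_genome_and_annotation(_small_cfg(), seed=5)
            d = tmp_path / sub
            d.mkdir()
            write_fasta(seqs, d / "g.fa")
            write_gene_models_gtf(models, d / "g.gtf")
        assert (tmp_path / "r1/g.fa").read_bytes() == (tmp_path / "r2/g.fa").read_bytes()
        assert (tmp_path / "r1/g.gtf").read_bytes() == (tmp_path / "r2/g.gtf").read_bytes()

    def test_gc_content_within_binomial_bounds(self):
        cfg = SimulationConfig(n_genes=100, gc_content=0.4)
        seqs, _ = generate_genome_and_annotation(cfg, seed=11)
        s = "".join(seqs.values())
        gc = (s.count("G") + s.count("C")) / len(s)
        assert 0.38 < gc < 0.42

    def test_gene_structure_valid(self):
        _, models = generate_genome_and_annotation(_small_cfg(), seed=2)
        for gm in models:
            gm.validate_cds()
            assert gm.cds_len % 3 == 0
            assert gm.utr5_len > 0 and gm.utr3_len > 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="gc_content"):
            generate_genome_and_annotation(SimulationConfig(gc_content=1.5), seed=0)


class TestMethylationTruth:
    def _truth(self, cfg, seed=0):
        rng = np.random.default_rng(seed)
        seqs, models = generate_genome_and_annotation(cfg, rng)
        grids = {g.gene_id: build_window_grid(g) for g in models}
        samples = make_sample_sheet(cfg)
        return simulate_methylation_truth(cfg, rng, models, grids, seqs, samples), seqs, models, grids

    def test_constitutive_beta_mean(self):
        cfg = SimulationConfig(n_genes=200, n_constitutive=200, n_variable=0)
        truth, *_ = self._truth(cfg)
        mean = truth.stoichiometry.to_numpy().mean()
        assert 0.78 < mean < 0.82  # Beta(160, 40) has mean 0.8

    def test_stoichiometry_cv_separates_classes(self):
        truth, *_ = self._truth(_small_cfg(n_genes=60, n_constitutive=20, n_variable=20))
        st = truth.stoichiometry
        cv = st.std(axis=1, ddof=1) / st.mean(axis=1)
        klass = truth.sites.set_index("site_id")["class"]
        assert (cv[klass == "constitutive"] < 0.15).all()
        assert (cv[klass == "variable"] > 0.3).all()

    def test_zero_regulators_zero_noise_collapse_to_baseline(self):
        cfg = _small_cfg(
            n_regulators=0, n_drivers=0, noise_logit_sd=0.0, tissue_effect_sd=0.0,
            condition_logit_shift=0.0, n_constitutive=0, n_variable=6,
        )
        truth, *_ = self._truth(cfg)
        st = truth.stoichiometry.to_numpy()
        expected = 1 / (1 + np.exp(-cfg.variable_baseline_logit))
        assert np.allclose(st, expected, atol=1e-12)

    def test_single_strong_driver_correlates_with_stoichiometry(self):
        cfg = SimulationConfig(
            n_genes=80, n_constitutive=0, n_variable=30, n_regulators=1, n_drivers=1,
            driver_effect=1.0, noise_logit_sd=0.05, tissue_effect_sd=0.0,
            condition_logit_shift=0.0, condition_noise_mult=1.0,
            tissues=("liver",), replicates=10,
        )
        truth, *_ = self._truth(cfg)
        z = np.log2(truth.expression.loc["REG1"].to_numpy(dtype=float) + 1)
        rs = [np.corrcoef(z, row)[0, 1] for _, row in truth.stoichiometry.iterrows()]
        assert np.median(rs) > 0.8

    def test_planted_window_contains_its_submotif(self):
        truth, seqs, models, grids = self._truth(_small_cfg())
        gm_by_id = {g.gene_id: g for g in models}
        peaks = [
            Peak(sid, g, w, w)
            for sid, g, w in zip(truth.sites["site_id"], truth.sites["gene_id"], truth.sites["window_index"])
        ]
        pseqs = {p.peak_id: s for p, s in zip(peaks, peak_sequences(peaks, grids, gm_by_id, seqs))}
        for _, row in truth.sites.iterrows():
            motif = row["submotif"].replace("U", "T")
            assert motif in pseqs[row["site_id"]].seq

    def test_too_many_sites_rejected(self):
        with pytest.raises(ValueError, match="sites"):
            self._truth(_small_cfg(n_constitutive=500))


class TestSampleCounts:
    def _setup(self, cfg, seed=0):
        rng = np.random.default_rng(seed)
        seqs, models = generate_genome_and_annotation(cfg, rng)
        grids = {g.gene_id: build_window_grid(g) for g in models}
        samples = make_sample_sheet(cfg)
        truth = simulate_methylation_truth(cfg, rng, models, grids, seqs, samples)
        return truth, samples, grids

    def test_expected_ratio_formulas(self):
        cfg = _small_cfg(batch_ip_efficiency={"A": 1.0, "B": 1.0})
        truth, samples, grids = self._setup(cfg)
        exp_ip, exp_in = expected_counts(truth, samples[0], cfg, grids)
        planted = truth.site_windows()
        sid = samples[0].sample_id
        for gid, grid in grids.items():
            ratio = exp_ip[gid] / exp_in[gid]
            for w in range(grid.n_windows):
                if (gid, w) in planted:
                    s = truth.stoichiometry.at[f"{gid}:{w}", sid]
                    assert ratio[w] == pytest.approx(1.0 + cfg.enrichment_fold * s)
                else:
                    assert ratio[w] == pytest.approx(1.0)  # null window: E[IP]/E[input] = background

    def test_doubling_efficiency_doubles_enrichment_component(self):
        cfg = _small_cfg(batch_ip_efficiency={"A": 1.0, "B": 2.0})
        truth, samples, grids = self._setup(cfg)
        a = next(s for s in samples if s.batch == "A")
        b = next(s for s in samples if s.batch == "B")
        exp_ip_a, exp_in_a = expected_counts(truth, a, cfg, grids)
        exp_ip_b, exp_in_b = expected_counts(truth, b, cfg, grids)
        for _, row in truth.sites.iterrows():
            gid, w, sid = row["gene_id"], row["window_index"], row["site_id"]
            enrich_a = exp_ip_a[gid][w] / exp_in_a[gid][w] - cfg.background
            enrich_b = exp_ip_b[gid][w] / exp_in_b[gid][w] - cfg.background
            s_a = truth.stoichiometry.at[sid, a.sample_id]
            s_b = truth.stoichiometry.at[sid, b.sample_id]
            assert enrich_b / s_b == pytest.approx(2.0 * enrich_a / s_a)

    def test_negative_binomial_mean_matches_theory(self):
        cfg = _small_cfg()
        rng = np.random.default_rng(9)
        m, size = 80.0, cfg.nb_size
        draws = rng.negative_binomial(size, size / (size + m), size=10_000)
        assert abs(draws.mean() - m) / m < 0.02

    def test_nonpositive_depth_rejected(self):
        cfg = _small_cfg()
        truth, samples, grids = self._setup(cfg)
        cfg.depth = 0.0
        with pytest.raises(ValueError, match="depth"):
            simulate_sample_counts(truth, samples[0], cfg, 0, grids)


class TestDataset:
    def test_end_to_end_determinism(self):
        cfg = _small_cfg()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = simulate_dataset(cfg, 4)
            d2 = simulate_dataset(cfg, 4)
        assert d1.sequences == d2.sequences
        for s in d1.ip_counts:
            for g in d1.ip_counts[s]:
                assert np.array_equal(d1.ip_counts[s][g], d2.ip_counts[s][g])
        assert d1.truth.stoichiometry.equals(d2.truth.stoichiometry)

    def test_submotif_proportions_respected(self):
        cfg = SimulationConfig(n_genes=150, n_constitutive=120, n_variable=0,
                               submotif_props=(0.0, 0.0, 1.0, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = simulate_dataset(cfg, 1)
        assert set(ds.truth.sites["submotif"]) == {SUBMOTIFS[2]}

    def test_library_sizes_are_column_sums_plus_background(self, small_dataset):
        cfg = small_dataset.config
        for rec in small_dataset.samples:
            total = sum(v.sum() for v in small_dataset.ip_counts[rec.sample_id].values())
            assert rec.ip_library_size == total + cfg.library_background
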