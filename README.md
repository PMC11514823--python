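# meripvar

Quantitative analysis of MeRIP-seq / m6A-seq experiments: window-based
**winscore** peak calling, per-sample **m6A ratio** quantification robust to
library and batch effects, coefficient-of-variation (CV) heterogeneity
analysis, mega-gene / sub-motif characterization, differential methylation,
and regulator–m6A correlation networks. A bundled synthetic MeRIP-seq
generator with planted ground truth makes every stage testable end to end
without downloading data.

## Who this is for

Epitranscriptomics groups comparing m6A methylomes across tissues,
conditions (cancer vs normal) or labs from antibody-based sequencing data,
and methodologists who want a peak-to-network pipeline whose every
statistical step is validated against a generative model with known truth.

## The model in brief

For each gene (longest transcript), 100-nt windows stepped by 50 nt are
quantified in IP and input libraries as RPKM. A window is a peak within a
sample when

    winscore = (RPKM_IP + 1) / (RPKM_input + 1) > 2,

the +1 pseudocount down-weighting low-coverage windows. Peak windows are
unioned across samples, merged when adjacent, and split into peaks of at
most five windows. Each peak's m6A ratio per sample is the maximum over its
windows of RPKM_IP / RPKM_input, NA when input RPKM < 5; peaks NA in a
majority of samples are dropped, and the peak x sample matrix is
quantile-normalized to remove sample-level distortions such as antibody
(IP) efficiency differences between batches. Downstream, per-group
CV = SD/mean flags cancer-specific sites (CV > 0.3), a Welch t-test with
Benjamini–Hochberg adjustment finds differentially methylated sites, a
composition-preserving shuffle test scores the m6A sub-motifs
(GGACA/AGACU/GGACU/GAACU), and Pearson correlation between regulator
expression (log2 TPM + 1) and site levels yields a thresholded regulatory
network. Details and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

```python
from meripvar.simulate import SimulationConfig, simulate_dataset
from meripvar.pipeline import call_and_quantify
from meripvar import benchmarks

ds = simulate_dataset(SimulationConfig(), seed=1)   # 200 genes, 12 samples
state = call_and_quantify(ds)                       # peaks -> ratios -> normalized
print(f"peaks called: {len(state.peaks)}")
rec = benchmarks.peak_recovery(ds, state)
print(f"sensitivity {rec['sensitivity']:.3f}, precision {rec['precision']:.3f}")
shrink = benchmarks.batch_shrinkage(ds, state)
print(f"batch difference: {shrink['pre_difference']:.2f} -> "
      f"{shrink['post_difference']:.2f} (shrinkage {shrink['shrinkage']:.1%})")
```

prints

```
peaks called: 240
sensitivity 1.000, precision 1.000
batch difference: 6.06 -> 0.17 (shrinkage 97.2%)
```

All 240 planted methylated windows are recovered with no false peaks, and
quantile normalization removes 97% of the mean ratio difference that the
planted 2x IP-efficiency batch effect introduced at stable (constitutive)
sites. The normalized matrix (`state.normalized`) is a peaks x samples
`DataFrame` ready for the CV, differential and network stages.

The same pipeline runs from the shell over files:

```
meripvar simulate --config config.yaml --seed 1 --out-dir run/
meripvar run      --config config.yaml --seed 1 --out-dir run/
```

writing `peaks.bed`, `ratio_matrix[.normalized].tsv`, `cv_table.tsv`,
`differential_methylation.tsv`, `submotif_results.tsv`, network tables and
a `manifest.json` stamped with the configuration hash and seed.

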