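# Methods

`meripvar` quantifies N6-methyladenosine (m6A) from MeRIP-seq / m6A-seq
experiments — paired immunoprecipitation (IP) and input libraries per
sample — and analyzes how methylation varies across tissues, conditions and
batches. This note records the model, the parameter choices, the synthetic
data generator's assumptions, and the numerical decisions a maintainer
would want to know.

## Window quantification and peak calling

Each gene is represented by a single transcript (the longest annotated
isoform) and scanned with 100-nt windows stepped by 50 nt, so consecutive
windows overlap by 50 nt; a terminal partial window is kept when it is at
least 50 nt. Windows are quantified as RPKM — reads x 10^9 / (window length
x mapped library reads) — separately for IP and input. The enrichment score
of a window is

    winscore = (RPKM_IP + 1) / (RPKM_input + 1)

with the +1 pseudocount damping low-coverage windows whose raw ratio is
unstable. Windows with winscore strictly above 2 are m6A peaks within a
sample. Peak windows are unioned across samples, adjacent flagged windows
merge, and runs longer than five windows (300 nt) are split greedily left
to right into chunks of at most five; the greedy split is one of several
valid partitions and was chosen for determinism.

The methylation level (m6A ratio) of a peak in a sample is the maximum over
the peak's windows of the plain ratio RPKM_IP / RPKM_input — the maximum
absorbs center/width shifts of the same underlying peak between library
preparations, and the pseudocount is deliberately *not* applied here: it
belongs to detection, not quantification. A window's ratio is NA when its
input RPKM is below 5 (exactly 5.0 is kept: the rule reads "below"); a peak
is NA when all its windows are; peaks NA in a strict majority of samples
are dropped (an exact half is kept). Both strictness choices are boundary
conventions documented here because the verbal rules do not decide them.

## Quantile normalization

Antibody efficiency and library chemistry differ between labs, scaling the
IP-enrichment component of the ratio per sample. Rank-based quantile
normalization forces every sample's ratio distribution onto a common
reference: the mean of the per-sample order statistics, interpolated onto a
shared grid of quantile positions so samples with unequal non-NA counts
contribute comparably. Ties within a sample receive the mean of the
reference values at the tied ranks; NA entries are untouched; a sample with
fewer than two non-NA values is an error. The interpolated-reference NA
handling is this package's choice — with complete columns of equal length
it reduces exactly to textbook quantile normalization.

A property worth knowing: when a large fraction of sites is genuinely
differentially distributed between samples, quantile normalization
converts other sites' biological variation into value noise for stable
sites (rank churn through a forced common distribution). This is the
standard caveat of the method and is visible in the synthetic experiments
when variable sites are made to dominate the peak set.

## Heterogeneity, specificity, differential methylation

Per site and group, the coefficient of variation CV = SD / mean uses the
sample SD (n−1 denominator; group sizes are small) over non-NA entries; CV
is NA when fewer than 3 values remain or the mean is non-positive. Sites
with CV strictly above 0.3 within a cancer group are that cancer type's
specific (variable) sites; a site may be specific to several groups.
CV fold changes (cancer/normal) are summarized per mega-gene segment by the
median. Differential methylation is a per-site Welch t-test (two-sided,
unpaired, unequal variance) between conditions on non-NA values, skipping
sites with fewer than 3 values in either condition (the skip is reported);
Benjamini–Hochberg adjustment runs over the tested universe only, and
fdr < 0.05 defines the significant set. Sample relationships use
pairwise-complete Pearson correlation (NA patterns differ per sample, so
listwise deletion would discard most data) with average-linkage clustering
on 1 − r.

## Mega-gene frame and sub-motif test

Coding transcripts are mapped onto a composite "mega gene" whose 5'UTR, CDS
and 3'UTR each contribute 10 bins; a peak's coordinate is its midpoint's
region index plus the fraction through that region, and densities are
normalized to mean 1 over the 30 bins. Start- and stop-codon segments are
the ±100 nt (one window width) neighborhoods of the codon's first base —
the segment width is a parameter (`--flank`) because no canonical value
exists; the nearer codon wins when both are in range, and flank 0 disables
codon segments entirely. Non-coding genes participate in peak calling but
have no UTR/CDS frame and are excluded from the profile.

The sub-motif analysis scans the four m6A consensus 5-mers GGACA, AGACU,
GGACU, GAACU (sense strand only) over each peak's spliced sequence and
counts, per motif, the windows containing at least one match start. The
null shuffles the nucleotides within each peak (composition-preserving),
rescans and recounts; with `n_iter` draws the empirical p-value is
(1 + #{null ≥ observed}) / (n_iter + 1), and per-motif percentages are
mean-centered for cross-sample display (they sum to zero by construction).
An alternative null that permutes motif labels among fixed occurrence
positions exists behind `mode="label_permute"` but is not the default; the
within-peak nucleotide shuffle is the more direct reading of a
sequence-shuffling null. Because the statistic is a small count, its null
distribution is discrete; uniformity of the empirical p-values is only a
meaningful check when the peak set carries enough windows (the calibration
harness uses 400) — with very few windows the ≥ convention at tied values
is visibly conservative.

## Regulator network

Candidate edges correlate a regulator's log2(TPM + 1) expression with a
cancer-specific site's normalized ratio across a group's samples
(pairwise-complete, at least 5 pairs; constant vectors are dropped with a
reason). The +1 inside the log avoids log 0 at unexpressed regulators.
Regulator classes (classical writers/erasers/readers vs additional
cell-specific trans-factors) come from user lists; cumulative |r| curves
per class are compared with a two-sided rank-sum test, against a null built
by permuting the matrix's sample labels (seeded). The network keeps edges
with |r| ≥ 0.6 after BH adjustment across all candidates at fdr < 0.05;
both thresholds are flags (`--r-min`, `--no-fdr`-style fidelity runs use
the unadjusted p), and the correlation sign is retained. Correlations
default to within-group computation with a pooled option.

## Synthetic data generator

No public MeRIP-seq dataset ships with ground truth, so the package
includes a generator that emulates the data-generating process the
pipeline assumes, with every planted quantity serialized:

* **Genome / annotation.** One contig per gene; i.i.d. background sequence
  at configurable GC; 1–4 exons on either strand; 5'UTR (60–300 nt), CDS
  (300–1500 nt, multiple of 3), 3'UTR (150–600 nt).
* **Sites.** Constitutive sites occupy the window nearest the stop codon
  with stoichiometry i.i.d. Beta(160, 40) per sample (mean 0.8, CV ≈ 0.035)
  — the stable, stop-codon-proximal methylation typical of most expressed
  genes; by default 180 of 200 genes carry one. Variable sites sit in the
  CDS/start-codon region with
  logit(stoichiometry) = baseline + tissue effect + condition shift +
  coeff x z(driver log2 TPM) + noise. Defaults: baseline logit −0.9
  (≈ 0.29), tissue effect SD 0.7, cancer shift +0.6 with noise SD
  0.5 x 1.5 (cancer methylation is both higher and noisier), two driver
  regulators with coefficient 2.2 among six regulators. The baseline keeps
  variable sites mid-range: near-zero stoichiometry is invisible behind the
  unmethylated background, and saturation near 1 erases variability, so
  neither emulates a genuinely variable site.
* **Counts.** Input counts are negative binomial with mean
  depth x (TPM / reference TPM) x window length / 100 (depth 300
  reads/window at reference expression, mild per-sample expression wobble,
  NB size 500 — mild overdispersion). IP counts are negative binomial with
  mean input_mean x (background + efficiency x fold x stoichiometry), fold
  8, background 1. Library sizes are the window-count column sums plus a
  2 x 10^7-read remainder representing the rest of the transcriptome, which
  puts window RPKMs on a realistic O(10) scale where the +1 pseudocount is
  meaningful.
* **Batch effect.** Per-sample IP efficiency multiplies the *enrichment
  component* only: antibody efficiency changes which fragments are
  captured, i.e. the read composition, while total sequencing depth is set
  by the sequencer. A global per-sample count multiplier would cancel
  exactly under RPKM and could never reach the ratio matrix; the
  composition form survives library-size normalization and is exactly the
  distortion quantile normalization removes. Default efficiencies: batch A
  1.0, batch B 2.0.
* **Motifs.** Each planted site has one sub-motif (configurable
  proportions) patched into the genome at its window center, through the
  strand-aware spliced projection.

Everything is deterministic under a fixed (config, seed) pair, file bytes
included.

**What the generator does not emulate:** read-level artifacts (mappability,
PCR duplication, fragment-length effects), isoform switching, correlated
counts between overlapping windows (window counts are drawn independently,
so a planted site elevates exactly one window), peak-width variation, and
any non-multiplicative batch distortion. Passing truth-recovery tests
therefore demonstrates the statistical machinery under the model's own
assumptions, not performance on real libraries.

## Validation experiments and problem sizes

The benchmark module runs scenario simulations sized to finish in seconds
to a couple of minutes each; these sizes are the package's validation
scale, chosen to make the recovery statistics stable:

* default conditions — 200 genes, 12 samples (2 tissues x 2 conditions x 3
  replicates, 2 batches), 240 planted sites: peak sensitivity/precision,
  batch-difference shrinkage after normalization, CV > 0.3 recovery of the
  variable/constitutive split;
* differential test — 1000 sites at n = 10/10 (pure noise for type-I
  calibration; 100 sites shifted 2 SD for power under BH at fdr < 0.05);
* sub-motif — 200 motif-free replicate datasets of 100 peaks x 4 windows at
  500 shuffles for p-value uniformity (one p per replicate, rotating the
  motif, so the 200 KS samples are independent), and a 70%-GGACU planted
  dataset at 10,000 shuffles for detection;
* regulator network — one driver regulator with 50 target sites among six
  regulators, 20 cancer + 20 normal samples;
* clustering — three tissues x two batches x two replicates per condition
  with tissue-effect SD 1.5 and weak drivers (0.8), since strong shared
  drivers legitimately correlate samples across tissues and would test the
  wrong thing.

## Known limitations

* One transcript per gene; no isoform-aware quantification.
* The bedGraph-to-counts estimator (coverage x length / read length) is an
  approximation and is labeled as such.
* Windows of a peak are scored independently; no spatial smoothing.
* Quantile normalization assumes most sites are comparably distributed
  across samples; it degrades when variable sites dominate (see above).
* The CV threshold (0.3) and network thresholds (|r| ≥ 0.6, fdr < 0.05) are
  conventions exposed as parameters, not estimated from data.
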