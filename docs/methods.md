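# Methods

## Scope and model

`xdosage` analyses dosage compensation in an XX (female) / XO (male) system.
Three observable signatures drive everything:

- **DNA dose.** A male carries one X copy, so at matched sequencing effort
  the male:female read depth ratio is 1 on autosomes and 0.5 on the X.
- **Expression balance between sexes.** With complete compensation the
  single male X is transcribed up to the female level, so per-gene F:M
  expression ratios on the X centre at 1; without compensation they centre
  at 2 (two copies vs one).
- **Expression balance between chromosome classes.** The X:A ratio (median
  X-linked expression over median autosomal expression, within one sex)
  distinguishes *how* balance is achieved: male upregulation keeps male
  X:A ≈ 1, whereas downregulation of both female copies drives X:A to ≈ 0.5
  in both sexes while still balancing the sexes.

## X identification

Input is a windowed coverage table (0-based half-open windows; 100 kb by
default, matching common practice for insect-sized genomes). Windows with
female depth < `min_depth` (default 5 reads) or zero male depth are dropped
and counted. When male and female libraries differ in total depth,
`normalize_libsize` divides all ratios by their genome-wide median — with
≥ 14 autosomes the median window is autosomal, so this pins the autosomal
mode at 1 without requiring the classes to be known in advance.

A chromosome is labelled **X** when the median of its window ratios falls
in `[0.35, 0.65]`, **autosome** in `[0.8, 1.2]`, else **unassigned**;
chromosomes with fewer than 5 retained windows are unassigned. The bands
are deliberately generous around the theoretical 0.5 and 1.0 — observed
medians sit within a few percent of theory at depth ≥ 20 — and are
configurable because no formal rule is standard in the literature, only the
observation. Medians, not means, resist coverage spikes from collapsed
repeats. Classification always uses raw-scale ratios; log2 ratios are kept
for plotting.

LOESS smoothing (local linear fit, tricube weights over the
`ceil(span · n)` nearest windows, span 0.3, no robustness iterations) is
provided for ratio-track figures only and never feeds the classifier. A
constant or exactly linear track is reproduced exactly (a property the test
suite exploits as an oracle), and each chromosome is smoothed independently
so curves never bleed across chromosome boundaries.

## Normalization and filtering

FPKM is computed as `count / (exonic_kb · libsize_millions)`, where the
library size is the column sum times the sample's TMM factor. TMM follows
the published trimmed-mean-of-M-values definition: reference sample chosen
by upper-quartile count fraction closest to the mean; genes with a zero in
either sample excluded; 30% two-sided trim on M (log ratio of count
fractions) and 5% on A (mean log abundance); factor = 2 to the
precision-weighted mean of surviving M values (binomial variance weights);
factors rescaled to multiply to 1. Known behaviour worth stating: the
binomial weights assume technical (Poisson) noise, so at shallow depth
(median gene counts in the single digits) the zero-exclusion step can bias
factors by several percent; at realistic depth the factors recover known
per-sample depth multipliers to well under 2%, and the depth-recovery test
runs at 2×10⁷ reads for that reason.

Replicates are arithmetic-averaged on the FPKM scale within (tissue, sex)
after a Spearman rank-correlation QC of replicate pairs. The expression
filter removes a gene from a tissue only when its mean FPKM is below the
threshold (default 1) in **both** sexes: filtering on either sex would
delete exactly the strongly sex-limited genes the sex-bias analysis is
about. The stricter `either_below` rule remains selectable. The filter is
applied per tissue, matching a per-tissue comparison design; a global
variant can be emulated by pre-filtering the count matrix.

For log-scale statistics, FPKM values are floored at 0.01 before log2, so
genes expressed in one sex only contribute large finite ratios rather than
infinities; the floor only matters for genes already past the expression
filter in at least one sex.

## Dosage statistics and status call

Per tissue the report contains Wilcoxon rank-sum p-values for X vs
autosomes within each sex (on log2 FPKM) and for F vs M within each class,
the X:A ratio per sex, and the per-gene F:M ratio distribution per class.
The "median F:M ratio" is the **median of per-gene ratios** — a
distribution supports the rank test comparing X against autosomes — and the
ratio-of-medians variant is also emitted for transparency. The Wilcoxon
wrapper enumerates exactly when min(n) ≤ 8 and the data are tie-free,
otherwise it uses the normal approximation with tie-corrected variance and
continuity correction (worst-case disagreement with the exact p at n = 8 is
about 0.011).

The qualitative status uses two configurable half-widths, δ = ε = 0.15:

- `complete_with_balance`: F:M-on-X median ∈ [1−δ, 1+δ] and male X:A ∈
  [1−ε, 1+ε];
- `complete_unbalanced`: F:M balanced but male X:A outside its band;
- `absent`: F:M-on-X median ≥ 2−δ;
- `partial`: everything else.

The thresholds are this package's construction — the underlying biology is
usually reported qualitatively — and 0.15 was chosen so that at the default
simulation size the sampling noise of the two medians (a few percent)
cannot flip a true regime, while a genuinely intermediate F:M of ~1.5 still
reads as partial.

## Sex-biased genes and enrichment

Counts are CPM-normalized (with TMM factors). The expression filter keeps a
gene when CPM > 1 in every replicate of at least one sex (replicated
design) or in at least one sample (unreplicated; requiring both samples
would discard sex-limited genes).

Dispersion: unreplicated designs fix φ = BCV² = 0.04 for every gene
(BCV 0.2). Replicated designs use a tag-wise method-of-moments estimate on
counts scaled to a common library size, pooled across sexes, shrunk toward
the median dispersion with weight n/(n + n₀) where n is the residual
degrees of freedom and n₀ = 10 prior degrees, floored at 10⁻⁴. The
shrinkage constant is a design choice standing in for full empirical-Bayes
machinery, which is out of scope.

Testing: the default for replicated designs is a likelihood-ratio test of a
one-coefficient NB log-linear model — per-sex means fitted by Fisher
scoring with log link and library-size offsets at fixed φ, LR statistic
referred to χ²(1). For unreplicated designs the default is the exact
conditional NB test: counts are moment-scaled to the mean library size, and
conditional on the total the group sum follows a negative hypergeometric
law with shapes n_F/φ and n_M/φ (binomial in the Poisson limit φ → 0); the
two-sided p sums all outcomes no more likely than the observed one.
logFC is log2 of prior-count-adjusted mean CPM (prior 0.5, scaled by
relative library size), oriented **female over male** throughout. BH
step-up adjustment controls FDR; genes with logFC > 2 (strictly) and
FDR < 0.05 are female-biased, logFC < −2 male-biased.

Enrichment: biased/unbiased × X/autosome 2×2 tables per direction, Fisher's
exact two-sided p (minimum-likelihood summation), odds ratio ad/bc with
rows (biased, unbiased) and columns (X, autosome), so OR > 1 means the
biased class is over-represented on the X. Unassigned chromosomes are
excluded from both classes everywhere.

## Synthetic data

The generator emulates the study conditions the analysis assumes:

- **Genome**: 14 autosomes + 1 X; chromosome length =
  `n_windows_per_chrom × window_size` (default 120 × 100 kb = 12 Mb, the
  small end of real planthopper chromosomes); 1000 genes per chromosome by
  default (~15k genes, matching real annotation density), tiled
  non-overlapping with lognormal exonic lengths (median ≈ 1.5 kb).
- **Coverage**: per window, female depth ~ Poisson(depth_female = 100);
  male depth ~ Poisson of the same mean on autosomes and half on the X.
- **Expression**: baseline lognormal(meanlog 3, sdlog 1.5) on the FPKM
  scale — a stand-in with a realistic heavy right tail, as the empirical
  expression distribution of the real tissues is not published — converted
  to expected counts via exonic length and library size (2×10⁶ reads per
  sample by default), then NB-sampled at dispersion 0.1 (BCV ≈ 0.32,
  typical for biological replicates). Regimes multiply (female X, male X)
  means by (1, 1) `complete_compensation`, (1, 0.5) `no_compensation`, or
  (0.5, 0.5) `female_downregulation`. Sex-biased genes (configurable
  fractions) get an 8-fold boost in the favoured sex, placed uniformly
  across chromosomes or concentrated on the X for enrichment-recovery
  tests. True labels are returned for every gene.
- **Determinism**: one global seed feeds named RNG streams (one per
  simulator), so identical seeds give bitwise-identical outputs and adding
  a simulator never perturbs the others.

What the generator does **not** emulate: GC/mappability coverage biases,
repeat-driven coverage spikes, isoform structure, count correlation between
genes, and batch effects. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated model, not robustness to
every artefact of real libraries; the classification bands and
median-based statistics are the components designed to absorb such
artefacts on real data.

## Problem sizes and numerical choices

Simulation-backed tests run at 15k genes × 2–4 samples (regime recovery,
20 seeds), 2k genes (dispersion recovery, null FDR at 10 seeds), and 120
windows × 15 chromosomes (X identification) — sizes chosen to keep
Monte-Carlo noise well inside the asserted bands. Fisher-scoring mean fits
clip steps to ±5 log units and converge to 10⁻¹⁰; all-zero genes are
reported as p = 1, logFC 0. Exact-test totals are rounded after library
scaling. Ratio computations floor FPKM at 0.01; dispersion estimates floor
at 10⁻⁴. The demo dataset uses 300 genes per chromosome and 60 windows per
chromosome so a full run completes in a few seconds.

## Known limitations

- The status call depends on δ, ε; regimes engineered near the band edges
  (true F:M ≈ 1.15) are ambiguous by construction.
- TMM under-corrects composition at very shallow depth (see above).
- The unreplicated exact test inherits the fixed-BCV assumption; its p
  values are only as good as the assumed dispersion.
- Y-chromosome / ZW systems, multi-factor designs, and mechanistic
  inference about which sex regulates are out of scope.
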