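# Methods

## Problem setting

Sequencing a fixed number of reads per library measures composition,
not amount. If every cell in one condition carries half as much
H3K27me3, or transcribes half as much RNA of every gene, the libraries
are indistinguishable after per-library normalization. Both pipelines
in this package anchor quantification to exogenous spike material whose
per-cell amount is constant across conditions — chromatin from a second
species for ChIP-seq, ERCC transcripts for RNA-seq — so that the
spike's share of each library reports absolute per-cell signal.

## ChIP spike-in model

**Normalization factor.** For an IP sample and its matched input, with
target- and spike-genome read totals (t, s),

NF = (t_IP / s_IP) / (t_input / s_input).

The ratio-of-ratios form is used (rather than any subtractive
"fraction of input") because it is exactly invariant to uniform depth
rescaling of either library and tracks ChIP recovery per cell: under
the generative model below, the expected NF of a condition whose true
per-cell signal mass is scaled by r equals r. A pure input
self-comparison gives NF = 1. Zero spike reads make the NF undefined
and raise a degenerate-input error rather than returning infinity.

**Binned enrichment.** Coverage is counted in non-overlapping 10 kb
bins tiling the genome (last bin of each chromosome truncated). By
default scaled counts are raw counts × NF with no depth adjustment,
matching the fixed-depth design the NF assumes; a `depth_normalize`
flag divides by library size in millions first, for unequal-depth
designs. Per-bin enrichment is log2(IP/input + 0.5), with replicates
averaged before the ratio. The pseudocount sits outside the ratio, so
a zero-IP bin over positive input contributes log2(0.5) = −1; bins with
zero input cannot form a ratio and are dropped with a tally (they are
removed upstream as no-coverage regions in real data anyway).
Distributions are compared by the two-sample two-sided
Kolmogorov–Smirnov test (asymptotic p); replicates are averaged for
ECDF/KS but kept separate for PCA, where each point is a replicate.

**Broad domains.** Domains are called from binned counts against
matched input: per bin, the IP count x is tested for enrichment given
the IP+input total n with the exact conditional binomial test
P(X ≥ x | n, p₀), p₀ = D_IP/(D_IP + D_input) — the standard exact
comparison of two Poisson rates. This form stays calibrated when the
input itself is a noisy count; scoring the IP against a Poisson with
mean equal to the scaled input count (available as
`input_as_expected=True`) treats the input as known and inflates the
false-positive rate roughly √2-fold in z-score terms, which at
genome-wide bin counts produces spurious domains on a null background.
P-values are BH-adjusted; significant bins are chained into domains
tolerating up to 3 non-significant gap bins; domains within 3 kb are
merged (a gap of exactly 3000 bp merges, matching bedtools `-d`
semantics) and replicate domain sets are intersected.

**Batch adjustment (ComBat).** Log-scale bin signal is adjusted for
batch with the parametric empirical-Bayes location/scale model:
features are standardized against the size-weighted grand mean and
pooled variance, per-batch per-feature means and variances are shrunk
toward their across-feature moments (normal prior on locations,
inverse-gamma on scales, iterative conditional updates), and the data
are rescaled. `shrink=False` applies the exact per-feature
standardization, after which batch means agree to machine precision —
the mode used for exactness tests. A single batch is returned
unchanged; a batch with one sample is an error since its scale is
unidentifiable. The implementation reproduces sva::ComBat to ~1e-5
(iteration tolerance) on dense matrices.

**PCA.** Samples-by-bins SVD after feature centering; component signs
are fixed so the largest-magnitude loading is positive, making repeated
runs bit-identical. Variance explained is reported as σₖ²/Σσ².

**Region quantification.** Signal over regions sums overlapping bins
weighted by overlap fraction, so any tiling of the genome conserves
total signal. Normalization is spike-NF or counts-per-million;
division by identically normalized matched input is optional. Promoter
windows extend TSSs strand-awarely (defaults 10 kb upstream / 1 kb
downstream; the bivalent-promoter variant uses 1 kb / 100 bp) and are
clamped to chromosome bounds. Minus-strand windows mirror plus-strand
windows exactly (equal lengths). Repeat elements are classified from
replicate-averaged normalized counts: hyper if log2(high/ctrl) > 0.7
and high > 5; hypo if log2 < −0.7 and high < 3; otherwise neither.
The 0.7 threshold is configurable (an alternative convention uses
|log2(0.7)| ≈ 0.515). Elements with zero control signal are excluded
with a tally.

**Signal matrices.** Heatmap/profile matrices sample the binned signal
on a fixed positional grid around a reference point (region start,
center or end; ±flank) or rescale region bodies to a fixed number of
positions plus flanks. Minus-strand rows are reversed; positions
beyond the chromosome are missing (NaN) unless `missing_as_zero`, and
mean profiles ignore missing values. Rows can be ordered by descending
row mean, the usual heatmap sort.

## CNN RNA-seq model

**Filtering.** ES-cell mode removes genes with a zero count in any
sample and genes never exceeding 3 CPM in any sample ("never exceeds in
all samples" is the reading adopted; an any/all switch exposes the
stricter alternative). Embryo mode removes genes with fewer than 10
raw counts summed across samples. Spike rows are never filtered.

**Normalization.** Trimmed-mean-of-M-values factors are computed from
the ERCC spike rows only, with library sizes fixed to the gene-count
sums N. The reference sample is the one whose upper-quartile
spike expression (count/library-size) is closest to the across-sample
mean; M-values are trimmed 30% each tail and A-values 5%; the factor is
2^(weighted mean of surviving M) with inverse-asymptotic-variance
weights; factors are centered to geometric mean 1. The implementation
matches edgeR::calcNormFactors to numerical precision. CNN
log-expression is log2((count + 0.5)/(N·nf + 1) × 1e6); because N·nf
tracks per-cell RNA content, a global scaling g of the transcriptome
shifts every gene by log2(g) on this scale while leaving plain log-CPM
unchanged — the identifiability the method exists for.

**Moderated differential expression.** Per gene, a two-group contrast
on CNN log-expression; residual variances are shrunk toward a common
prior, s²_post = (d₀s₀² + d·s²)/(d₀ + d), with (d₀, s₀) fitted by
moment-matching the log-variance distribution against the theoretical
scaled-F form (trigamma inversion by Newton iteration) and the
moderated t referred to d₀ + d degrees of freedom. d₀ = 0 recovers the
ordinary equal-variance t exactly. Optional precision weights from a
lowess mean–variance trend are available but off by default: at the
sequencing depths simulated here the trend is nearly flat and the
weights change little. Significance applies BH-adjusted p < 0.05
together with |log2FC| > 0.7.

**Global shift.** The per-gene fold-change list (treated minus control
means on the CNN scale) is summarized with boxplot statistics
(quartile hinges, ±1.5·IQR whiskers) and tested two-sidedly by Wilcoxon
rank-sum against zero-centered control-vs-control fold-changes — an
empirical null with the same per-gene sampling spread. Identical
treated and control sets are permitted (a self-comparison returns all
zeros); partially overlapping sets are a parameter error.

**Litter-matched DE.** Within each litter, treated and control embryos
are compared with a negative-binomial Wald test: median-of-ratios size
factors; per-gene method-of-moments dispersions shrunk on the log scale
toward a fitted mean–dispersion trend α(μ) = a₁/μ + a₀ with 10
pseudo-degrees of freedom on the trend; delta-method standard error of
the log-ratio of group means with a 0.5 pseudocount. The final up
(down) set contains genes with adjusted p < 0.1 and a positive
(negative) fold-change in every litter; direction-discordant genes are
excluded. Acceptance for this engine is calibration (type-I error,
power ranking) rather than identity with any particular external tool.

**Gene sets.** Overlap enrichment is the one-sided Fisher exact
(hypergeometric upper tail) test of the 2×2 membership table,
restricted to a declared universe (defaulting, in the pipeline, to the
genes surviving expression filtering), BH-adjusted across annotation
sets; a two-sided option exists. Random subsets are uniform without
replacement with a mandatory, logged seed. Target-vs-background
fold-change comparisons report boxplot summaries, one-way ANOVA and
pairwise two-sided rank-sum tests.

## Synthetic data

**What it emulates.** The ChIP generator draws, per sample, a
target/spike read split binomial in the mass ratio
(r·(1−f)) : f for IPs (r = 1 in the control condition,
f = spike mass fraction) and (1−f) : f for inputs, then distributes
target reads multinomially over bins proportional to a per-bin profile:
a chromatin background with 5% log-normal bin-to-bin roughness, shared
between an IP and its matched input, times domain enrichment
multipliers. Sharing the background between IP and input is what makes
the domain caller's null exact; the roughness keeps input ratios away
from divide-by-zero while staying featureless. Every sample's reads
sum exactly to the nominal depth.

The RNA generator draws per-cell gene abundances once (log-normal,
σ = 1 on the natural-log scale, giving a realistic several-hundred-fold
expression range at ~500 reads/gene mean), scales the treated
condition's gene abundances by g_global and per-gene DE effects, and
holds spike abundances fixed (92 species, log-normal σ = 2 mimicking
the wide ERCC concentration range, totalling 3% of the control
transcriptome — the typical spike proportion of such designs). Batch
offsets are multiplicative on gene rows only, since spikes are added
after lysis. Libraries of exactly `depth` reads come from a
gamma-perturbed multinomial: relative abundances are jittered by
Gamma(1/α, α) factors and the library drawn multinomially, giving
marginal counts with negative-binomial dispersion α (default 0.05, a
typical biological-replicate value) while conserving depth exactly.
A `profile_seed` can pin the abundance draw independently of the
sampling seed, which is how the Monte-Carlo-vs-expectation oracle
tests condition on a fixed truth.

**What it does not emulate.** No read-level sequence, mappability,
GC or copy-number structure; no PCR duplication; ChIP counts carry no
overdispersion beyond multinomial sampling; domains have hard edges.
Passing tests therefore demonstrate that the estimators recover the
quantities they target under their stated sampling models — not
robustness to alignment artifacts or unmodelled covariance in real
libraries.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; conversions happen only
  at I/O boundaries (BED/bedGraph already use this convention).
- Seeds: one master seed per experiment; per-sample child streams are
  derived through numpy SeedSequence spawn keys, so adding samples
  never perturbs existing ones.
- Merge tie-break: a gap of exactly the merge distance merges.
- KS uses the asymptotic two-sample p-value; D is oracle-checked
  against an exhaustive threshold scan.
- ComBat iteration stops at 1e-8 parameter change (200 iterations max).
- Trigamma inversion: Newton with the standard safeguarded start,
  50 iterations, 1e-8 relative tolerance.
- Degenerate inputs (zero spike reads, all-zero input, empty
  distributions, singleton batches, empty gene sets) raise typed errors
  rather than propagating NaN/inf.
- Problem sizes in tests and the acceptance script (5000 bins at 10 kb,
  1e6 reads, 2000 genes, 2–3 replicates, 100 calibration runs) are
  desk-scale renditions of the study design: large enough that the
  closed-form expectations are sharp, small enough to run in seconds.

## Known limitations

- The NB Wald test is asymptotic; at 3-vs-3 its raw type-I error runs
  slightly above nominal, which the litter-intersection step is
  designed to absorb (only cross-litter-consistent calls survive).
- ComBat is applied without condition covariates; with strongly
  unbalanced condition-by-batch designs some condition signal would be
  absorbed into batch means.
- The broad-domain caller assumes counts at bin scale are
  (conditionally) Poisson; heavy ChIP overdispersion in real data would
  require an NB version of the same conditional test.
- `aggregate_signal_matrix` resamples at bin resolution; flanks smaller
  than one bin width collapse to a single position.
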