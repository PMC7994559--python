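# spikequant

Spike-in-calibrated quantitative ChIP-seq and cell-number-normalized
(CNN) RNA-seq analysis, for detecting **global** per-cell shifts in a
chromatin mark (here, H3K27me3) or in transcriptional output between
cell states — shifts that standard fixed-depth sequencing normalizes
away. The motivating biology is the transition between preimplantation-
like (naive) and postimplantation-like (primed) pluripotent states,
where H3K27me3 redistributes from broad genome-wide domains to focal
peaks and total transcriptional output changes genome-wide.

The package is aimed at computational epigenomics practitioners: it
consumes species-split read totals and binned/region count tables
(plain TSV), BED annotations and chrom.sizes files, and ships a
synthetic-data generator with exact ground truth so the entire stack is
testable without any sequencing data.

## The quantitative core

**ChIP spike-in normalization.** Exogenous chromatin from a second
species is added per cell equivalent before sequencing. For each IP
sample with matched input, the normalization factor is the ratio of
ratios

```
NF = (target_IP / spike_IP) / (target_input / spike_input)
```

which is dimensionless, invariant to sequencing depth, and proportional
to per-cell ChIP recovery. NFs scale binned coverage (non-overlapping
10 kb bins by default); per-bin enrichment is `log2(IP/input + 0.5)`,
compared between states by ECDF plots and two-sample Kolmogorov–Smirnov
tests, and embedded by ComBat-adjusted PCA. A calibrated binned test
against input calls broad domains (with 3 kb merging and
between-replicate intersection), and repeat elements are classified as
hyper-/hypo-marked with count and fold-change thresholds.

**CNN RNA-seq.** ERCC spike-ins added per cell equivalent anchor the
normalization: TMM factors are computed from the spike rows only, with
library sizes fixed to the gene-count sums `N`, and expression is

```
log2( (count + 0.5) / (N * nf + 1) * 1e6 )
```

On this scale a genome-wide doubling of the transcriptome appears as a
median log2 fold-change of +1 (hypertranscription), where per-library
CPM normalization reports 0. Differential expression uses an
empirical-Bayes moderated t on CNN log-expression (ES-cell designs) or
a litter-matched negative-binomial Wald test with direction-consistent
intersection (embryo designs), and gene-set machinery provides
Fisher-exact overlap enrichment and target-vs-random fold-change
comparisons.

## Worked example

Simulate a spike-in ChIP experiment in which the treated condition
carries half the per-cell H3K27me3 mass (`r_global = 0.5`), and an
ERCC-spiked RNA experiment with a transcriptome halving
(`g_global = 0.5`):

```python
import numpy as np
from spikequant import (
    ChipSimParams, RnaSimParams, simulate_chip_experiment, simulate_rna_experiment,
    compute_spikein_nf, cnn_norm_factors, cnn_log_expression, global_shift,
)

params = ChipSimParams(n_bins=5000, depth=1_000_000, n_replicates=2,
                       r_global=0.5, spike_fraction=0.05, seed=1)
splits, bins, truth = simulate_chip_experiment(params)
by = {s.sample: s for s in splits}
for cond in ("control", "treated"):
    nfs = [compute_spikein_nf(by[f"{cond}_rep{i}_IP"], by[f"{cond}_rep{i}_input"]).nf
           for i in (1, 2)]
    print(f"{cond}: mean NF = {np.mean(nfs):.3f}")

rna = RnaSimParams(n_genes=2000, depth=1_000_000, n_replicates=3, g_global=0.5, seed=1)
counts, _ = simulate_rna_experiment(rna)
factors = cnn_norm_factors(counts)
cnn = cnn_log_expression(counts, factors)
info = counts.sample_info
shift = global_shift(cnn,
                     list(info.index[info.condition == "treated"]),
                     list(info.index[info.condition == "control"]))
print(f"median CNN log2FC = {shift['median']:.3f} (rank-sum p = {shift['pvalue']:.3g})")
```

Output:

```
control: mean NF = 0.995
treated: mean NF = 0.503
median CNN log2FC = -1.090 (rank-sum p = 0)
```

The spike-in NF recovers the implanted two-fold loss of per-cell
H3K27me3 (0.503 vs 0.995), and the CNN fold-change distribution is
centred near −1: genome-wide hypotranscription that per-library
normalization would have reported as no change.

The same analyses run from the shell:

```
spikequant simulate chip --seed 1 --outdir sim/
spikequant chip nf --species-counts sim/species_counts.tsv --out nf.tsv
spikequant run chip --outdir chip_out/       # full pipeline on synthetic data
spikequant run rna  --outdir rna_out/
```

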