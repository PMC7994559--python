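"""Spike-in-calibrated quantitative ChIP-seq analysis.

The quantitative backbone is exogenous-genome spike-in normalization:
chromatin from a second species is added per cell equivalent before
sequencing, so the ratio of target-genome to spike-genome reads measures
absolute per-cell signal, which fixed-depth sequencing otherwise erases.
The normalization factor (NF) of an IP sample is its target/spike read
ratio divided by that of its matched input — a dimensionless, depth-
invariant estimate of ChIP recovery per cell.

Downstream, NFs scale binned coverage for cumulative-enrichment (ECDF)
comparisons, batch-adjusted PCA of genome-wide signal, broad-domain
calling, region quantification, and repeat-element classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenomeIndex, Interval

logger = logging.getLogger("spikequant")


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate for this computation."""


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class SpeciesSplitCounts:
    """Per-sample read totals split by genome of origin."""

    sample: str
    role: str  # "IP" or "input"
    condition: str
    replicate: int
    target_reads: int
    spike_reads: int

    def __post_init__(self) -> None:
        if self.role not in ("IP", "input"):
            raise ValueError(f"role must be 'IP' or 'input', got {self.role!r}")

    @property
    def ratio(self) -> float:
        if self.spike_reads <= 0:
            raise DegenerateInputError(
                f"sample {self.sample!r}: zero spike reads, target/spike ratio undefined"
            )
        return self.target_reads / self.spike_reads


@dataclass(frozen=True)
class ScaleFactor:
    sample: str
    nf: float

    def __post_init__(self) -> None:
        if not self.nf > 0:
            raise ValueError(f"normalization factor must be positive, got {self.nf}")


@dataclass
class BinMatrix:
    """Counts over non-overlapping genomic bins x samples.

    ``bins`` tile each chromosome with uniform-width windows (the last bin
    of a chromosome may be short); ``counts`` rows align with ``bins``;
    ``scale_applied`` records the composite per-sample factor already
    multiplied in (1.0 when raw).
    """

    bins: list[Interval]
    counts: pd.DataFrame
    scale_applied: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.bins) != self.counts.shape[0]:
            raise ValueError(
                f"{len(self.bins)} bins but {self.counts.shape[0]} count rows"
            )
        if not self.scale_applied:
            self.scale_applied = {s: 1.0 for s in self.counts.columns}

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def same_bins(self, other: "BinMatrix") -> bool:
        if len(self.bins) != len(other.bins):
            return False
        return all(
            a.chrom == b.chrom and a.start == b.start and a.end == b.end
            for a, b in zip(self.bins, other.bins)
        )


@dataclass
class EnrichmentDistribution:
    """Per-bin log2 IP/input enrichment values for one sample or condition."""

    values: np.ndarray
    label: str
    pseudocount: float
    n_dropped: int = 0

    def ecdf(self, grid: np.ndarray) -> np.ndarray:
        values = np.sort(self.values)
        return np.searchsorted(values, grid, side="right") / len(values)


@dataclass(frozen=True)
class RepeatCall:
    element: Interval
    family: str
    high_signal: float
    ctrl_signal: float
    log2_ratio: float
    call: str  # hyper | hypo | neither


def read_bin_counts(path) -> BinMatrix:
    """Read a bins-x-samples TSV with 3 leading coordinate columns."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["chrom", "start", "end"]:
        raise ValueError(f"{path}: expected leading columns chrom, start, end")
    bins = [
        Interval(row.chrom, int(row.start), int(row.end))
        for row in df.itertuples(index=False)
    ]
    counts = df.drop(columns=["chrom", "start", "end"])
    return BinMatrix(bins=bins, counts=counts)


def write_bin_counts(bins: BinMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in bins.bins],
            "start": [iv.start for iv in bins.bins],
            "end": [iv.end for iv in bins.bins],
        }
    )
    out = pd.concat([df, bins.counts.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalization factors and binned signal


def compute_spikein_nf(
    ip: SpeciesSplitCounts, matched_input: SpeciesSplitCounts
) -> ScaleFactor:
    """Spike-in normalization factor of an IP sample against its input.

    NF = (IP target/spike) / (input target/spike): the target-genome
    enrichment of the IP expressed as a fraction of the input's.  Invariant
    to uniform depth rescaling of either sample; equals 1 for a pure-input
    self-comparison.
    """
    if ip.role != "IP" or matched_input.role != "input":
        raise ValueError("expected an IP sample and its matched input, in that order")
    if matched_input.target_reads <= 0:
        raise DegenerateInputError(
            f"input {matched_input.sample!r} has no target reads; NF undefined"
        )
    nf = ip.ratio / matched_input.ratio
    logger.info("compute_spikein_nf: %s vs %s -> %.6g", ip.sample, matched_input.sample, nf)
    return ScaleFactor(sample=ip.sample, nf=nf)


def bin_genome(genome: GenomeIndex, width: int = 10_000) -> list[Interval]:
    """Tile the genome with non-overlapping fixed-width bins.

    Per chromosome the bins are [0,w), [w,2w), ...; the last bin is
    truncated at the chromosome end, so the union of bins equals the
    genome exactly.
    """
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    bins: list[Interval] = []
    for chrom, length in genome.sizes.items():
        for start in range(0, length, width):
            bins.append(Interval(chrom, start, min(start + width, length)))
    return bins


def scale_bin_counts(
    bins: BinMatrix,
    factors: Sequence[ScaleFactor],
    depth_normalize: bool = False,
    library_sizes: Optional[dict[str, int]] = None,
) -> BinMatrix:
    """Multiply each sample's bin counts by its spike-in NF.

    With ``depth_normalize`` the counts are first divided by the sample's
    library size in millions (counts-per-million), for designs with
    unequal depth.  ``scale_applied`` records the composite factor.
    """
    by_sample = {f.sample: f.nf for f in factors}
    missing = [s for s in bins.samples if s not in by_sample]
    if missing:
        raise KeyError(f"no scale factor for sample(s) {missing}")
    scaled = bins.counts.astype(float).copy()
    applied: dict[str, float] = {}
    for sample in bins.samples:
        factor = by_sample[sample]
        if depth_normalize:
            if library_sizes is None or sample not in library_sizes:
                raise KeyError(f"depth_normalize requires a library size for {sample!r}")
            factor = factor / (library_sizes[sample] / 1e6)
        scaled[sample] = scaled[sample] * factor
        applied[sample] = bins.scale_applied.get(sample, 1.0) * factor
        logger.info("scale_bin_counts: %s x %.6g", sample, factor)
    return BinMatrix(bins=list(bins.bins), counts=scaled, scale_applied=applied)


def enrichment_distribution(
    ip_bins: BinMatrix,
    input_bins: BinMatrix,
    pseudocount: float = 0.5,
    label: str = "",
) -> EnrichmentDistribution:
    """Per-bin log2(IP/input + pseudocount) enrichment values.

    Replicate columns of each matrix are averaged before the ratio is
    formed.  Bins with zero input signal are dropped (they cannot form a
    ratio) and tallied in ``n_dropped``; a zero-IP bin over positive input
    contributes log2(pseudocount).
    """
    if not ip_bins.same_bins(input_bins):
        raise ValueError("IP and input bin lists differ")
    ip = ip_bins.counts.mean(axis=1).to_numpy(dtype=float)
    inp = input_bins.counts.mean(axis=1).to_numpy(dtype=float)
    keep = inp > 0
    values = np.log2(ip[keep] / inp[keep] + pseudocount)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("enrichment_distribution: dropped %d zero-input bins", n_dropped)
    return EnrichmentDistribution(
        values=values, label=label, pseudocount=pseudocount, n_dropped=n_dropped
    )


def ks_compare(
    a: EnrichmentDistribution, b: EnrichmentDistribution
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov comparison of enrichment ECDFs."""
    if len(a.values) == 0 or len(b.values) == 0:
        raise DegenerateInputError("cannot run a KS test on an empty distribution")
    result = stats.ks_2samp(a.values, b.values, alternative="two-sided", method="asymp")
    return float(result.statistic), float(result.pvalue)


# ---------------------------------------------------------------------------
# batch adjustment and PCA


def batch_adjust(
    bins: BinMatrix,
    batch_labels: Sequence[str],
    shrink: bool = True,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> BinMatrix:
    """Location/scale batch adjustment of log-scale bin signal (ComBat).

    Per feature, each batch's mean and variance are standardized away;
    with ``shrink`` the per-batch, per-feature location and scale
    parameters are shrunk toward their across-feature means by parametric
    empirical Bayes (normal prior on locations, inverse-gamma on scales,
    solved by the standard iterative conditional-mode updates).  With
    ``shrink=False`` the adjustment is the exact per-feature
    standardization, after which batch means agree to machine precision.

    Values are expected on a log scale.  A single batch is returned
    unchanged; a batch with fewer than 2 samples is an error.
    """
    labels = np.asarray(batch_labels)
    if len(labels) != len(bins.samples):
        raise ValueError("one batch label per sample required")
    batches = pd.unique(labels)
    if len(batches) == 1:
        return bins
    for b in batches:
        if (labels == b).sum() < 2:
            raise DegenerateInputError(f"batch {b!r} has fewer than 2 samples")

    X = bins.counts.to_numpy(dtype=float).copy()  # features x samples
    n_features, n_samples = X.shape
    batch_idx = [np.flatnonzero(labels == b) for b in batches]
    n_per_batch = np.array([len(ix) for ix in batch_idx])

    # grand mean weighted by batch size; pooled variance of batch-centred data
    batch_means = np.column_stack([X[:, ix].mean(axis=1) for ix in batch_idx])
    grand_mean = batch_means @ (n_per_batch / n_samples)
    resid = X.copy()
    for i, ix in enumerate(batch_idx):
        resid[:, ix] -= batch_means[:, [i]]
    var_pooled = (resid**2).sum(axis=1) / n_samples
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    Z = (X - grand_mean[:, None]) / np.sqrt(var_pooled)[:, None]

    Z_adj = np.empty_like(Z)
    for i, ix in enumerate(batch_idx):
        Zb = Z[:, ix]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        delta_hat = np.where(delta_hat <= 0, 1e-12, delta_hat)
        if shrink:
            gamma_star, delta_star = _eb_batch_params(
                Zb, gamma_hat, delta_hat, max_iter=max_iter, tol=tol
            )
        else:
            gamma_star, delta_star = gamma_hat, delta_hat
        Z_adj[:, ix] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    adjusted = Z_adj * np.sqrt(var_pooled)[:, None] + grand_mean[:, None]
    out = bins.counts.copy()
    out.iloc[:, :] = adjusted
    logger.info(
        "batch_adjust: %d features, %d samples, %d batches (shrink=%s)",
        n_features, n_samples, len(batches), shrink,
    )
    return BinMatrix(bins=list(bins.bins), counts=out,
                     scale_applied=dict(bins.scale_applied))


def _eb_batch_params(Zb, gamma_hat, delta_hat, max_iter, tol):
    """Parametric empirical-Bayes shrinkage of one batch's location/scale."""
    n = Zb.shape[1]
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    # inverse-gamma hyperparameters by moment matching of the delta_hat
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    if s2 <= 0:
        return np.full_like(gamma_hat, gamma_bar), delta_hat
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n * tau2 * gamma_hat + delta_star * gamma_bar) / (
            n * tau2 + delta_star
        )
        sum2 = ((Zb - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (0.5 * sum2 + b_prior) / (n / 2 + a_prior - 1)
        change = max(
            np.abs(gamma_new - gamma_star).max(), np.abs(delta_new - delta_star).max()
        )
        gamma_star, delta_star = gamma_new, delta_new
        if change < tol:
            break
    return gamma_star, delta_star


def pca_embed(
    bins: BinMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the sample-by-bin matrix.

    Returns per-sample coordinates and the variance-explained fraction of
    each component.  Component signs are fixed so the largest-magnitude
    feature loading is positive, making repeated runs bit-identical.
    """
    n_samples = len(bins.samples)
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > n_samples:
        raise ValueError(
            f"cannot extract {n_components} components from {n_samples} samples"
        )
    X = bins.counts.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U * S
    total_var = (X**2).sum()
    var_explained = (S**2) / total_var if total_var > 0 else np.zeros(n_components)
    frame = pd.DataFrame(
        coords,
        index=bins.samples,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return frame, var_explained


# ---------------------------------------------------------------------------
# broad-domain calling and interval post-processing


def call_broad_domains(
    ip_bins: BinMatrix,
    input_bins: BinMatrix,
    gap_bins: int = 3,
    q_threshold: float = 0.05,
    input_as_expected: bool = False,
) -> list[Interval]:
    """Call broad enrichment domains from binned IP counts against input.

    Replicate columns are summed.  Per bin the IP count is tested for
    enrichment over the depth-adjusted input rate: by default with the
    exact conditional (binomial) comparison of two Poisson counts — the
    IP count given the IP+input total — which stays calibrated when the
    input itself is noisy; ``input_as_expected`` instead scores the IP
    count against a Poisson with mean equal to the depth-scaled input
    count.  P-values are BH-adjusted across bins; significant bins are
    chained into domains, tolerating gaps of up to ``gap_bins``
    non-significant bins, and reported as merged intervals.
    """
    if not ip_bins.same_bins(input_bins):
        raise ValueError("IP and input bin lists differ")
    ip = np.rint(ip_bins.counts.sum(axis=1).to_numpy(dtype=float)).astype(np.int64)
    inp = np.rint(input_bins.counts.sum(axis=1).to_numpy(dtype=float)).astype(np.int64)
    ip_total, in_total = ip.sum(), inp.sum()
    if in_total == 0:
        raise DegenerateInputError("input has no reads; domain calling undefined")
    if input_as_expected:
        lam = inp * (ip_total / in_total)
        pvals = stats.poisson.sf(ip - 1, np.maximum(lam, 1e-300))
    else:
        n = ip + inp
        p0 = ip_total / (ip_total + in_total)
        pvals = stats.binom.sf(ip - 1, n, p0)
        pvals[n == 0] = 1.0
    reject, _, _, _ = multipletests(pvals, alpha=q_threshold, method="fdr_bh")

    domains: list[Interval] = []
    sig_by_chrom: dict[str, list[int]] = {}
    for idx, iv in enumerate(ip_bins.bins):
        if reject[idx]:
            sig_by_chrom.setdefault(iv.chrom, []).append(idx)
    for chrom, indices in sig_by_chrom.items():
        run_start = indices[0]
        prev = indices[0]
        for idx in indices[1:]:
            if idx - prev - 1 > gap_bins:
                domains.append(
                    Interval(chrom, ip_bins.bins[run_start].start, ip_bins.bins[prev].end)
                )
                run_start = idx
            prev = idx
        domains.append(
            Interval(chrom, ip_bins.bins[run_start].start, ip_bins.bins[prev].end)
        )
    domains.sort(key=lambda iv: (iv.chrom, iv.start))
    logger.info(
        "call_broad_domains: %d/%d significant bins -> %d domains",
        int(reject.sum()), len(pvals), len(domains),
    )
    return domains


def merge_intervals(
    intervals: Iterable[Interval], merge_distance: int = 0
) -> list[Interval]:
    """Merge intervals whose gap is <= merge_distance (bedtools merge -d semantics)."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= merge_distance:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(chrom, cur_start, cur_end))
    return merged


def intersect_intervals(
    a: Sequence[Interval], b: Sequence[Interval]
) -> list[Interval]:
    """Intersection regions of two sorted, disjoint interval sets."""
    by_chrom_b: dict[str, list[Interval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    out: list[Interval] = []
    for iv in sorted(a, key=lambda iv: (iv.chrom, iv.start)):
        for other in by_chrom_b.get(iv.chrom, []):
            start, end = max(iv.start, other.start), min(iv.end, other.end)
            if start < end:
                out.append(Interval(iv.chrom, start, end))
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


def merge_and_intersect(
    peaks_rep1: Sequence[Interval],
    peaks_rep2: Sequence[Interval],
    merge_distance: int = 3_000,
) -> list[Interval]:
    """Per-replicate 3 kb merge followed by the between-replicate intersection.

    Within each replicate, peaks separated by at most ``merge_distance``
    bases are merged (a gap of exactly 3000 merges); the returned set is
    the regions present in both merged replicates.  Idempotent.
    """
    merged1 = merge_intervals(peaks_rep1, merge_distance)
    merged2 = merge_intervals(peaks_rep2, merge_distance)
    return intersect_intervals(merged1, merged2)


# ---------------------------------------------------------------------------
# region quantification


def region_counts(
    signal: BinMatrix,
    regions: Sequence[Interval],
    normalization: str = "none",
    factors: Optional[Sequence[ScaleFactor]] = None,
    library_sizes: Optional[dict[str, int]] = None,
    input_signal: Optional[BinMatrix] = None,
    average_replicates: bool = False,
) -> pd.DataFrame:
    """Summed signal over regions, one row per region, one column per sample.

    Bins partially covered by a region contribute in proportion to the
    overlap fraction, so summing over any tiling of the genome conserves
    total signal.  ``normalization`` is ``"spike_nf"`` (multiply by the
    sample's NF), ``"library_size"`` (counts per million) or ``"none"``;
    with ``input_signal`` the result is divided by the identically
    normalized input (regions with zero input yield NaN).
    """
    known_chroms = {iv.chrom for iv in signal.bins}
    for region in regions:
        if region.chrom not in known_chroms:
            raise KeyError(f"region on unknown chromosome {region.chrom!r}")

    bin_index: dict[str, list[tuple[int, int, int]]] = {}
    for idx, iv in enumerate(signal.bins):
        bin_index.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))

    counts = signal.counts.to_numpy(dtype=float)
    rows = np.zeros((len(regions), counts.shape[1]))
    for r, region in enumerate(regions):
        for start, end, idx in bin_index[region.chrom]:
            ov = min(end, region.end) - max(start, region.start)
            if ov > 0:
                rows[r] += counts[idx] * (ov / (end - start))

    names = [
        region.name or f"{region.chrom}:{region.start}-{region.end}"
        for region in regions
    ]
    table = pd.DataFrame(rows, index=names, columns=signal.samples)

    if normalization == "spike_nf":
        if factors is None:
            raise ValueError("spike_nf normalization requires factors")
        nf = {f.sample: f.nf for f in factors}
        for sample in table.columns:
            table[sample] *= nf[sample]
    elif normalization == "library_size":
        if library_sizes is None:
            raise ValueError("library_size normalization requires library sizes")
        for sample in table.columns:
            table[sample] /= library_sizes[sample] / 1e6
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")

    if input_signal is not None:
        denom = region_counts(
            input_signal, regions, normalization=normalization,
            factors=factors, library_sizes=library_sizes,
        )
        denom_mean = denom.mean(axis=1)
        table = table.div(denom_mean.where(denom_mean > 0), axis=0)

    if average_replicates:
        table = table.mean(axis=1).to_frame("mean")
    return table


def promoter_windows(
    tss: Sequence[Interval],
    upstream: int = 10_000,
    downstream: int = 1_000,
    genome: Optional[GenomeIndex] = None,
) -> list[Interval]:
    """Strand-aware promoter windows around single-base TSS records.

    Upstream extends against the direction of transcription, downstream
    with it (bedtools slop -l/-r semantics); windows are clamped to
    chromosome bounds when a genome index is given.  The defaults give
    the generous promoter window; (1000, 100) gives the bivalent-promoter
    variant.
    """
    out: list[Interval] = []
    for iv in tss:
        if genome is not None and iv.chrom not in genome:
            raise KeyError(f"TSS on unknown chromosome {iv.chrom!r}")
        if iv.strand == "-":
            start, end = iv.start - downstream, iv.end + upstream
        else:
            start, end = iv.start - upstream, iv.end + downstream
        start = max(0, start)
        if genome is not None:
            end = min(end, genome[iv.chrom])
        out.append(Interval(iv.chrom, start, end, name=iv.name, strand=iv.strand))
    return out


def bivalent_peak_set(
    bivalent_gene_tss: Sequence[Interval],
    baseline_peaks: Sequence[Interval],
    genome: Optional[GenomeIndex] = None,
) -> list[Interval]:
    """Baseline peaks overlapping at least one bivalent promoter window.

    Windows are the (1 kb upstream, 100 bp downstream) bivalent variant;
    each overlapping peak is reported once, in sorted order.
    """
    windows = promoter_windows(
        bivalent_gene_tss, upstream=1_000, downstream=100, genome=genome
    )
    win_by_chrom: dict[str, list[Interval]] = {}
    for w in windows:
        win_by_chrom.setdefault(w.chrom, []).append(w)
    selected = []
    for peak in baseline_peaks:
        if any(peak.overlaps(w) for w in win_by_chrom.get(peak.chrom, [])):
            selected.append(peak)
    selected.sort(key=lambda iv: (iv.chrom, iv.start))
    return selected


def classify_repeat_elements(
    high: pd.Series,
    ctrl: pd.Series,
    elements: Optional[Sequence[Interval]] = None,
    families: Optional[Sequence[str]] = None,
    min_hyper: float = 5.0,
    max_hypo: float = 3.0,
    log2_threshold: float = 0.7,
) -> tuple[list[RepeatCall], int]:
    """Classify repeat elements as hyper-, hypo- or unchanged in signal.

    ``high`` and ``ctrl`` are replicate-averaged normalized counts per
    element, aligned by index.  An element is *hyper* when
    log2(high/ctrl) > ``log2_threshold`` and high > ``min_hyper``; *hypo*
    when log2(high/ctrl) < -``log2_threshold`` and high < ``max_hypo``;
    otherwise *neither*.  Elements with zero control signal cannot form a
    ratio; they are excluded and tallied in the returned count.
    """
    if not high.index.equals(ctrl.index):
        raise ValueError("element lists are not aligned")
    calls: list[RepeatCall] = []
    n_excluded = 0
    for i, key in enumerate(high.index):
        h, c = float(high.iloc[i]), float(ctrl.iloc[i])
        if c <= 0:
            n_excluded += 1
            continue
        ratio = np.log2(h / c) if h > 0 else -np.inf
        if ratio > log2_threshold and h > min_hyper:
            call = "hyper"
        elif ratio < -log2_threshold and h < max_hypo:
            call = "hypo"
        else:
            call = "neither"
        element = elements[i] if elements is not None else Interval("?", 0, 1, name=str(key))
        family = families[i] if families is not None else str(key)
        calls.append(
            RepeatCall(
                element=element, family=family, high_signal=h, ctrl_signal=c,
                log2_ratio=float(ratio), call=call,
            )
        )
    return calls, n_excluded


# ---------------------------------------------------------------------------
# signal matrices for heatmaps / profile plots


def aggregate_signal_matrix(
    signal: BinMatrix,
    regions: Sequence[Interval],
    mode: str = "reference_point",
    flank: int = 5_000,
    body_bins: int = 0,
    anchor: str = "start",
    sample: Optional[str] = None,
    missing_as_zero: bool = False,
    sort_by_mean: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Region-by-position signal matrix plus its mean profile.

    ``reference_point`` mode samples the binned signal on a fixed grid of
    positions spanning +/- ``flank`` around each region's anchor (its
    start, center, or end); ``scale_regions`` mode resamples each region
    body to ``body_bins`` positions and adds flanks.  Minus-strand
    regions are reversed so position runs 5'->3'.  Positions beyond the
    chromosome are missing (NaN) unless ``missing_as_zero``; the mean
    profile is the column mean ignoring missing values.  With
    ``sort_by_mean`` rows are ordered by decreasing row mean, the order
    used for signal heatmaps.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if mode not in ("reference_point", "scale_regions"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "scale_regions" and body_bins <= 0:
        raise ValueError("scale_regions mode requires body_bins > 0")

    width = len(signal.bins[0])
    tracks: dict[str, np.ndarray] = {}
    chrom_len: dict[str, int] = {}
    values = (
        signal.counts[sample].to_numpy(dtype=float)
        if sample is not None
        else signal.counts.mean(axis=1).to_numpy(dtype=float)
    )
    for idx, iv in enumerate(signal.bins):
        chrom_len[iv.chrom] = max(chrom_len.get(iv.chrom, 0), iv.end)
    for chrom, length in chrom_len.items():
        tracks[chrom] = np.full((length + width - 1) // width, np.nan)
    for idx, iv in enumerate(signal.bins):
        tracks[iv.chrom][iv.start // width] = values[idx]

    def sample_at(chrom: str, pos: float) -> float:
        if chrom not in tracks or pos < 0 or pos >= chrom_len[chrom]:
            return 0.0 if missing_as_zero else np.nan
        return tracks[chrom][int(pos // width)]

    n_flank = max(1, flank // width)
    if mode == "reference_point":
        offsets = (np.arange(2 * n_flank) - n_flank) * width + width / 2
        columns = [int(o - width / 2) for o in offsets]
        rows = []
        for region in regions:
            if anchor == "start":
                ref = region.end if region.strand == "-" else region.start
            elif anchor == "center":
                ref = (region.start + region.end) / 2
            elif anchor == "end":
                ref = region.start if region.strand == "-" else region.end
            else:
                raise ValueError(f"unknown anchor {anchor!r}")
            row = np.array([sample_at(region.chrom, ref + o) for o in offsets])
            if region.strand == "-":
                row = row[::-1]
            rows.append(row)
    else:
        columns = (
            [f"u{k}" for k in range(n_flank)]
            + [f"b{k}" for k in range(body_bins)]
            + [f"d{k}" for k in range(n_flank)]
        )
        rows = []
        for region in regions:
            up = [
                sample_at(region.chrom, region.start - (n_flank - k) * width + width / 2)
                for k in range(n_flank)
            ]
            body = [
                sample_at(
                    region.chrom,
                    region.start + (k + 0.5) / body_bins * len(region),
                )
                for k in range(body_bins)
            ]
            down = [
                sample_at(region.chrom, region.end + k * width + width / 2)
                for k in range(n_flank)
            ]
            row = np.array(up + body + down)
            if region.strand == "-":
                row = row[::-1]
            rows.append(row)

    names = [
        region.name or f"{region.chrom}:{region.start}-{region.end}"
        for region in regions
    ]
    matrix = pd.DataFrame(np.vstack(rows), index=names, columns=columns)
    if sort_by_mean:
        order = matrix.mean(axis=1, skipna=True).sort_values(ascending=False).index
        matrix = matrix.loc[order]
    profile = matrix.mean(axis=0, skipna=True).to_numpy()
    return matrix, profile
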