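"""Cell-number-normalized (CNN) RNA-seq analysis anchored to ERCC spike-ins.

Standard RNA-seq normalization forces every library to the same total and
so cannot see a global rise or fall of the transcriptome: a cell making
twice as much RNA of every gene yields an identical library.  When ERCC
spike-ins are added per cell equivalent, the spikes' share of the library
reports per-cell RNA content.  Normalization factors are computed from
the spike rows only (trimmed mean of M-values, with library sizes fixed
to the *gene*-count sums), and expression is put on a log scale against
the spike-anchored effective library size.  On that CNN scale, global
hyper- and hypotranscription appear as a genome-wide shift of fold-
changes that per-library normalization hides.

The module also provides the differential-expression machinery used
downstream: an empirical-Bayes moderated t-test on CNN log-expression,
and a negative-binomial Wald test applied litter by litter with
direction-consistent intersection of significant genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("spikequant")


class DegenerateInputError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Gene-by-sample raw counts with flagged spike-in (ERCC) rows.

    ``sample_info`` is indexed by sample name with at least a
    ``condition`` column; ``batch`` (litter) and ``replicate`` are used
    where relevant.
    """

    counts: pd.DataFrame
    spike_rows: pd.Index
    sample_info: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        unknown = self.spike_rows.difference(self.counts.index)
        if len(unknown):
            raise ValueError(f"spike rows not present in counts: {list(unknown)[:3]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_rows(self) -> pd.Index:
        return self.counts.index.difference(self.spike_rows, sort=False)

    @property
    def gene_counts(self) -> pd.DataFrame:
        return self.counts.loc[~self.counts.index.isin(self.spike_rows)]

    @property
    def spike_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.counts.index.isin(self.spike_rows)]

    @property
    def lib_sizes(self) -> pd.Series:
        """Library sizes N: per-sample sums of gene (not spike) counts."""
        return self.gene_counts.sum(axis=0)


@dataclass
class CnnFactors:
    """Per-sample spike-anchored normalization factors.

    ``nf`` has geometric mean 1 (the usual centering convention);
    ``effective_sizes`` = N * nf are the CNN effective library sizes.
    """

    nf: pd.Series
    lib_sizes: pd.Series

    @property
    def effective_sizes(self) -> pd.Series:
        return self.lib_sizes * self.nf


# ---------------------------------------------------------------------------
# filtering and normalization


def filter_low_expression(
    counts: CountMatrix,
    cpm_threshold: float = 3.0,
    mode: str = "es",
    min_total: int = 10,
    cpm_rule: str = "all",
) -> CountMatrix:
    """Remove weakly expressed genes; spike rows are never filtered.

    ES mode drops genes with a zero count in any sample and genes whose
    counts-per-million fall at or below ``cpm_threshold`` in all samples
    (``cpm_rule="any"`` switches to the stricter reading that one low
    sample suffices).  Embryo mode drops genes whose raw counts sum to
    fewer than ``min_total`` across samples.
    """
    genes = counts.gene_counts
    if mode == "es":
        no_zero = (genes > 0).all(axis=1)
        cpm = genes / counts.lib_sizes * 1e6
        if cpm_rule == "all":
            passes_cpm = (cpm > cpm_threshold).any(axis=1)
        elif cpm_rule == "any":
            passes_cpm = (cpm > cpm_threshold).all(axis=1)
        else:
            raise ValueError(f"unknown cpm_rule {cpm_rule!r}")
        keep = genes.index[no_zero & passes_cpm]
    elif mode == "embryo":
        keep = genes.index[genes.sum(axis=1) >= min_total]
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    if len(keep) == 0:
        raise DegenerateInputError("all genes removed by expression filtering")
    kept = counts.counts.loc[counts.counts.index.isin(keep) |
                             counts.counts.index.isin(counts.spike_rows)]
    logger.info(
        "filter_low_expression(%s): kept %d / %d genes", mode, len(keep), genes.shape[0]
    )
    return CountMatrix(counts=kept, spike_rows=counts.spike_rows,
                       sample_info=counts.sample_info)


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    do_weighting: bool = True,
) -> float:
    """TMM factor of one sample against the reference (edgeR conventions).

    Gene-wise log ratios (M) are trimmed by 30%, average abundances (A)
    by 5%; the factor is 2 to the inverse-asymptotic-variance weighted
    mean of the surviving M values.
    """
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask].astype(float), ref[mask].astype(float)
    if obs.size == 0:
        return 1.0
    log_ratio = np.log2((obs / lib_obs) / (ref / lib_ref))
    abs_expr = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
    variance = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(log_ratio) & np.isfinite(abs_expr) & (abs_expr > -1e10)
    log_ratio, abs_expr, variance = log_ratio[finite], abs_expr[finite], variance[finite]
    if log_ratio.size == 0 or np.max(np.abs(log_ratio)) < 1e-6:
        return 1.0
    n = log_ratio.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_ratio)
    rank_a = stats.rankdata(abs_expr)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    if do_weighting:
        f = np.nansum(log_ratio[keep] / variance[keep]) / np.nansum(1.0 / variance[keep])
    else:
        f = np.nanmean(log_ratio[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_norm_factors(
    table: pd.DataFrame,
    lib_sizes: pd.Series,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    do_weighting: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values factors for a counts table with given library sizes.

    The reference sample is the one whose upper-quartile expression
    (counts over library size) is closest to the across-sample mean.
    Factors are centered to geometric mean 1.
    """
    lib = lib_sizes.loc[table.columns].astype(float)
    scaled = table.div(lib, axis=1)
    f75 = scaled.quantile(0.75, axis=0)
    if (f75 == 0).any():
        logger.warning("tmm_norm_factors: a sample has zero upper-quartile expression")
    ref = (f75 - f75.mean()).abs().idxmin()
    ref_col = table[ref].to_numpy()
    factors = pd.Series(
        {
            sample: _tmm_pair_factor(
                table[sample].to_numpy(), ref_col, lib[sample], lib[ref],
                logratio_trim=logratio_trim, sum_trim=sum_trim,
                do_weighting=do_weighting,
            )
            for sample in table.columns
        }
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def cnn_norm_factors(counts: CountMatrix) -> CnnFactors:
    """Spike-anchored CNN normalization factors.

    The TMM scheme is applied to the ERCC spike rows only, with library
    sizes fixed to the gene-count sums N.  A factor below 1 means the
    sample's spikes are under-represented — its cells carried more RNA.
    """
    if len(counts.samples) < 2:
        raise DegenerateInputError("CNN factors need at least 2 samples")
    spikes = counts.spike_counts
    if spikes.shape[0] == 0:
        raise DegenerateInputError("no spike rows flagged; CNN normalization impossible")
    totals = spikes.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise DegenerateInputError(f"sample {bad!r} has no spike counts")
    factors = tmm_norm_factors(spikes, counts.lib_sizes)
    logger.info("cnn_norm_factors: %s", dict(factors.round(4)))
    return CnnFactors(nf=factors, lib_sizes=counts.lib_sizes.astype(float))


def cnn_log_expression(
    counts: CountMatrix, factors: CnnFactors, prior: float = 0.5
) -> pd.DataFrame:
    """CNN log2 expression: log2((count + prior) / (N*nf + 1) * 1e6).

    Spike rows are excluded from the output.  Because the effective size
    N*nf tracks per-cell RNA content, global transcription shifts move
    these values where plain log-CPM stays put.
    """
    eff = factors.effective_sizes.loc[counts.samples]
    genes = counts.gene_counts
    return np.log2((genes + prior).div(eff + 1.0, axis=1) * 1e6)


# ---------------------------------------------------------------------------
# moderated t differential expression


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on the trigamma function (limma's algorithm)
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df1: float) -> tuple[float, float]:
    """Moment-match a scaled F distribution to gene-wise sample variances.

    Returns (df2, s0^2): the prior degrees of freedom and prior variance
    such that s2 ~ s0^2 * F(df1, df2).  df2 = inf when the variances are
    no more spread than chi-square sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.where(s2 <= 0, 1e-300, s2)
    z = np.log(s2)
    e = z - special.digamma(df1 / 2.0) + np.log(df1 / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df1 / 2.0)
    if e_var > 0:
        df2 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + special.digamma(df2 / 2.0) - np.log(df2 / 2.0))
    else:
        df2 = np.inf
        s0_sq = np.exp(e_mean)
    return float(df2), float(s0_sq)


def moderated_de(
    logexpr: pd.DataFrame,
    groups: Sequence[str],
    control: Optional[str] = None,
    weights: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
    lfc_threshold: float = 0.7,
    d0: Optional[float] = None,
) -> pd.DataFrame:
    """Two-group moderated-t differential expression on log expression.

    Per gene, the contrast (treated minus control means) is tested with
    residual variances shrunk toward a common prior by empirical Bayes:
    s2_post = (d0*s0^2 + d*s2)/(d0 + d), with (d0, s0) fitted by moment
    matching of the variance distribution and the moderated t referred to
    d0 + d degrees of freedom.  Passing ``d0=0`` disables moderation
    (ordinary equal-variance t).  Optional per-observation precision
    weights give a weighted fit.  Status applies the combined threshold:
    BH-adjusted p < ``alpha`` and |log2FC| > ``lfc_threshold``.
    """
    groups = pd.Series(list(groups), index=logexpr.columns)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if control is None:
        control = levels[0]
    treated = next(l for l in levels if l != control)
    cols_c = groups.index[groups == control]
    cols_t = groups.index[groups == treated]
    n_c, n_t = len(cols_c), len(cols_t)
    if n_c < 2 or n_t < 2:
        raise ValueError("need at least 2 samples per group")
    df_resid = n_c + n_t - 2
    if df_resid <= 0:
        raise DegenerateInputError("zero residual degrees of freedom")

    Y = logexpr.to_numpy(dtype=float)
    if weights is None:
        mean_t = logexpr[cols_t].mean(axis=1).to_numpy()
        mean_c = logexpr[cols_c].mean(axis=1).to_numpy()
        beta = mean_t - mean_c
        rss = (
            ((logexpr[cols_t].to_numpy() - mean_t[:, None]) ** 2).sum(axis=1)
            + ((logexpr[cols_c].to_numpy() - mean_c[:, None]) ** 2).sum(axis=1)
        )
        s2 = rss / df_resid
        var_unscaled = 1.0 / n_t + 1.0 / n_c
        var_unscaled = np.full(Y.shape[0], var_unscaled)
    else:
        W = weights.loc[logexpr.index, logexpr.columns].to_numpy(dtype=float)
        t_mask = logexpr.columns.isin(cols_t)
        beta = np.empty(Y.shape[0])
        s2 = np.empty(Y.shape[0])
        var_unscaled = np.empty(Y.shape[0])
        for g in range(Y.shape[0]):
            w = W[g]
            wt, wc = w[t_mask], w[~t_mask]
            yt, yc = Y[g, t_mask], Y[g, ~t_mask]
            mt = np.average(yt, weights=wt)
            mc = np.average(yc, weights=wc)
            beta[g] = mt - mc
            rss = (wt * (yt - mt) ** 2).sum() + (wc * (yc - mc) ** 2).sum()
            s2[g] = rss / df_resid
            var_unscaled[g] = 1.0 / wt.sum() + 1.0 / wc.sum()

    if d0 is None:
        d0, s0_sq = fit_f_dist(s2, df_resid)
    else:
        s0_sq = float(np.median(s2)) if d0 > 0 else 0.0
    if np.isfinite(d0) and d0 > 0:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    elif d0 == 0:
        s2_post = s2
        df_total = df_resid
    else:  # infinite prior df: all variances shrunk to the common value
        s2_post = np.full_like(s2, s0_sq)
        df_total = 1e9
    tstat = beta / np.sqrt(s2_post * var_unscaled)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    status = np.where(
        (padj < alpha) & (beta > lfc_threshold), "up",
        np.where((padj < alpha) & (beta < -lfc_threshold), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "log2FC": beta,
            "t": tstat,
            "pvalue": pvals,
            "padj": padj,
            "status": status,
        },
        index=logexpr.index,
    )
    logger.info(
        "moderated_de: %d genes, d0=%.3g, %d up / %d down",
        table.shape[0], d0, (status == "up").sum(), (status == "down").sum(),
    )
    return table


def voom_weights(
    counts: CountMatrix, factors: CnnFactors, span: float = 0.5
) -> pd.DataFrame:
    """Mean-variance-trend precision weights (voom-style), optional for moderated_de.

    Fits a lowess trend of per-gene residual sqrt-standard-deviation on
    average log count, then assigns each observation the inverse squared
    trend value at its fitted log count.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    eff = factors.effective_sizes.loc[counts.samples].to_numpy()
    genes = counts.gene_counts.to_numpy(dtype=float)
    logcpm = np.log2((genes + 0.5) / (eff + 1.0) * 1e6)
    mean_log_count = logcpm.mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    resid_sd = np.sqrt(logcpm.var(axis=1, ddof=1))
    fit = lowess(np.sqrt(resid_sd), mean_log_count, frac=span, return_sorted=True)
    fitted_count = mean_log_count[:, None] + np.log2(eff + 1.0)[None, :] - \
        np.mean(np.log2(eff + 1.0))
    interp = np.interp(fitted_count, fit[:, 0], fit[:, 1])
    weights = 1.0 / np.maximum(interp, 1e-6) ** 4
    return pd.DataFrame(weights, index=counts.gene_counts.index, columns=counts.samples)


# ---------------------------------------------------------------------------
# global-shift summary


def global_shift(
    logexpr: pd.DataFrame,
    treated: Sequence[str],
    control: Sequence[str],
) -> dict:
    """Genome-wide fold-change distribution between two sample sets.

    Per gene, log2FC = mean(treated) - mean(control) on the CNN log
    scale.  The summary gives boxplot statistics (median, quartile
    hinges, +/-1.5*IQR whiskers) and a two-sided Wilcoxon rank-sum test
    of the fold-change list against zero-centered control-vs-control
    fold-changes (the null spread of the same contrast).
    """
    treated, control = list(treated), list(control)
    t_set, c_set = set(treated), set(control)
    if not treated or not control:
        raise ValueError("both sample sets must be non-empty")
    if (t_set & c_set) and t_set != c_set:
        raise ValueError("treated and control sample sets overlap")
    fc = logexpr[treated].mean(axis=1) - logexpr[control].mean(axis=1)
    q1, med, q3 = np.percentile(fc, [25, 50, 75])
    iqr = q3 - q1
    if len(control) >= 2:
        half = len(control) // 2
        null_fc = (
            logexpr[control[:half]].mean(axis=1)
            - logexpr[control[half:]].mean(axis=1)
        )
        null_fc = null_fc - null_fc.median()
    else:
        null_fc = pd.Series(np.zeros(len(fc)), index=fc.index)
    stat, pvalue = stats.ranksums(fc, null_fc)
    return {
        "log2fc": fc,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
        "ranksum_stat": float(stat),
        "pvalue": float(pvalue),
    }


# ---------------------------------------------------------------------------
# negative-binomial two-group test and litter-matched overlap


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors; falls back to totals if no gene qualifies."""
    log_counts = np.log(counts.where(counts > 0))
    log_means = log_counts.mean(axis=1)
    usable = np.isfinite(log_means) & (counts > 0).all(axis=1)
    if usable.sum() >= 1:
        ratios = log_counts.loc[usable].sub(log_means.loc[usable], axis=0)
        sf = np.exp(ratios.median(axis=0))
    else:
        totals = counts.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals.where(totals > 0))))
    return sf / np.exp(np.mean(np.log(sf)))


def nb_two_group_test(
    counts: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    prior_df: float = 10.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Wald test of the group-2 vs group-1 log2 fold-change under an NB model.

    Counts are put on a common scale with median-of-ratios size factors.
    Per-gene dispersions come from method-of-moments estimates shrunk on
    the log scale toward a fitted mean-dispersion trend
    (alpha(mu) = a1/mu + a0), with ``prior_df`` pseudo-degrees of freedom
    on the trend.  The Wald statistic uses the delta-method standard
    error of the log-ratio of group means.
    """
    group1, group2 = list(group1), list(group2)
    sf = _size_factors(counts[group1 + group2])
    q = counts[group1 + group2].div(sf, axis=1)
    q1, q2 = q[group1], q[group2]
    n1, n2 = len(group1), len(group2)
    mu1 = q1.mean(axis=1).to_numpy()
    mu2 = q2.mean(axis=1).to_numpy()
    mu = q.mean(axis=1).to_numpy()

    # method-of-moments dispersion from pooled within-group variance
    df_within = (n1 - 1) + (n2 - 1)
    rss = ((q1.to_numpy() - mu1[:, None]) ** 2).sum(axis=1) + (
        (q2.to_numpy() - mu2[:, None]) ** 2
    ).sum(axis=1)
    s2 = rss / max(df_within, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_g = (s2 - mu) / mu**2
    alpha_g = np.where(np.isfinite(alpha_g), alpha_g, 0.0)

    # mean-dispersion trend alpha(mu) = a1/mu + a0, fitted to positive estimates
    pos = (alpha_g > 0) & (mu > 0)
    if pos.sum() >= 10:
        A = np.column_stack([1.0 / mu[pos], np.ones(pos.sum())])
        coef, *_ = np.linalg.lstsq(A, alpha_g[pos], rcond=None)
        a1, a0 = max(coef[0], 0.0), max(coef[1], 1e-8)
    else:
        a1, a0 = 0.0, max(np.median(alpha_g[alpha_g > 0]) if (alpha_g > 0).any() else 0.01, 1e-8)
    alpha_trend = a1 / np.maximum(mu, 1e-8) + a0
    alpha_floor = np.maximum(alpha_g, 1e-8)
    alpha = np.exp(
        (df_within * np.log(alpha_floor) + prior_df * np.log(alpha_trend))
        / (df_within + prior_df)
    )

    lfc = np.log2((mu2 + pseudocount) / (mu1 + pseudocount))
    var1 = (mu1 + alpha * mu1**2) / n1
    var2 = (mu2 + alpha * mu2**2) / n2
    ln2 = np.log(2.0)
    se = np.sqrt(
        var1 / np.maximum(mu1 + pseudocount, 1e-8) ** 2
        + var2 / np.maximum(mu2 + pseudocount, 1e-8) ** 2
    ) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, lfc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    pvals = np.where((mu1 == 0) & (mu2 == 0), 1.0, pvals)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "log2FC": lfc,
            "stat": wald,
            "pvalue": pvals,
            "padj": padj,
            "dispersion": alpha,
        },
        index=counts.index,
    )


def litter_matched_de(
    counts: CountMatrix,
    padj_cutoff: float = 0.1,
    condition_col: str = "condition",
    litter_col: str = "batch",
    treated_level: str = "mutant",
    control_level: str = "control",
) -> tuple[set[str], set[str], dict[str, pd.DataFrame]]:
    """Litter-by-litter differential expression with direction-consistent overlap.

    Within each litter, treated and control samples are compared with the
    NB Wald test; a gene enters the final up (down) set only when its
    adjusted p falls below ``padj_cutoff`` with a positive (negative)
    fold-change in *every* litter.  Direction-discordant genes are
    excluded.  Returns (up set, down set, per-litter tables).
    """
    info = counts.sample_info
    litters = list(pd.unique(info[litter_col]))
    if len(litters) < 2:
        raise ValueError("litter-matched DE needs at least 2 litters")
    tables: dict[str, pd.DataFrame] = {}
    up_sets, down_sets = [], []
    for litter in litters:
        members = info.index[info[litter_col] == litter]
        treated = [s for s in members if info.loc[s, condition_col] == treated_level]
        control = [s for s in members if info.loc[s, condition_col] == control_level]
        if not treated or not control:
            raise ValueError(f"litter {litter!r} is missing a condition group")
        table = nb_two_group_test(counts.gene_counts, control, treated)
        tables[str(litter)] = table
        sig = table["padj"] < padj_cutoff
        up_sets.append(set(table.index[sig & (table["log2FC"] > 0)]))
        down_sets.append(set(table.index[sig & (table["log2FC"] < 0)]))
    up = set.intersection(*up_sets)
    down = set.intersection(*down_sets)
    logger.info(
        "litter_matched_de: %d litters -> %d up, %d down", len(litters), len(up), len(down)
    )
    return up, down, tables
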