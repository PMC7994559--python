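"""End-to-end orchestration of the ChIP and RNA analysis pipelines.

Each pipeline runs its stages in the study's order, writes every
artifact as plain text beside a manifest recording the resolved
configuration, the normalization factors, and the seeds, and is
bit-reproducible given the same configuration.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import chip as chip_mod
from . import genesets as sets_mod
from . import rnaseq as rna_mod
from . import simulate as sim_mod
from .io import (
    GenomeIndex,
    dump_config,
    read_counts_table,
    write_bed,
    write_bedgraph,
    write_counts_table,
)

logger = logging.getLogger("spikequant")


class PipelineError(RuntimeError):
    """A stage failure, reported with the stage name and offending sample."""


CHIP_DEFAULTS = {
    "seed": 0,
    "simulate": {
        "n_bins": 2000,
        "bin_width": 10000,
        "depth": 200000,
        "n_replicates": 2,
        "r_global": 0.5,
        "spike_fraction": 0.05,
        "domain_spec": [[200, 30, 3.0], [900, 20, 4.0]],
    },
    "pseudocount": 0.5,
    "gap_bins": 3,
    "q_threshold": 0.05,
    "merge_distance": 3000,
    "min_hyper": 5.0,
    "max_hypo": 3.0,
    "log2_threshold": 0.7,
    "n_repeats": 50,
    "n_tss": 50,
    "promoter_upstream": 10000,
    "promoter_downstream": 1000,
}

RNA_DEFAULTS = {
    "seed": 0,
    "mode": "es",  # "es" or "embryo"
    "simulate": {
        "n_genes": 2000,
        "g_global": 2.0,
        "n_replicates": 3,
        "n_batches": 1,
        "batch_effect_sd": 0.0,
        "depth": 1000000,
        "dispersion": 0.05,
        "de_spec": [],
    },
    "cpm_threshold": 3.0,
    "min_total": 10,
    "alpha": 0.05,
    "lfc_threshold": 0.7,
    "litter_padj_cutoff": 0.1,
    "geneset_sizes": {"target": 200},
}


def _merged(defaults: dict, config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in defaults.items()}
    for key, value in (config or {}).items():
        if key not in cfg and key not in ("inputs",):
            raise KeyError(f"unknown config key {key!r}")
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def run_chip_pipeline(config: dict | None, outdir) -> Path:
    """NF -> scaling -> ECDF/KS -> domains -> repeats -> region counts -> PCA."""
    cfg = _merged(CHIP_DEFAULTS, config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if "inputs" in (config or {}):
            split_df = pd.read_csv(config["inputs"]["species_counts"], sep="\t")
            splits = [
                chip_mod.SpeciesSplitCounts(
                    sample=r["sample"], role=r["role"], condition=r["condition"],
                    replicate=int(r["replicate"]),
                    target_reads=int(r["target_reads"]),
                    spike_reads=int(r["spike_reads"]),
                )
                for _, r in split_df.iterrows()
            ]
            bin_matrix = chip_mod.read_bin_counts(config["inputs"]["bin_counts"])
            truth = None
            params = sim_mod.ChipSimParams(
                seed=int(cfg["seed"]),
                n_bins=len(bin_matrix.bins),
                bin_width=len(bin_matrix.bins[0]),
            )
        else:
            params = sim_mod.ChipSimParams(seed=int(cfg["seed"]), **cfg["simulate"])
            params.domain_spec = [tuple(d) for d in params.domain_spec]
            splits, bin_matrix, truth = sim_mod.simulate_chip_experiment(params)
            truth.save(out / "sim_truth.yaml")
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    by_sample = {s.sample: s for s in splits}
    ips = [s for s in splits if s.role == "IP"]

    stage = "normalization_factors"
    try:
        factors = []
        for ip in ips:
            input_name = ip.sample.replace("_IP", "_input")
            if input_name not in by_sample:
                raise PipelineError(
                    f"stage {stage}: missing matched input for sample {ip.sample!r}"
                )
            factors.append(chip_mod.compute_spikein_nf(ip, by_sample[input_name]))
        pd.DataFrame(
            [{"sample": f.sample, "nf": f.nf} for f in factors]
        ).to_csv(out / "factors.tsv", sep="\t", index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    ip_cols = [s.sample for s in ips]
    input_cols = [s.sample for s in splits if s.role == "input"]
    ip_bins = chip_mod.BinMatrix(
        bins=list(bin_matrix.bins), counts=bin_matrix.counts[ip_cols]
    )
    input_bins = chip_mod.BinMatrix(
        bins=list(bin_matrix.bins), counts=bin_matrix.counts[input_cols]
    )

    stage = "scaling"
    try:
        scaled_ip = chip_mod.scale_bin_counts(ip_bins, factors)
        write_bedgraph(scaled_ip, ip_cols[0], out / "scaled_signal.bedgraph")
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "ecdf_ks"
    try:
        conditions = sorted({s.condition for s in ips})
        dists = {}
        for cond in conditions:
            cond_ip = chip_mod.BinMatrix(
                bins=list(bin_matrix.bins),
                counts=scaled_ip.counts[[s.sample for s in ips if s.condition == cond]],
            )
            cond_input = chip_mod.BinMatrix(
                bins=list(bin_matrix.bins),
                counts=bin_matrix.counts[
                    [s.sample for s in splits
                     if s.role == "input" and s.condition == cond]
                ],
            )
            dists[cond] = chip_mod.enrichment_distribution(
                cond_ip, cond_input, pseudocount=cfg["pseudocount"], label=cond
            )
        ecdf_table = pd.DataFrame(
            {cond: pd.Series(d.values) for cond, d in dists.items()}
        )
        ecdf_table.to_csv(out / "ecdf_values.tsv", sep="\t", index=False)
        ks_rows = []
        for i, a in enumerate(conditions):
            for b in conditions[i + 1:]:
                D, p = chip_mod.ks_compare(dists[a], dists[b])
                ks_rows.append({"a": a, "b": b, "D": D, "pvalue": p})
        pd.DataFrame(ks_rows).to_csv(out / "ks_tests.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "broad_domains"
    try:
        per_rep_domains = []
        treated_ips = [s for s in ips if s.condition == conditions[-1]]
        for ip in treated_ips[:2]:
            rep_ip = chip_mod.BinMatrix(
                bins=list(bin_matrix.bins), counts=bin_matrix.counts[[ip.sample]]
            )
            rep_input = chip_mod.BinMatrix(
                bins=list(bin_matrix.bins),
                counts=bin_matrix.counts[[ip.sample.replace("_IP", "_input")]],
            )
            per_rep_domains.append(
                chip_mod.call_broad_domains(
                    rep_ip, rep_input,
                    gap_bins=cfg["gap_bins"], q_threshold=cfg["q_threshold"],
                )
            )
        if len(per_rep_domains) >= 2:
            domains = chip_mod.merge_and_intersect(
                per_rep_domains[0], per_rep_domains[1],
                merge_distance=cfg["merge_distance"],
            )
        else:
            domains = chip_mod.merge_intervals(
                per_rep_domains[0], cfg["merge_distance"]
            )
        write_bed(domains, out / "domains.bed")
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    genome = GenomeIndex({"chrS": params.n_bins * params.bin_width})
    tss, repeats, _ = sim_mod.simulate_annotations(
        genome, n_tss=cfg["n_tss"], n_repeats=cfg["n_repeats"], seed=int(cfg["seed"])
    )

    stage = "repeats"
    try:
        repeat_signal = chip_mod.region_counts(scaled_ip, repeats)
        cond_means = {}
        for cond in conditions:
            cols = [s.sample for s in ips if s.condition == cond]
            cond_means[cond] = repeat_signal[cols].mean(axis=1)
        high_cond, ctrl_cond = conditions[-1], conditions[0]
        calls, n_excluded = chip_mod.classify_repeat_elements(
            cond_means[high_cond], cond_means[ctrl_cond],
            elements=repeats, families=[iv.name for iv in repeats],
            min_hyper=cfg["min_hyper"], max_hypo=cfg["max_hypo"],
            log2_threshold=cfg["log2_threshold"],
        )
        pd.DataFrame(
            [
                {
                    "chrom": c.element.chrom, "start": c.element.start,
                    "end": c.element.end, "family": c.family,
                    "high": c.high_signal, "ctrl": c.ctrl_signal,
                    "log2_ratio": c.log2_ratio, "call": c.call,
                }
                for c in calls
            ]
        ).to_csv(out / "repeat_calls.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "region_counts"
    try:
        promoters = chip_mod.promoter_windows(
            tss, upstream=cfg["promoter_upstream"],
            downstream=cfg["promoter_downstream"], genome=genome,
        )
        promoter_table = chip_mod.region_counts(scaled_ip, promoters)
        write_counts_table(promoter_table, out / "promoter_counts.tsv", index_label="region")
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "pca"
    try:
        log_bins = chip_mod.BinMatrix(
            bins=list(bin_matrix.bins), counts=np.log2(scaled_ip.counts + 1.0)
        )
        coords, var = chip_mod.pca_embed(log_bins, n_components=2)
        coords["variance_explained_pc1"] = var[0]
        coords.to_csv(out / "pca_coordinates.tsv", sep="\t", index_label="sample")
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    manifest = {
        "pipeline": "chip",
        "config": _jsonable(cfg),
        "factors": {f.sample: float(f.nf) for f in factors},
        "seed": int(cfg["seed"]),
    }
    dump_config(manifest, out / "manifest.yaml")
    return out


def run_rna_pipeline(config: dict | None, outdir) -> Path:
    """filter -> CNN factors -> CNN matrix -> DE (or litter DE) -> global shift -> gene sets."""
    cfg = _merged(RNA_DEFAULTS, config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mode = cfg["mode"]

    stage = "simulate"
    try:
        if "inputs" in (config or {}):
            raw = read_counts_table(config["inputs"]["counts"], spike_prefix="ERCC-")
            sample_info = pd.read_csv(
                config["inputs"]["sample_sheet"], sep="\t", index_col=0
            )
            counts = rna_mod.CountMatrix(
                counts=raw.values, spike_rows=raw.spike_rows, sample_info=sample_info
            )
            truth = None
        else:
            sim_cfg = dict(cfg["simulate"])
            if mode == "embryo" and sim_cfg.get("n_batches", 1) < 2:
                sim_cfg["n_batches"] = 2
            params = sim_mod.RnaSimParams(seed=int(cfg["seed"]), **sim_cfg)
            params.de_spec = [tuple(d) for d in params.de_spec]
            counts, truth = sim_mod.simulate_rna_experiment(params)
            truth.save(out / "sim_truth.yaml")
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "filter"
    try:
        filtered = rna_mod.filter_low_expression(
            counts, cpm_threshold=cfg["cpm_threshold"], mode=mode,
            min_total=cfg["min_total"],
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "cnn_factors"
    try:
        factors = rna_mod.cnn_norm_factors(filtered)
        pd.DataFrame(
            {
                "nf": factors.nf,
                "lib_size": factors.lib_sizes,
                "effective_size": factors.effective_sizes,
            }
        ).to_csv(out / "cnn_factors.tsv", sep="\t", index_label="sample")
        logexpr = rna_mod.cnn_log_expression(filtered, factors)
        write_counts_table(logexpr, out / "cnn_log_expression.tsv", index_label="gene")
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    info = filtered.sample_info
    conditions = list(pd.unique(info["condition"]))
    control = "control" if "control" in conditions else conditions[0]
    treated = next(c for c in conditions if c != control)
    treated_samples = list(info.index[info["condition"] == treated])
    control_samples = list(info.index[info["condition"] == control])

    de_table = None
    if mode == "embryo":
        stage = "litter_de"
        try:
            up, down, tables = rna_mod.litter_matched_de(
                filtered, padj_cutoff=cfg["litter_padj_cutoff"],
                treated_level=treated, control_level=control,
            )
            for litter, table in tables.items():
                table.to_csv(out / f"de_{litter}.tsv", sep="\t", index_label="gene")
            pd.Series(sorted(up)).to_csv(
                out / "up_genes.txt", index=False, header=False
            )
            pd.Series(sorted(down)).to_csv(
                out / "down_genes.txt", index=False, header=False
            )
            up_genes = sorted(up)
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc
    else:
        stage = "moderated_de"
        try:
            de_table = rna_mod.moderated_de(
                logexpr, info["condition"], control=control,
                alpha=cfg["alpha"], lfc_threshold=cfg["lfc_threshold"],
            )
            de_table.to_csv(out / "de_table.tsv", sep="\t", index_label="gene")
            up_genes = sorted(de_table.index[de_table["status"] == "up"])
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "global_shift"
    try:
        shift = rna_mod.global_shift(logexpr, treated_samples, control_samples)
        pd.DataFrame(
            [{k: v for k, v in shift.items() if k != "log2fc"}]
        ).to_csv(out / "global_shift.tsv", sep="\t", index=False)
        shift["log2fc"].to_csv(out / "global_shift_fc.tsv", sep="\t",
                               index_label="gene", header=["log2FC"])
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "gene_sets"
    try:
        universe = sets_mod.GeneSet("expressed", list(logexpr.index))
        rng_sets = {
            name: sets_mod.random_subset(universe, min(size, len(universe)),
                                         seed=int(cfg["seed"]) + 1)
            for name, size in cfg["geneset_sizes"].items()
        }
        query = sets_mod.GeneSet("de_up", [g for g in up_genes if g in universe.members])
        if len(query) > 0:
            enrich = sets_mod.fisher_overlap(query, list(rng_sets.values()), universe)
            enrich.to_csv(out / "set_enrichment.tsv", sep="\t")
        else:
            pd.DataFrame().to_csv(out / "set_enrichment.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    manifest = {
        "pipeline": "rna",
        "mode": mode,
        "config": _jsonable(cfg),
        "factors": {s: float(v) for s, v in factors.nf.items()},
        "seed": int(cfg["seed"]),
    }
    dump_config(manifest, out / "manifest.yaml")
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
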