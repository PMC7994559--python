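"""Synthetic spike-in ChIP-seq and ERCC RNA-seq experiments with known truth.

The generators reproduce the measurement structure the normalizations
exploit: sequencing at fixed depth erases global per-cell differences,
but exogenous spike material — whose per-cell amount is constant across
conditions — competes for reads against the endogenous signal, so the
target:spike read split encodes the per-cell signal mass.

ChIP model: each IP sample carries target chromatin mass proportional to
``r_global`` (1 in the control condition) and constant spike mass; reads
are allocated binomially between genomes by mass and multinomially over
bins by the per-bin signal profile (a near-uniform chromatin background
shared with the matched input, times the domain enrichment multipliers).

RNA model: per-cell gene abundances are drawn once (log-normal), scaled
by ``g_global`` and gene-level effects in the treated condition; spike
abundances are constant per cell.  Libraries of exactly ``depth`` reads
are drawn from a gamma-perturbed multinomial, giving negative-binomial-
like overdispersion at the stated dispersion while conserving depth.
Batch offsets act multiplicatively on gene rows only — spikes are added
after lysis, so batch structure must not touch them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .chip import BinMatrix, SpeciesSplitCounts
from .io import GenomeIndex, Interval
from .rnaseq import CountMatrix


class ParameterError(ValueError):
    pass


@dataclass
class ChipSimParams:
    """Conditions of a simulated two-genome spike-in ChIP experiment."""

    n_bins: int = 5_000
    bin_width: int = 10_000
    n_spike_bins: int = 500
    domain_spec: list[tuple[int, int, float]] = field(default_factory=list)
    r_global: float = 1.0
    spike_fraction: float = 0.05
    depth: int = 1_000_000
    n_replicates: int = 2
    input_uniformity: bool = False
    input_roughness_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.spike_fraction < 1:
            raise ParameterError(
                f"spike_fraction must be in (0,1), got {self.spike_fraction}"
            )
        if self.r_global <= 0:
            raise ParameterError("r_global must be positive")
        if self.depth <= 0:
            raise ParameterError("depth must be positive")
        for start, n, mult in self.domain_spec:
            if start < 0 or start + n > self.n_bins:
                raise ParameterError(f"domain ({start},{n}) outside the genome")
            if mult <= 0:
                raise ParameterError("domain multiplier must be positive")


@dataclass
class RnaSimParams:
    """Conditions of a simulated ERCC-spiked RNA-seq experiment."""

    n_genes: int = 2_000
    n_spike_species: int = 92
    g_global: float = 1.0
    de_spec: list[tuple[int, float]] = field(default_factory=list)
    n_replicates: int = 3
    n_batches: int = 1
    batch_effect_sd: float = 0.0
    depth: int = 1_000_000
    dispersion: float = 0.05
    spike_fraction: float = 0.03
    abundance_sd: float = 1.0
    spike_abundance_sd: float = 2.0
    seed: int = 0
    profile_seed: Optional[int] = None  # fixes abundances/batch offsets independently

    def validate(self) -> None:
        if self.dispersion < 0:
            raise ParameterError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.g_global <= 0:
            raise ParameterError("g_global must be positive")
        for idx, _ in self.de_spec:
            if not 0 <= idx < self.n_genes:
                raise ParameterError(f"DE gene index {idx} outside gene universe")
        if not 0 < self.spike_fraction < 1:
            raise ParameterError("spike_fraction must be in (0,1)")


@dataclass
class SimTruth:
    """Ground-truth manifest of one simulation, sufficient to recompute expectations."""

    kind: str
    params: dict
    seed: int
    profiles: dict[str, list] = field(default_factory=dict)
    expected_split: dict[str, dict] = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "kind": self.kind,
                    "params": self.params,
                    "seed": self.seed,
                    "profiles": self.profiles,
                    "expected_split": self.expected_split,
                },
                fh, sort_keys=False,
            )

    @classmethod
    def load(cls, path) -> "SimTruth":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _child_rng(seed: int, index: int) -> np.random.Generator:
    # independent, reproducible per-sample stream derived from the master seed
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


# ---------------------------------------------------------------------------
# ChIP


def chip_signal_profile(params: ChipSimParams) -> np.ndarray:
    """Per-bin enrichment multipliers: background 1x, domain bins at their multiplier."""
    mult = np.ones(params.n_bins)
    for start, n, m in params.domain_spec:
        mult[start : start + n] *= m
    return mult


def simulate_chip_experiment(
    params: ChipSimParams,
) -> tuple[list[SpeciesSplitCounts], BinMatrix, SimTruth]:
    """Simulate a two-condition spike-in ChIP experiment.

    Returns the per-sample species-split totals (IP and input for each
    condition and replicate), the raw target-genome bin counts for all
    samples, and a :class:`SimTruth` manifest holding the realized
    per-sample background profiles and expected species splits.
    """
    params.validate()
    mult = chip_signal_profile(params)
    f = params.spike_fraction

    splits: list[SpeciesSplitCounts] = []
    columns: dict[str, np.ndarray] = {}
    profiles: dict[str, list] = {}
    expected_split: dict[str, dict] = {}

    sample_index = 0
    for condition, r in (("control", 1.0), ("treated", params.r_global)):
        for rep in range(1, params.n_replicates + 1):
            rng = _child_rng(params.seed, sample_index)
            sample_index += 1
            # chromatin background shared between the IP and its matched input
            if params.input_uniformity:
                background = np.ones(params.n_bins)
            else:
                background = np.exp(
                    rng.normal(0.0, params.input_roughness_sd, size=params.n_bins)
                )
            ip_profile = background * mult
            for role, prof, p_target in (
                ("IP", ip_profile, (r * (1 - f)) / (r * (1 - f) + f)),
                ("input", background, 1 - f),
            ):
                name = f"{condition}_rep{rep}_{role}"
                target_total = int(rng.binomial(params.depth, p_target))
                spike_total = params.depth - target_total
                bin_counts = rng.multinomial(target_total, prof / prof.sum())
                columns[name] = bin_counts
                splits.append(
                    SpeciesSplitCounts(
                        sample=name, role=role, condition=condition,
                        replicate=rep, target_reads=target_total,
                        spike_reads=spike_total,
                    )
                )
                profiles[name] = [float(x) for x in prof]
                expected_split[name] = {
                    "p_target": float(p_target),
                    "expected_target": float(params.depth * p_target),
                    "expected_spike": float(params.depth * (1 - p_target)),
                }

    genome = GenomeIndex({"chrS": params.n_bins * params.bin_width})
    bins = [
        Interval("chrS", i * params.bin_width, (i + 1) * params.bin_width)
        for i in range(params.n_bins)
    ]
    counts = pd.DataFrame(columns, index=range(params.n_bins))
    truth = SimTruth(
        kind="chip",
        params={**asdict(params), "genome": dict(genome.sizes)},
        seed=params.seed,
        profiles=profiles,
        expected_split=expected_split,
    )
    return splits, BinMatrix(bins=bins, counts=counts), truth


def expected_chip_bin_counts(truth: SimTruth, sample: str) -> np.ndarray:
    """Exact per-bin expected counts for a simulated ChIP sample (no sampling)."""
    prof = np.asarray(truth.profiles[sample], dtype=float)
    expected_target = truth.expected_split[sample]["expected_target"]
    return expected_target * prof / prof.sum()


# ---------------------------------------------------------------------------
# RNA


def _rna_abundances(params: RnaSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Base per-cell gene and spike abundances, drawn once from the master seed."""
    entropy = params.seed if params.profile_seed is None else params.profile_seed
    rng = np.random.default_rng(np.random.SeedSequence(entropy=entropy,
                                                       spawn_key=(10_000,)))
    genes = rng.lognormal(mean=0.0, sigma=params.abundance_sd, size=params.n_genes)
    spikes = rng.lognormal(
        mean=0.0, sigma=params.spike_abundance_sd, size=params.n_spike_species
    )
    # scale total spike mass to the stated fraction of the control transcriptome
    target_spike_mass = params.spike_fraction / (1 - params.spike_fraction) * genes.sum()
    spikes *= target_spike_mass / spikes.sum()
    return genes, spikes


def simulate_rna_experiment(params: RnaSimParams) -> tuple[CountMatrix, SimTruth]:
    """Simulate an ERCC-spiked two-condition RNA-seq experiment.

    Treated-condition gene abundances are the control abundances times
    ``g_global`` and any gene-level DE effects; spike abundances are
    identical per cell in both conditions.  Each library holds exactly
    ``depth`` reads, drawn from a gamma-perturbed multinomial whose
    marginals have negative-binomial dispersion ``params.dispersion``.
    """
    params.validate()
    base_genes, spikes = _rna_abundances(params)
    de_effect = np.zeros(params.n_genes)
    for idx, lfc in params.de_spec:
        de_effect[idx] += lfc

    gene_ids = [f"gene{i:05d}" for i in range(params.n_genes)]
    spike_ids = [f"ERCC-{i:05d}" for i in range(params.n_spike_species)]

    columns: dict[str, np.ndarray] = {}
    info_rows = []
    expected: dict[str, dict] = {}
    profiles: dict[str, list] = {}

    rng_batch = np.random.default_rng(
        np.random.SeedSequence(
            entropy=params.seed if params.profile_seed is None else params.profile_seed,
            spawn_key=(20_000,),
        )
    )
    batch_offsets = rng_batch.normal(
        0.0, params.batch_effect_sd, size=(params.n_batches, params.n_genes)
    ) if params.batch_effect_sd > 0 else np.zeros((params.n_batches, params.n_genes))

    sample_index = 0
    for condition, scale in (("control", 1.0), ("treated", params.g_global)):
        for rep in range(1, params.n_replicates + 1):
            batch = rep % params.n_batches if params.n_batches > 1 else 0
            name = f"{condition}_rep{rep}"
            rng = _child_rng(params.seed, 30_000 + sample_index)
            sample_index += 1
            gene_mass = (
                base_genes * scale * np.exp2(de_effect * (condition == "treated"))
                * np.exp2(batch_offsets[batch])
            )
            mass = np.concatenate([gene_mass, spikes])
            p = mass / mass.sum()
            if params.dispersion > 0:
                shape = 1.0 / params.dispersion
                gamma = rng.gamma(shape, scale=1.0 / shape, size=p.size)
                p = p * gamma
                p = p / p.sum()
            counts = rng.multinomial(params.depth, p)
            columns[name] = counts
            info_rows.append(
                {"sample": name, "condition": condition, "batch": f"batch{batch}",
                 "replicate": rep}
            )
            expected[name] = {
                "gene_mass_total": float(gene_mass.sum()),
                "spike_mass_total": float(spikes.sum()),
                "expected_spike_share": float(spikes.sum() / mass.sum()),
            }
            profiles[name] = [float(x) for x in mass]

    counts_df = pd.DataFrame(columns, index=gene_ids + spike_ids)
    sample_info = pd.DataFrame(info_rows).set_index("sample")
    truth = SimTruth(
        kind="rna",
        params=asdict(params),
        seed=params.seed,
        profiles=profiles,
        expected_split=expected,
    )
    matrix = CountMatrix(
        counts=counts_df, spike_rows=pd.Index(spike_ids), sample_info=sample_info
    )
    return matrix, truth


def expected_rna_counts(truth: SimTruth, sample: str) -> np.ndarray:
    """Exact per-row expected counts for a simulated RNA sample (no sampling)."""
    mass = np.asarray(truth.profiles[sample], dtype=float)
    depth = truth.params["depth"]
    return depth * mass / mass.sum()


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(
    genome: GenomeIndex,
    n_tss: int = 100,
    n_repeats: int = 50,
    gene_sets: Optional[dict[str, int]] = None,
    seed: int = 0,
    universe: Optional[Sequence[str]] = None,
) -> tuple[list[Interval], list[Interval], dict[str, set[str]]]:
    """Random TSS records, non-overlapping repeat elements, and gene sets.

    TSSs are single-base, strand-labelled records named after the gene
    universe; repeats are disjoint intervals of 200-2000 bp; gene sets
    are uniform draws from the universe (by default the TSS gene names).
    """
    if not genome.sizes:
        raise ParameterError("genome is empty")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    chroms = genome.chroms
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    if n_tss > genome.total_length:
        raise ParameterError("more TSSs requested than bases in the genome")
    tss: list[Interval] = []
    for i in range(n_tss):
        c = chroms[rng.choice(len(chroms), p=probs)]
        pos = int(rng.integers(0, genome[c]))
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(Interval(c, pos, pos + 1, name=f"gene{i:05d}", strand=strand))

    repeats: list[Interval] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(repeats) < n_repeats:
        attempts += 1
        if attempts > 50 * n_repeats + 100:
            raise ParameterError("cannot place requested repeats without overlap")
        c = chroms[rng.choice(len(chroms), p=probs)]
        width = int(rng.integers(200, 2001))
        if genome[c] <= width:
            continue
        start = int(rng.integers(0, genome[c] - width))
        end = start + width
        if any(start < e and s < end for s, e in occupied[c]):
            continue
        occupied[c].append((start, end))
        family = f"RepFam{int(rng.integers(1, 6))}"
        repeats.append(Interval(c, start, end, name=family))
    repeats.sort(key=lambda iv: (iv.chrom, iv.start))

    members = list(universe) if universe is not None else [iv.name for iv in tss]
    sets: dict[str, set[str]] = {}
    for set_name, size in (gene_sets or {}).items():
        if size > len(members):
            raise ParameterError(
                f"gene set {set_name!r} requests {size} of {len(members)} genes"
            )
        chosen = rng.choice(len(members), size=size, replace=False)
        sets[set_name] = {members[i] for i in chosen}
    return tss, repeats, sets
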