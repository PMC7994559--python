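"""Readers and writers for the plain-text genomic formats the pipeline touches.

All coordinates are 0-based half-open internally; conversion (there is none
for BED/bedGraph, which share that convention) happens only at I/O
boundaries.  Count matrices are dense TSV — every table in this pipeline is
small enough for a DataFrame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

logger = logging.getLogger("spikequant")

VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """A malformed record in an input file, reported with its line number."""


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeIndex:
    """Ordered chromosome-name -> length map (a chrom.sizes file)."""

    sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    @property
    def total_length(self) -> int:
        return sum(self.sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]


@dataclass
class TableHandle:
    """A dense counts table (rows x samples) with optional spike-row flags."""

    values: pd.DataFrame
    spike_rows: pd.Index = field(default_factory=lambda: pd.Index([]))

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_bed(path, expected_columns: Optional[int] = None) -> list[Interval]:
    """Read a BED3-BED6 file into a list of intervals, in file order.

    ``track`` and ``browser`` header lines are skipped.  Malformed lines
    raise :class:`FormatError` naming the offending line.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if expected_columns is not None and len(fields) != expected_columns:
                raise FormatError(
                    f"{path}:{lineno}: expected {expected_columns} columns, "
                    f"got {len(fields)}"
                )
            if not 3 <= len(fields) <= 6:
                raise FormatError(f"{path}:{lineno}: expected 3-6 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            try:
                intervals.append(
                    Interval(fields[0], start, end, name=name, score=score, strand=strand)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    logger.info("read_bed: %d intervals from %s", len(intervals), path)
    return intervals


def write_bed(intervals: Iterable[Interval], path) -> None:
    """Write intervals as BED6 (BED3 when no interval carries name/strand)."""
    intervals = list(intervals)
    six = any(iv.name is not None or iv.strand != "." or iv.score is not None
              for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            if six:
                score = 0.0 if iv.score is None else iv.score
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path) -> GenomeIndex:
    """Read a two-column chrom.sizes file; duplicates and non-positive lengths rejected."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            chrom, length_s = fields
            try:
                length = int(length_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer length") from exc
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length {length}")
            if chrom in sizes:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            sizes[chrom] = length
    return GenomeIndex(sizes)


def write_chrom_sizes(genome: GenomeIndex, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_counts_table(path, spike_prefix: Optional[str] = None) -> TableHandle:
    """Read a genes-x-samples TSV counts table.

    The first column holds row identifiers; the header row holds sample
    names.  Rows whose identifier starts with ``spike_prefix`` (e.g.
    ``"ERCC-"``) are flagged as spike rows.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or unparsable table: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cells in counts table")
    if not df.index.is_unique:
        raise FormatError(f"{path}: duplicate row identifiers")
    if (df.to_numpy() < 0).any():
        bad = df.index[(df < 0).any(axis=1)][0]
        raise FormatError(f"{path}: negative count in row {bad!r}")
    spike_rows = pd.Index([])
    if spike_prefix is not None:
        spike_rows = df.index[df.index.astype(str).str.startswith(spike_prefix)]
    logger.info(
        "read_counts_table: %d rows x %d samples from %s (%d spike rows)",
        df.shape[0], df.shape[1], path, len(spike_rows),
    )
    return TableHandle(values=df, spike_rows=spike_rows)


def write_counts_table(table: pd.DataFrame, path, index_label: str = "id") -> None:
    table.to_csv(path, sep="\t", index_label=index_label)


def write_bedgraph(bins, sample: str, path) -> None:
    """Write one sample of a :class:`~spikequant.chip.BinMatrix` as 4-column bedGraph.

    Values are the (scaled) per-bin signal, formatted with 6-decimal
    round-trip fidelity.  No track header is emitted.
    """
    if sample not in bins.counts.columns:
        raise KeyError(f"unknown sample {sample!r}")
    values = bins.counts[sample].to_numpy()
    with open(path, "w") as fh:
        for iv, value in zip(bins.bins, values):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:.6g}\n")


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return records


def load_config(path) -> dict:
    """Load a nested key-value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
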