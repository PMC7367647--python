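"""Per-bin raw coverage for one sample: counting from alignments, count-table
round-trips, QC against the minimum-depth requirement, and optional GC
correction.

A fragment is counted once, at the leftmost mapped coordinate of read 1
(or of the read itself for unpaired data). With ~300 bp cfDNA fragments
against 200 kb bins the choice of anchor is numerically negligible, but it
is fixed so counts are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinGrid

logger = logging.getLogger(__name__)

__all__ = [
    "RawCoverageProfile",
    "QCReport",
    "ReadFilters",
    "count_reads_per_bin",
    "load_counts_table",
    "write_counts_table",
    "gc_correct",
    "qc_profile",
    "MIN_READS_DEFAULT",
]

#: minimum usable fragments per sample for screening-grade depth
MIN_READS_DEFAULT = 10_000_000


@dataclass
class ReadFilters:
    min_mapq: int = 30
    dedup: bool = True
    proper_pair: bool = True


@dataclass
class RawCoverageProfile:
    """Per-bin fragment counts and relative coverage for one sample.

    ``relative_coverage`` is counts / total usable fragments, so it sums to
    one and is invariant under uniform depth scaling; it is the coverage
    unit used by the reference-panel Z-score transform.
    """

    sample_id: str
    grid: BinGrid
    counts: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"counts length {self.counts.shape} != grid bins {self.grid.n_bins}")
        if np.any(self.counts < 0):
            raise ValueError("negative bin counts")

    @property
    def total_reads(self) -> float:
        return float(self.counts.sum())

    @property
    def relative_coverage(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts)
        return self.counts / total


@dataclass(frozen=True)
class QCReport:
    total_reads: float
    pass_min_reads: bool
    fraction_nonzero_bins: float
    flags: tuple[str, ...] = ()


def count_reads_per_bin(
    alignment_source,
    grid: BinGrid,
    filters: ReadFilters | None = None,
    sample_id: str | None = None,
) -> RawCoverageProfile:
    """Count usable fragments per grid bin from a SAM/BAM/CRAM file.

    Each passing read-1 (or unpaired read) increments exactly one bin, by
    its leftmost mapped coordinate. Reads on chromosomes absent from the
    grid are discarded and their count logged and recorded in metadata.
    Raises if the alignment header disagrees with the grid's build on the
    length of any shared chromosome.
    """
    import pysam

    filters = filters or ReadFilters()
    path = str(alignment_source)
    mode = "r" if path.endswith(".sam") else "rb"
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    discarded_chrom = 0
    filtered = 0
    with pysam.AlignmentFile(path, mode) as af:
        header_len = {sq["SN"]: sq["LN"] for sq in af.header.get("SQ", [])}
        shared = [c for c in grid.build.names if c in header_len]
        if not shared:
            raise ValueError(
                f"no grid chromosome found in alignment header; grid has "
                f"{list(grid.build.names)[:5]}..., header has "
                f"{list(header_len)[:5]}...")
        bad = [c for c in shared if header_len[c] != grid.build.length(c)]
        if bad:
            raise ValueError(
                f"chromosome length mismatch between grid build and alignment "
                f"header for: {bad}")
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if filters.dedup and read.is_duplicate:
                continue
            if read.mapping_quality < filters.min_mapq:
                filtered += 1
                continue
            if read.is_paired:
                if filters.proper_pair and not read.is_proper_pair:
                    filtered += 1
                    continue
                if read.is_read2:
                    continue  # count each fragment once
            chrom = read.reference_name
            try:
                ordinal = grid.locate(chrom, read.reference_start)
            except (KeyError, ValueError):
                discarded_chrom += 1
                continue
            counts[ordinal] += 1
    if discarded_chrom:
        logger.info("discarded %d reads on chromosomes outside the grid",
                    discarded_chrom)
    sid = sample_id or Path(path).stem
    return RawCoverageProfile(
        sample_id=sid, grid=grid, counts=counts,
        metadata={"discarded_offgrid": discarded_chrom,
                  "filtered": filtered,
                  "filters": vars(filters).copy(),
                  "source": path})


_COUNTS_COLUMNS = ["chrom", "start", "end", "count"]


def write_counts_table(profile: RawCoverageProfile, path: str | Path) -> None:
    """Write the per-bin counts TSV (chrom/start/end/count, 0-based half-open)."""
    df = pd.DataFrame({
        "chrom": profile.grid.bin_chrom,
        "start": profile.grid.start,
        "end": profile.grid.end,
        "count": profile.counts,
    })
    df.to_csv(path, sep="\t", index=False)


def load_counts_table(path: str | Path, grid: BinGrid) -> RawCoverageProfile:
    """Read a counts TSV; every grid bin must appear exactly once, in any order."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _COUNTS_COLUMNS:
        raise ValueError(f"{path}: expected columns {_COUNTS_COLUMNS}, got {list(df.columns)}")
    counts = np.full(grid.n_bins, -1.0)
    for chrom, start, end, count in df.itertuples(index=False):
        try:
            ordinal = grid.locate(str(chrom), int(start))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: row {chrom}:{start}-{end} outside grid") from exc
        if grid.start[ordinal] != start or grid.end[ordinal] != end:
            raise ValueError(
                f"{path}: row {chrom}:{start}-{end} does not match grid bin "
                f"{grid.interval(ordinal)}")
        if counts[ordinal] >= 0:
            raise ValueError(f"{path}: duplicate bin {chrom}:{start}-{end}")
        counts[ordinal] = count
    missing = np.flatnonzero(counts < 0)
    if missing.size:
        raise ValueError(
            f"{path}: missing {missing.size} bins, first: {grid.interval(int(missing[0]))}")
    return RawCoverageProfile(sample_id=Path(path).stem, grid=grid, counts=counts)


def gc_correct(
    profile: RawCoverageProfile,
    gc_per_bin: np.ndarray,
    enabled: bool = False,
    lowess_frac: float = 0.3,
) -> RawCoverageProfile:
    """Optionally remove a smooth coverage-vs-GC trend.

    Disabled by default — the reference workflow applies none, and the
    control-panel Z-score already absorbs bin-wise bias shared between
    samples and controls. When enabled, each bin is divided by a LOWESS
    trend of coverage against GC fraction, then rescaled so the total is
    preserved.
    """
    if not enabled:
        return profile
    gc = np.asarray(gc_per_bin, dtype=float)
    if gc.shape != (profile.grid.n_bins,):
        raise ValueError("gc_per_bin length does not match grid")
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("gc_per_bin must lie in [0, 1]")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    counts = profile.counts.astype(float)
    usable = counts > 0
    if usable.sum() < 10:
        return profile
    if np.ptp(gc[usable]) < 1e-6:
        return profile  # constant GC: the trend is flat, correction is a no-op
    trend = lowess(counts[usable], gc[usable], frac=lowess_frac,
                   return_sorted=False)
    trend = np.clip(trend, np.median(trend) * 1e-3, None)
    corrected = counts.copy()
    corrected[usable] = counts[usable] / trend * trend.mean()
    corrected *= counts.sum() / corrected.sum()
    meta = dict(profile.metadata, gc_corrected=True)
    return RawCoverageProfile(profile.sample_id, profile.grid, corrected, meta)


def qc_profile(profile: RawCoverageProfile,
               min_reads: float = MIN_READS_DEFAULT) -> QCReport:
    """Depth and sanity QC; screening-grade samples need >= ``min_reads``."""
    total = profile.total_reads
    flags = []
    if total == 0:
        flags.append("empty")
    nonzero = float(np.mean(profile.counts > 0)) if profile.grid.n_bins else 0.0
    if total > 0 and nonzero < 0.5:
        flags.append("sparse")
    passing = total >= min_reads
    if not passing:
        flags.append("low_depth")
    return QCReport(total_reads=total, pass_min_reads=passing,
                    fraction_nonzero_bins=nonzero, flags=tuple(flags))
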