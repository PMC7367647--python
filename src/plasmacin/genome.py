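"""Genomic coordinate frame: genome build, fixed-width bin grid, and the
packaged 29-segment liver-cancer copy-number panel.

All coordinates are 0-based, half-open (``[start, end)``), including the
packaged panel and every on-disk dialect written by this package.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBuild",
    "GenomicInterval",
    "BinGrid",
    "PanelSegment",
    "make_bin_grid",
    "load_panel",
    "panel_to_bed",
    "bins_in_interval",
    "DEFAULT_BIN_SIZE",
]

DEFAULT_BIN_SIZE = 200_000

_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


def _data_path(name: str):
    return resources.files("plasmacin.data").joinpath(name)


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with lengths.

    ``require_autosomes`` enforces presence of chr1..chr22 (the screening
    frame); toy builds used in tests and simulations may switch it off.
    """

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    require_autosomes: bool = False

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names in build")
        if not self.chromosomes:
            raise ValueError("empty genome build")
        for c, ln in self.chromosomes:
            if ln <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {ln}")
        if self.require_autosomes:
            missing = [c for c in _AUTOSOMES if c not in names]
            if missing:
                raise ValueError(f"build {self.name!r} missing autosomes: {missing}")

    @classmethod
    def from_dict(cls, name: str, sizes: dict[str, int], **kw) -> "GenomeBuild":
        return cls(name, tuple(sizes.items()), **kw)

    @classmethod
    def hg19(cls, include_sex: bool = False) -> "GenomeBuild":
        """The packaged hg19 build (autosomes; optionally chrX/chrY)."""
        rows = []
        with _data_path("hg19.chrom.sizes").open() as fh:
            for line in fh:
                chrom, ln = line.split()
                rows.append((chrom, int(ln)))
        if not include_sex:
            rows = [r for r in rows if r[0] not in ("chrX", "chrY")]
        return cls("hg19", tuple(rows), require_autosomes=True)

    @classmethod
    def hg19_subset(cls, chroms: Sequence[str]) -> "GenomeBuild":
        """hg19 restricted to the given chromosomes (analysis speed-ups)."""
        full = dict(cls.hg19(include_sex=True).chromosomes)
        unknown = [c for c in chroms if c not in full]
        if unknown:
            raise KeyError(f"not in hg19: {unknown}")
        return cls("hg19-subset", tuple((c, full[c]) for c in chroms))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for c, ln in self.chromosomes:
            if c == chrom:
                return ln
        raise KeyError(f"unknown chromosome {chrom!r} in build {self.name!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class BinGrid:
    """Fixed-width tiling of a genome build; the coordinate frame for all
    per-bin vectors downstream.

    Bins tile each chromosome left to right; every bin has length
    ``bin_size`` except possibly the last per chromosome (the remainder).
    Global bin ordinals are contiguous in build chromosome order.
    """

    def __init__(self, build: GenomeBuild, bin_size: int = DEFAULT_BIN_SIZE):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.build = build
        self.bin_size = int(bin_size)
        starts, ends, chrom_idx = [], [], []
        self._chrom_bounds: dict[str, tuple[int, int]] = {}
        ordinal = 0
        for ci, (chrom, ln) in enumerate(build.chromosomes):
            n = -(-ln // bin_size)  # ceil division
            s = np.arange(n, dtype=np.int64) * bin_size
            e = np.minimum(s + bin_size, ln)
            starts.append(s)
            ends.append(e)
            chrom_idx.append(np.full(n, ci, dtype=np.int32))
            self._chrom_bounds[chrom] = (ordinal, ordinal + n)
            ordinal += n
        self.start = np.concatenate(starts)
        self.end = np.concatenate(ends)
        self.chrom_index = np.concatenate(chrom_idx)
        self._chrom_names = build.names

    @property
    def n_bins(self) -> int:
        return len(self.start)

    def __len__(self) -> int:
        return self.n_bins

    @property
    def bin_chrom(self) -> np.ndarray:
        """Per-bin chromosome name array."""
        return np.asarray(self._chrom_names, dtype=object)[self.chrom_index]

    @property
    def midpoints(self) -> np.ndarray:
        return (self.start + self.end) / 2.0

    def chrom_range(self, chrom: str) -> range:
        """Global ordinals of all bins on one chromosome."""
        if chrom not in self._chrom_bounds:
            raise KeyError(f"unknown chromosome {chrom!r}")
        lo, hi = self._chrom_bounds[chrom]
        return range(lo, hi)

    def locate(self, chrom: str, pos: int) -> int:
        """Ordinal of the bin containing position ``pos`` on ``chrom``."""
        lo, hi = self._chrom_bounds.get(chrom, (None, None))
        if lo is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.build.length(chrom)):
            raise ValueError(f"position {pos} outside {chrom}")
        return lo + pos // self.bin_size

    def interval(self, ordinal: int) -> GenomicInterval:
        return GenomicInterval(
            self._chrom_names[self.chrom_index[ordinal]],
            int(self.start[ordinal]),
            int(self.end[ordinal]),
        )

    def bins_in_interval(self, interval: GenomicInterval) -> range:
        """Contiguous ordinal range of bins whose midpoint lies in
        ``[start, end)``; may be empty.

        Midpoint membership means an interval boundary falling inside a bin
        never double-counts that bin between adjacent intervals.
        """
        lo, hi = self._chrom_bounds.get(interval.chrom, (None, None))
        if lo is None:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        mids = self.midpoints[lo:hi]
        inside = np.flatnonzero((mids >= interval.start) & (mids < interval.end))
        if inside.size == 0:
            return range(lo, lo)
        return range(lo + int(inside[0]), lo + int(inside[-1]) + 1)

    def fingerprint(self) -> str:
        """Stable hash of (build, bin size) for provenance headers."""
        h = hashlib.md5()
        h.update(self.build.name.encode())
        h.update(str(self.bin_size).encode())
        for c, ln in self.build.chromosomes:
            h.update(f"{c}:{ln};".encode())
        return h.hexdigest()[:12]

    def same_frame(self, other: "BinGrid") -> bool:
        return self.fingerprint() == other.fingerprint()


def make_bin_grid(build: GenomeBuild, bin_size: int = DEFAULT_BIN_SIZE) -> BinGrid:
    """Tile ``build`` into fixed ``bin_size`` windows (default 200 kb)."""
    return BinGrid(build, bin_size)


def bins_in_interval(grid: BinGrid, interval: GenomicInterval) -> range:
    return grid.bins_in_interval(interval)


@dataclass(frozen=True)
class PanelSegment:
    """One recurrently altered genomic segment of a screening panel.

    ``direction`` records whether the segment is recurrently gained or lost;
    discovery statistics (cohort frequency, mean normalized coverage,
    log10 p) are carried as annotation only — screening uses the sample's
    own aggregated Z against the cutoff.
    """

    name: str
    interval: GenomicInterval
    direction: str  # "gain" | "loss"
    key_genes: tuple[str, ...] = ()
    discovery_frequency: float | None = None
    discovery_seg_mean: float | None = None
    discovery_logP: float | None = None

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"segment {self.name}: bad direction {self.direction!r}")
        suffix = self.name[-1]
        if suffix in "+-":
            if (suffix == "+") != (self.direction == "gain"):
                raise ValueError(
                    f"segment {self.name}: direction {self.direction} inconsistent "
                    f"with name suffix {suffix!r}"
                )


_PANEL_COLUMNS = [
    "name", "chrom", "loc.start", "loc.end", "direction",
    "key_genes", "frequency", "seg_mean", "logP",
]


def load_panel(source: str | Path | None = None) -> list[PanelSegment]:
    """Load a segment panel from a TSV, or the packaged 29-segment
    liver-cancer panel when ``source`` is None.

    The TSV dialect has a header and columns name, chrom, loc.start,
    loc.end, direction, key_genes, frequency, seg_mean, logP; key_genes
    is a comma-separated list and may be empty.
    """
    if source is None:
        with _data_path("liver_panel.tsv").open() as fh:
            return _parse_panel(fh, "<packaged liver panel>")
    with open(source) as fh:
        return _parse_panel(fh, str(source))


def _parse_panel(fh, origin: str) -> list[PanelSegment]:
    header = fh.readline().rstrip("\n").split("\t")
    if header != _PANEL_COLUMNS:
        raise ValueError(f"{origin}: bad panel header {header}")
    segments = []
    for lineno, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(_PANEL_COLUMNS):
            raise ValueError(f"{origin}: line {lineno}: expected "
                             f"{len(_PANEL_COLUMNS)} fields, got {len(fields)}")
        try:
            name, chrom = fields[0], fields[1]
            interval = GenomicInterval(chrom, int(fields[2]), int(fields[3]))
            genes = tuple(g for g in fields[5].split(",") if g)
            seg = PanelSegment(
                name=name,
                interval=interval,
                direction=fields[4],
                key_genes=genes,
                discovery_frequency=float(fields[6]) if fields[6] else None,
                discovery_seg_mean=float(fields[7]) if fields[7] else None,
                discovery_logP=float(fields[8]) if fields[8] else None,
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{origin}: line {lineno}: {exc}") from exc
        segments.append(seg)
    return segments


def panel_to_bed(segments: Iterable[PanelSegment], path: str | Path) -> None:
    """Export a panel as BED6 (name in column 4, +/- direction in column 6)."""
    with open(path, "w") as fh:
        for s in segments:
            strand = "+" if s.direction == "gain" else "-"
            score = 0 if s.discovery_frequency is None else int(round(1000 * s.discovery_frequency))
            fh.write(f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                     f"\t{s.name}\t{score}\t{strand}\n")


def panel_to_frame(segments: Iterable[PanelSegment]) -> pd.DataFrame:
    """Panel as a DataFrame in the on-disk column layout."""
    rows = []
    for s in segments:
        rows.append({
            "name": s.name, "chrom": s.interval.chrom,
            "loc.start": s.interval.start, "loc.end": s.interval.end,
            "direction": s.direction, "key_genes": ",".join(s.key_genes),
            "frequency": s.discovery_frequency, "seg_mean": s.discovery_seg_mean,
            "logP": s.discovery_logP,
        })
    return pd.DataFrame(rows, columns=_PANEL_COLUMNS)
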