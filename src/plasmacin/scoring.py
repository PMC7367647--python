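"""Panel scoring and the positive/negative screen.

A panel segment spanning n usable bins is scored by Stouffer aggregation:

    seg_mean = mean(z_b over bins in the segment)
    Z        = seg_mean * sqrt(n)

Under the null each bin Z is approximately N(0, 1), so the segment Z is
again approximately standard normal regardless of segment length, and one
fixed cutoff applies to every segment. The default cutoff 2.702 is the
ROC-optimized screening threshold of the liver-cancer panel; a segment is
called altered when |Z| >= cutoff (absolute mode) or when Z crosses the
cutoff in the segment's annotated direction (matched mode). A sample
screens positive with at least one altered segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomicInterval, PanelSegment
from .normalization import NormalizedProfile
from .segmentation import Segment, SegmentationResult

__all__ = [
    "DEFAULT_CUTOFF",
    "SegmentZ",
    "PanelScore",
    "ScreeningCall",
    "UncallableSegmentError",
    "segment_z",
    "score_panel",
    "score_cbs_segments",
    "screen",
    "track_longitudinal",
    "category_of",
]

#: ROC-optimized screening cutoff on the aggregated segment Z
DEFAULT_CUTOFF = 2.702


class UncallableSegmentError(ValueError):
    """A segment with no usable bins cannot be scored (never silently 0)."""


@dataclass(frozen=True)
class SegmentZ:
    name: str
    interval: GenomicInterval | None
    n_bins: int
    seg_mean: float
    z: float
    direction: str | None = None


@dataclass
class PanelScore:
    sample_id: str
    segment_scores: list[SegmentZ]
    calls: dict[str, bool]
    altered_count: int
    category: str
    cutoff: float
    direction_mode: str
    uncallable: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ScreeningCall:
    sample_id: str
    positive: bool
    altered_count: int
    cutoff_used: float


def category_of(altered_count: int) -> str:
    """Altered-segment count category: '>=3', '2', '1' or '0'."""
    if altered_count >= 3:
        return ">=3"
    return str(altered_count)


def segment_z(profile: NormalizedProfile, interval: GenomicInterval,
              name: str = "", direction: str | None = None) -> SegmentZ:
    """Stouffer-aggregated Z of one genomic interval on a normalized profile."""
    if interval.chrom not in profile.grid.build:
        raise UncallableSegmentError(
            f"segment {name or interval}: chromosome {interval.chrom} "
            f"not in the profile's grid")
    bins = profile.grid.bins_in_interval(interval)
    idx = np.arange(bins.start, bins.stop)
    usable = idx[profile.mask[idx]] if idx.size else idx
    if usable.size == 0:
        raise UncallableSegmentError(
            f"segment {name or interval} has no usable bins")
    z_bins = profile.z[usable]
    seg_mean = float(z_bins.mean())
    n = int(usable.size)
    return SegmentZ(name=name or str(interval), interval=interval,
                    n_bins=n, seg_mean=seg_mean,
                    z=seg_mean * math.sqrt(n), direction=direction)


def _call(z: float, cutoff: float, direction: str | None, mode: str) -> bool:
    if mode == "absolute":
        return abs(z) >= cutoff
    if mode == "matched":
        if direction == "gain":
            return z >= cutoff
        if direction == "loss":
            return z <= -cutoff
        return abs(z) >= cutoff
    raise ValueError(f"unknown direction_mode {mode!r}")


def score_panel(
    profile: NormalizedProfile,
    panel: Sequence[PanelSegment],
    cutoff: float = DEFAULT_CUTOFF,
    direction_mode: str = "absolute",
) -> PanelScore:
    """Score every panel segment and derive the altered count / category.

    The cutoff is inclusive (|Z| >= cutoff is altered). Segments with no
    usable bins are excluded from the count and listed in ``uncallable``.
    """
    scores: list[SegmentZ] = []
    calls: dict[str, bool] = {}
    uncallable: list[str] = []
    for seg in panel:
        try:
            sz = segment_z(profile, seg.interval, name=seg.name,
                           direction=seg.direction)
        except UncallableSegmentError:
            uncallable.append(seg.name)
            continue
        scores.append(sz)
        calls[seg.name] = _call(sz.z, cutoff, seg.direction, direction_mode)
    altered = sum(calls.values())
    return PanelScore(sample_id=profile.sample_id, segment_scores=scores,
                      calls=calls, altered_count=altered,
                      category=category_of(altered), cutoff=cutoff,
                      direction_mode=direction_mode, uncallable=uncallable)


def score_cbs_segments(
    result: SegmentationResult,
    cutoff: float = DEFAULT_CUTOFF,
    sample_id: str | None = None,
) -> PanelScore:
    """Discovery-phase variant: screen a sample's own CBS segments instead
    of the fixed panel. Segment Z is already Stouffer-aggregated."""
    scores: list[SegmentZ] = []
    calls: dict[str, bool] = {}
    for s in result.all_segments():
        name = f"{s.chrom}:{s.start}-{s.end}"
        iv = GenomicInterval(s.chrom, s.start, s.end) if s.chrom else None
        scores.append(SegmentZ(name=name, interval=iv, n_bins=s.n_bins,
                               seg_mean=s.seg_mean, z=s.z))
        calls[name] = abs(s.z) >= cutoff
    altered = sum(calls.values())
    return PanelScore(sample_id=sample_id or result.sample_id,
                      segment_scores=scores, calls=calls,
                      altered_count=altered, category=category_of(altered),
                      cutoff=cutoff, direction_mode="absolute")


def screen(score: PanelScore) -> ScreeningCall:
    """Positive screen iff at least one altered segment."""
    return ScreeningCall(sample_id=score.sample_id,
                         positive=score.altered_count >= 1,
                         altered_count=score.altered_count,
                         cutoff_used=score.cutoff)


def track_longitudinal(
    scores: Sequence[PanelScore],
    timepoints: Sequence | None = None,
) -> dict[str, list[tuple]]:
    """Per-segment (timepoint, Z, altered) trajectories over serial samples.

    All scores must come from the same panel (same segment names); no
    interpolation between timepoints is performed. Each trajectory entry is
    (timepoint, z, altered_call); a parallel entry under the key
    ``"__screen__"`` carries the per-timepoint ScreeningCall.
    """
    if not scores:
        raise ValueError("need at least one timepoint")
    if timepoints is None:
        timepoints = list(range(len(scores)))
    if len(timepoints) != len(scores):
        raise ValueError("timepoints and scores differ in length")
    names = [tuple(s.name for s in sc.segment_scores) for sc in scores]
    if any(n != names[0] for n in names[1:]):
        raise ValueError("longitudinal scores mix different panels")
    traj: dict[str, list[tuple]] = {name: [] for name in names[0]}
    traj["__screen__"] = []
    for t, sc in zip(timepoints, scores):
        for sz in sc.segment_scores:
            traj[sz.name].append((t, sz.z, sc.calls[sz.name]))
        traj["__screen__"].append((t, screen(sc)))
    return traj
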