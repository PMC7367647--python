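"""Circular binary segmentation (CBS) of per-bin Z-score vectors.

The change-point statistic for an arc (i, j] of a chromosome's bin vector
(treated circularly) is the pooled-variance two-sample t statistic between
the bins inside the arc and the bins outside it. Because |t| is symmetric
between a set and its complement, wrap-around arcs are redundant and the
search reduces to all contiguous arcs with both parts at least
``min_width`` bins. Significance of the maximal |t| is assessed by
permutation: the bins of the (sub-)vector are shuffled and the maximal
arc statistic recomputed.

The permutation p-value is p = (1 + #{max |T*| > |T_obs|}) / (n_perm + 1),
with a *strict* inequality: permutations that merely tie the observed
maximum (which happens with high probability for discrete, e.g. noiseless
two-level, vectors) do not count against it. For continuous data ties have
probability zero, so null calibration is unaffected; for idealized step
vectors a perfect split is correctly called significant.

Splitting recurses on the resulting parts until no arc is significant at
``alpha`` or parts become too short.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .normalization import NormalizedProfile

__all__ = [
    "CbsParams",
    "Segment",
    "SegmentationResult",
    "max_circular_t",
    "permutation_p",
    "cbs_segment",
    "segment_profile",
    "segment_table",
    "write_seg",
    "read_seg",
]

_MEAN_TOL = 1e-12


@dataclass(frozen=True)
class CbsParams:
    """Tunables of the segmentation: significance level of a split, number
    of permutations, minimal segment width in bins, RNG seed, recursion cap."""

    alpha: float = 0.05
    n_perm: int = 10_000
    min_width: int = 2
    seed: int = 0
    max_depth: int = 30
    early_stop: bool = True

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


class ArcSplit(NamedTuple):
    i: int
    j: int
    T: float


@dataclass(frozen=True)
class Segment:
    """A maximal run of bins with common mean Z.

    ``start``/``end`` are bp coordinates snapped to the outer boundaries of
    the terminal bins (bin indices when the segmentation was run on a bare
    vector); ``seg_mean`` is the mean bin Z, ``z`` the Stouffer-aggregated
    segment Z = seg_mean * sqrt(n_bins), and ``logP`` the log10 permutation
    p-value of the split that created the segment (0 for an unsplit root).
    """

    chrom: str
    start: int
    end: int
    n_bins: int
    seg_mean: float
    z: float
    logP: float
    start_idx: int = 0
    end_idx: int = 0


@dataclass
class SegmentationResult:
    sample_id: str
    segments: dict[str, list[Segment]]
    params: CbsParams

    def all_segments(self) -> list[Segment]:
        return [s for chrom in self.segments.values() for s in chrom]


@lru_cache(maxsize=256)
def _arc_pairs(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) with arc (i, j], min_width <= j-i <= n-min_width, j <= n,
    in lexicographic (i, j) order so argmax tie-breaks to smallest (i, j)."""
    i_parts, j_parts = [], []
    for i in range(n):
        j_lo = i + min_width
        j_hi = min(n, i + n - min_width)
        if j_hi >= j_lo:
            j = np.arange(j_lo, j_hi + 1, dtype=np.int64)
            i_parts.append(np.full(j.size, i, dtype=np.int64))
            j_parts.append(j)
    if not i_parts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(i_parts), np.concatenate(j_parts)


def _arc_t_values(x: np.ndarray, min_width: int) -> np.ndarray:
    """|t| for every admissible arc of x, aligned with _arc_pairs order."""
    n = x.size
    i_idx, j_idx = _arc_pairs(n, min_width)
    if i_idx.size == 0:
        return np.empty(0)
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = np.concatenate(([0.0], np.cumsum(x * x)))
    m = (j_idx - i_idx).astype(float)
    k = n - m
    s_in = S[j_idx] - S[i_idx]
    q_in = Q[j_idx] - Q[i_idx]
    mean_in = s_in / m
    mean_out = (S[n] - s_in) / k
    ss = (q_in - s_in * s_in / m) + ((Q[n] - q_in) - (S[n] - s_in) ** 2 / k)
    # pooled SS indistinguishable from zero at float precision (cancellation
    # residue of the prefix sums) counts as zero: perfect split, not noise
    ss_floor = 1e-10 * max(float(Q[n]), 1e-30)
    ss = np.where(ss <= ss_floor, 0.0, ss)
    diff = np.abs(mean_in - mean_out)
    denom = np.sqrt(ss / (n - 2) * (1.0 / m + 1.0 / k))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    degenerate = denom == 0
    if np.any(degenerate):
        scale = np.maximum(1.0, np.abs(mean_in[degenerate])
                           + np.abs(mean_out[degenerate]))
        t[degenerate] = np.where(diff[degenerate] <= _MEAN_TOL * scale,
                                 0.0, np.inf)
    return t


def max_circular_t(values, min_width: int = 2) -> ArcSplit | None:
    """Arc (i, j] maximizing |two-sample t| between arc and complement.

    Both arc and complement must span at least ``min_width`` bins. Ties are
    broken toward the smallest i, then smallest j. Returns None when the
    vector is too short to admit any split.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 * min_width:
        return None
    t = _arc_t_values(x, min_width)
    if t.size == 0:
        return None
    t_max = float(np.max(t))
    # complementary arcs describe the same split but travel different float
    # paths; treat near-ties as exact and break toward smallest (i, j)
    if np.isinf(t_max):
        candidates = np.isinf(t)
    else:
        candidates = t >= t_max - 1e-9 * max(1.0, abs(t_max))
    best = int(np.flatnonzero(candidates)[0])
    i_idx, j_idx = _arc_pairs(x.size, min_width)
    return ArcSplit(int(i_idx[best]), int(j_idx[best]), float(t[best]))


def permutation_p(
    values,
    observed_T: float,
    n_perm: int = 10_000,
    seed: int = 0,
    min_width: int = 2,
    early_stop_count: int | None = None,
) -> float:
    """Permutation p-value of the maximal arc statistic.

    p = (1 + #{permutations with max |T*| strictly above observed})
        / (#permutations run + 1); deterministic for a fixed seed.
    ``early_stop_count`` aborts once that many exceedances accumulate (the
    p-value is then already known to exceed any threshold below
    early_stop_count / (n_perm + 1)).
    """
    x = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    for _ in range(n_perm):
        perm = rng.permutation(x)
        t = _arc_t_values(perm, min_width)
        done += 1
        if t.size and float(np.max(t)) > observed_T:
            exceed += 1
            if early_stop_count is not None and exceed >= early_stop_count:
                break
    return (1 + exceed) / (done + 1)


def _node_seed(base_seed: int, node_id: int) -> int:
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, node_id])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def cbs_segment(values, params: CbsParams | None = None) -> list[Segment]:
    """Segment one chromosome's Z vector by recursive circular binary
    splitting; a split is accepted only when its permutation p < alpha.

    Returned segments carry bin *indices* in ``start``/``end`` (use
    :func:`segment_profile` for bp coordinates on a grid).
    """
    params = params or CbsParams()
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("segmentation input must be finite")
    out: list[tuple[int, int, float]] = []  # (lo, hi, logP)
    node_counter = [0]

    def recurse(lo: int, hi: int, depth: int, created_logp: float) -> None:
        node_counter[0] += 1
        node_id = node_counter[0]
        seg = x[lo:hi]
        if seg.size < 2 * params.min_width or depth >= params.max_depth:
            out.append((lo, hi, created_logp))
            return
        split = max_circular_t(seg, params.min_width)
        if split is None or split.T <= 0:
            out.append((lo, hi, created_logp))
            return
        stop = (math.ceil(params.alpha * (params.n_perm + 1))
                if params.early_stop else None)
        p = permutation_p(seg, split.T, n_perm=params.n_perm,
                          seed=_node_seed(params.seed, node_id),
                          min_width=params.min_width,
                          early_stop_count=stop)
        if p >= params.alpha:
            out.append((lo, hi, created_logp))
            return
        logp = math.log10(p)
        bounds = [lo]
        if split.i > 0:
            bounds.append(lo + split.i)
        if split.j < seg.size:
            bounds.append(lo + split.j)
        bounds.append(hi)
        if len(bounds) < 3:  # arc spans the whole sub-vector: no real split
            out.append((lo, hi, created_logp))
            return
        for a, b in zip(bounds[:-1], bounds[1:]):
            recurse(a, b, depth + 1, logp)

    if x.size == 0:
        return []
    recurse(0, x.size, 0, 0.0)
    out.sort()
    merged: list[tuple[int, int, float]] = []
    for lo, hi, logp in out:
        if merged:
            plo, phi, plogp = merged[-1]
            scale = max(1.0, abs(x[plo:phi].mean()), abs(x[lo:hi].mean()))
            if abs(x[plo:phi].mean() - x[lo:hi].mean()) <= _MEAN_TOL * scale:
                merged[-1] = (plo, hi, plogp)
                continue
        merged.append((lo, hi, logp))
    segments = []
    for lo, hi, logp in merged:
        n = hi - lo
        m = float(x[lo:hi].mean())
        segments.append(Segment(chrom="", start=lo, end=hi, n_bins=n,
                                seg_mean=m, z=m * math.sqrt(n), logP=logp,
                                start_idx=lo, end_idx=hi))
    return segments


def segment_profile(profile: NormalizedProfile,
                    params: CbsParams | None = None) -> SegmentationResult:
    """Segment every chromosome of a normalized profile.

    Masked bins are skipped (not interpolated); bp coordinates of each
    segment snap to the outer boundaries of its terminal unmasked bins.
    """
    params = params or CbsParams()
    grid = profile.grid
    result: dict[str, list[Segment]] = {}
    for ci, (chrom, _) in enumerate(grid.build.chromosomes):
        rng_bins = grid.chrom_range(chrom)
        idx = np.arange(rng_bins.start, rng_bins.stop)
        usable = idx[profile.mask[idx]]
        if usable.size == 0:
            result[chrom] = []
            continue
        z = profile.z[usable]
        # distinct per-chromosome seed stream, deterministic in params.seed
        chrom_params = replace(params, seed=_node_seed(params.seed, 10_000 + ci))
        segs = cbs_segment(z, chrom_params)
        mapped = []
        for s in segs:
            bins = usable[s.start_idx:s.end_idx]
            mapped.append(replace(
                s, chrom=chrom,
                start=int(grid.start[bins[0]]), end=int(grid.end[bins[-1]]),
                start_idx=int(bins[0]), end_idx=int(bins[-1]) + 1))
        result[chrom] = mapped
    return SegmentationResult(sample_id=profile.sample_id, segments=result,
                              params=params)


_SEG_COLUMNS = ["sample", "chrom", "loc.start", "loc.end", "num.bins",
                "seg.mean", "z", "logP"]


def segment_table(result: SegmentationResult) -> pd.DataFrame:
    """SEG-style table of all segments (one row per segment)."""
    rows = [
        {"sample": result.sample_id, "chrom": s.chrom,
         "loc.start": s.start, "loc.end": s.end, "num.bins": s.n_bins,
         "seg.mean": s.seg_mean, "z": s.z, "logP": s.logP}
        for s in result.all_segments()
    ]
    return pd.DataFrame(rows, columns=_SEG_COLUMNS)


def write_seg(result: SegmentationResult, path: str | Path) -> None:
    segment_table(result).to_csv(path, sep="\t", index=False,
                                 float_format="%.10g")


def read_seg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _SEG_COLUMNS:
        raise ValueError(f"{path}: expected SEG columns {_SEG_COLUMNS}")
    return df
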