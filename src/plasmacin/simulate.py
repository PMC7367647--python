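"""Seeded synthetic cfDNA bin-count generator with known copy-number truth.

A sample is modelled as a diploid admixture: a tumor fraction ``tf`` of the
plasma DNA derives from a tumor genome with per-bin copy number c_b, the
rest from diploid tissue, so the expected relative coverage of bin b is
proportional to

    baseline_b * (1 + tf * (c_b / 2 - 1)) * gc_bias_b.

Counts are drawn negative-binomially around depth * weight with
overdispersion ``dispersion`` (variance = mu + mu^2/dispersion; real cfDNA
bin counts are overdispersed relative to Poisson), or multinomially in the
``dispersion=None`` limit, which keeps the exact count-conservation
identity for oracle math. Defaults emulate the screening study conditions:
10 M fragments per sample on a 200 kb grid, dispersion 50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .coverage import RawCoverageProfile
from .genome import BinGrid, GenomicInterval, PanelSegment

__all__ = [
    "CNVEvent",
    "SimulationParams",
    "SimulatedTruth",
    "expected_profile",
    "simulate_profile",
    "simulate_cohort",
    "menu_from_panel",
]

DEFAULT_DEPTH = 10_000_000
DEFAULT_DISPERSION = 50.0


@dataclass(frozen=True)
class CNVEvent:
    """A copy-number event: interval plus (possibly fractional) tumor copy
    number; 2 is neutral, 3 a single-copy gain, 1 a single-copy loss."""

    interval: GenomicInterval
    copy_number: float

    def __post_init__(self):
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


@dataclass
class SimulationParams:
    grid: BinGrid
    depth: int = DEFAULT_DEPTH
    tumor_fraction: float = 0.0
    events: tuple[CNVEvent, ...] = ()
    dispersion: float | None = DEFAULT_DISPERSION
    baseline: np.ndarray | None = None  # per-bin mappability-like weights
    gc_bias: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.tumor_fraction <= 1):
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for arr_name in ("baseline", "gc_bias"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.grid.n_bins,):
                    raise ValueError(f"{arr_name} length != grid bins")
                setattr(self, arr_name, arr)


@dataclass
class SimulatedTruth:
    params: SimulationParams
    expected_weight: np.ndarray  # per-bin expected relative coverage
    copy_state: np.ndarray       # per-bin true tumor copy number


def _copy_state(grid: BinGrid, events: Sequence[CNVEvent]) -> np.ndarray:
    c = np.full(grid.n_bins, 2.0)
    claimed = np.zeros(grid.n_bins, dtype=bool)
    for ev in events:
        rng = grid.bins_in_interval(ev.interval)
        idx = np.arange(rng.start, rng.stop)
        if np.any(claimed[idx] & (c[idx] != ev.copy_number)):
            raise ValueError(f"overlapping events within one truth set at {ev.interval}")
        c[idx] = ev.copy_number
        claimed[idx] = True
    return c


def expected_profile(params: SimulationParams) -> SimulatedTruth:
    """Per-bin expected relative coverage under the admixture model."""
    grid = params.grid
    c = _copy_state(grid, params.events)
    base = params.baseline if params.baseline is not None else np.ones(grid.n_bins)
    w = base * (1.0 + params.tumor_fraction * (c / 2.0 - 1.0))
    if params.gc_bias is not None:
        w = w * params.gc_bias
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero expected weights")
    return SimulatedTruth(params=params, expected_weight=w / total, copy_state=c)


def simulate_profile(
    params: SimulationParams,
    sample_id: str = "sim",
) -> tuple[RawCoverageProfile, SimulatedTruth]:
    """Draw one bin-count profile; fully reproducible for a fixed seed."""
    truth = expected_profile(params)
    rng = np.random.default_rng(params.seed)
    mu = params.depth * truth.expected_weight
    if params.dispersion is None or not np.isfinite(params.dispersion):
        counts = rng.multinomial(params.depth, truth.expected_weight)
    else:
        k = float(params.dispersion)
        p = k / (k + mu)
        counts = rng.negative_binomial(k, p)
    profile = RawCoverageProfile(
        sample_id=sample_id, grid=params.grid, counts=counts.astype(float),
        metadata={"simulated": True, "seed": params.seed,
                  "tumor_fraction": params.tumor_fraction,
                  "depth": params.depth, "dispersion": params.dispersion})
    return profile, truth


@dataclass(frozen=True)
class MenuEntry:
    segment: PanelSegment
    probability: float
    copy_number: float


def menu_from_panel(
    panel: Sequence[PanelSegment],
    probabilities: Sequence[float] | None = None,
    gain_copy: float = 3.0,
    loss_copy: float = 1.0,
) -> list[MenuEntry]:
    """Event menu from a panel; probabilities default to each segment's
    discovery cohort frequency, copy numbers to single-copy gain/loss."""
    menu = []
    for i, seg in enumerate(panel):
        p = (probabilities[i] if probabilities is not None
             else (seg.discovery_frequency or 0.0))
        cn = gain_copy if seg.direction == "gain" else loss_copy
        menu.append(MenuEntry(segment=seg, probability=float(p), copy_number=cn))
    return menu


def simulate_cohort(
    n_cases: int,
    n_controls: int,
    event_menu: Sequence[MenuEntry],
    tf_distribution: tuple[float, float] | Callable,
    params: SimulationParams,
    seed: int = 0,
) -> list[tuple[RawCoverageProfile, SimulatedTruth, str]]:
    """Simulate a labeled case/control cohort with known truth.

    Controls carry tumor fraction 0 and no events. Each case independently
    draws events segment-by-segment at the menu probabilities (earlier menu
    entries take precedence when drawn events would overlap) and a tumor
    fraction from ``tf_distribution`` (a (low, high) uniform range or a
    callable of the RNG).
    """
    if n_controls < 2:
        raise ValueError("need >= 2 controls")
    rng = np.random.default_rng(seed)
    grid = params.grid
    out = []
    for i in range(n_controls):
        p = replace(params, tumor_fraction=0.0, events=(),
                    seed=int(rng.integers(2**31 - 1)))
        prof, truth = simulate_profile(p, sample_id=f"control_{i:03d}")
        out.append((prof, truth, "control"))
    for i in range(n_cases):
        if callable(tf_distribution):
            tf = float(tf_distribution(rng))
        else:
            lo, hi = tf_distribution
            tf = float(rng.uniform(lo, hi))
        events: list[CNVEvent] = []
        claimed = np.zeros(grid.n_bins, dtype=bool)
        for entry in event_menu:
            if rng.random() >= entry.probability:
                continue
            bins = grid.bins_in_interval(entry.segment.interval)
            idx = np.arange(bins.start, bins.stop)
            if idx.size == 0 or np.any(claimed[idx]):
                continue  # earlier menu entries take precedence
            claimed[idx] = True
            events.append(CNVEvent(entry.segment.interval, entry.copy_number))
        p = replace(params, tumor_fraction=tf, events=tuple(events),
                    seed=int(rng.integers(2**31 - 1)))
        prof, truth = simulate_profile(p, sample_id=f"case_{i:03d}")
        out.append((prof, truth, "cancer"))
    return out
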