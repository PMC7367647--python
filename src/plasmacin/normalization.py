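"""Control reference panel and per-bin Z-score normalization.

A sample's per-bin relative coverage x_b is converted to

    z_b = (x_b - mean_b) / sd_b

where mean_b and sd_b are the per-bin mean and sample standard deviation
of relative coverage across the healthy-control panel. Under the null
(sample drawn from the control distribution) each z_b is approximately
standard normal, which is what makes segment-level Stouffer aggregation
and a fixed Z cutoff meaningful downstream.

Bins where the controls carry no information (zero variance, or mean
coverage below 10% of the genome-wide median bin mean — centromeric and
telomeric dropout) are masked and excluded from all downstream statistics.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import RawCoverageProfile
from .genome import BinGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ReferencePanel",
    "NormalizedProfile",
    "build_reference",
    "normalize",
    "write_reference",
    "load_reference",
]


@dataclass
class ReferencePanel:
    """Per-bin control mean/SD of relative coverage plus the usable-bin mask."""

    grid: BinGrid
    n_controls: int
    mean_per_bin: np.ndarray
    stdev_per_bin: np.ndarray
    mask: np.ndarray  # True = usable
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.grid.n_bins
        for name in ("mean_per_bin", "stdev_per_bin", "mask"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != grid bins {n}")
        if self.n_controls < 2:
            raise ValueError("reference panel needs >= 2 controls")
        if np.any(self.stdev_per_bin[self.mask] <= 0):
            raise ValueError("unmasked bin with non-positive stdev")

    @property
    def n_usable(self) -> int:
        return int(self.mask.sum())


@dataclass
class NormalizedProfile:
    """Per-bin Z-scores for one sample; NaN on masked bins."""

    sample_id: str
    grid: BinGrid
    z: np.ndarray
    mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.z.shape != (self.grid.n_bins,):
            raise ValueError("z length does not match grid")
        if not np.all(np.isfinite(self.z[self.mask])):
            raise ValueError("non-finite z on unmasked bins")


def build_reference(
    controls: list[RawCoverageProfile],
    low_coverage_fraction: float = 0.10,
) -> ReferencePanel:
    """Build the per-bin mean/SD reference from healthy-control profiles.

    Uses the sample (n-1) standard deviation. Bins with zero control
    variance or control mean below ``low_coverage_fraction`` of the
    genome-wide median bin mean are masked.
    """
    if len(controls) < 2:
        raise ValueError(f"need >= 2 controls, got {len(controls)}")
    grid = controls[0].grid
    for c in controls[1:]:
        if not grid.same_frame(c.grid):
            raise ValueError(f"control {c.sample_id} is on a different grid")
    mat = np.vstack([c.relative_coverage for c in controls])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    median_mean = np.median(mean[mean > 0]) if np.any(mean > 0) else 0.0
    # sd indistinguishable from zero at float precision counts as zero
    sd_floor = 1e-9 * np.maximum(mean, median_mean)
    mask = (sd > sd_floor) & (mean >= low_coverage_fraction * median_mean)
    n_masked = int((~mask).sum())
    if mask.sum() == 0:
        warnings.warn("all bins masked — controls are degenerate "
                      "(zero variance or no coverage)", stacklevel=2)
    elif n_masked:
        logger.info("masked %d/%d bins (zero variance or low control coverage)",
                    n_masked, grid.n_bins)
    return ReferencePanel(
        grid=grid, n_controls=len(controls), mean_per_bin=mean,
        stdev_per_bin=sd, mask=mask,
        metadata={"n_masked": n_masked,
                  "coverage_unit": "relative",
                  "control_ids": [c.sample_id for c in controls]})


def normalize(profile: RawCoverageProfile,
              reference: ReferencePanel) -> NormalizedProfile:
    """Per-bin Z-scores of one sample against the control reference."""
    if not profile.grid.same_frame(reference.grid):
        raise ValueError(
            f"sample {profile.sample_id} grid does not match reference grid")
    z = np.full(reference.grid.n_bins, np.nan)
    m = reference.mask
    z[m] = ((profile.relative_coverage[m] - reference.mean_per_bin[m])
            / reference.stdev_per_bin[m])
    return NormalizedProfile(
        sample_id=profile.sample_id, grid=reference.grid, z=z,
        mask=m.copy(),
        metadata={"n_controls": reference.n_controls})


_REF_COLUMNS = ["chrom", "start", "end", "mean", "stdev", "mask"]


def write_reference(reference: ReferencePanel, path: str | Path) -> None:
    """Serialize the panel: one JSON provenance header line, then a TSV."""
    header = {
        "grid": reference.grid.fingerprint(),
        "bin_size": reference.grid.bin_size,
        "build": reference.grid.build.name,
        "n_controls": reference.n_controls,
        "coverage_unit": "relative",
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        fh.write("\t".join(_REF_COLUMNS) + "\n")
        chroms = reference.grid.bin_chrom
        for i in range(reference.grid.n_bins):
            fh.write(f"{chroms[i]}\t{reference.grid.start[i]}\t{reference.grid.end[i]}"
                     f"\t{reference.mean_per_bin[i]:.10g}\t{reference.stdev_per_bin[i]:.10g}"
                     f"\t{int(reference.mask[i])}\n")


def load_reference(path: str | Path, grid: BinGrid) -> ReferencePanel:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[1:])
        df = pd.read_csv(fh, sep="\t")
    if header.get("grid") != grid.fingerprint():
        raise ValueError(f"{path}: reference was built on a different grid "
                         f"({header.get('grid')} != {grid.fingerprint()})")
    if len(df) != grid.n_bins or list(df.columns) != _REF_COLUMNS:
        raise ValueError(f"{path}: malformed reference table")
    return ReferencePanel(
        grid=grid, n_controls=int(header["n_controls"]),
        mean_per_bin=df["mean"].to_numpy(float),
        stdev_per_bin=df["stdev"].to_numpy(float),
        mask=df["mask"].to_numpy(bool),
        metadata=header)
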