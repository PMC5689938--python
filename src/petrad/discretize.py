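"""Fixed-bin-count gray-level discretization of masked SUV volumes.

The ROI's SUV range is split into ``Ng`` equally spaced intervals
(``bin_size = (suv_max - suv_min) / Ng``) and each in-mask voxel is assigned
an integer level in ``1..Ng``.  Extrema are taken over in-mask voxels only,
so the binning is range-relative: adding a constant to every ROI voxel
leaves the levels unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volio import ROIMask, SUVVolume, check_geometry

__all__ = ["DiscretizedROI", "discretize_roi", "DEFAULT_GRAY_LEVELS", "REFERENCE_GRAY_LEVEL"]

logger = logging.getLogger(__name__)

#: Bin counts evaluated by the study design.
DEFAULT_GRAY_LEVELS = (32, 64, 128, 256)
#: Bin count used as the reference arm in gray-level comparisons.
REFERENCE_GRAY_LEVEL = 64


@dataclass
class DiscretizedROI:
    """Integer gray levels (1..Ng) for in-mask voxels of a volume.

    ``levels`` is a full-grid int array with 0 outside the mask; ``mask`` is
    the boolean foreground.  ``bin_size`` is the SUV width of one level.
    """

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    bin_size: float
    suv_min: float
    suv_max: float
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("discretized ROI has no in-mask voxels")
        if inside.min() < 1 or inside.max() > self.ng:
            raise ValueError("in-mask levels must lie in 1..Ng")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def roi_levels(self) -> np.ndarray:
        """Flat array of in-mask levels."""
        return self.levels[self.mask]

    def level_histogram(self) -> np.ndarray:
        """Counts per level 1..Ng (index 0 corresponds to level 1)."""
        return np.bincount(self.roi_levels(), minlength=self.ng + 1)[1:]


def discretize_roi(volume: SUVVolume, mask: ROIMask, ng: int) -> DiscretizedROI:
    """Discretize the in-mask SUVs of ``volume`` into ``ng`` equal-width bins.

    Levels follow ``min(ng, floor((suv - suv_min) / bin_size) + 1)`` so the
    ROI maximum maps to ``ng`` rather than an ``ng + 1`` label.  A constant
    ROI (zero range) degenerates to all voxels at level 1 with a warning.
    """
    ng = int(ng)
    if ng < 2:
        raise ValueError(f"Ng must be >= 2, got {ng}")
    check_geometry(volume, mask)
    m = mask.as_bool()
    if not m.any():
        raise ValueError("mask is empty")

    suv = volume.values[m]
    suv_min = float(suv.min())
    suv_max = float(suv.max())
    bin_size = (suv_max - suv_min) / ng

    levels = np.zeros(volume.shape, dtype=np.int32)
    if bin_size == 0.0:
        logger.warning(
            "constant ROI (SUV range 0); assigning all %d voxels level 1", int(m.sum())
        )
        levels[m] = 1
    else:
        lv = np.floor((volume.values[m] - suv_min) / bin_size).astype(np.int32) + 1
        np.minimum(lv, ng, out=lv)
        levels[m] = lv

    return DiscretizedROI(
        levels=levels,
        mask=m,
        ng=ng,
        bin_size=bin_size,
        suv_min=suv_min,
        suv_max=suv_max,
        spacing_mm=volume.spacing_mm,
    )
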