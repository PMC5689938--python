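"""Shape features and intensity-histogram / intensity-volume-histogram features.

Shape descriptors are computed from the binary mask alone (voxel-count
volume, triangulated isosurface area, convex hull, principal axes), so they
are invariant to the gray-level parameter.  Intensity features combine raw
in-mask SUV moments with IVH cut-points on a relative-intensity axis
(``Vx``: volume fraction at or above ``min + x% * range``; ``Ix``: minimum
intensity of the hottest ``x%`` of the ROI volume).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import QhullError
from skimage import measure, morphology

from .discretize import DiscretizedROI
from .volio import ROIMask, SUVVolume, check_geometry

__all__ = [
    "ShapeSummary",
    "IVHSummary",
    "shape_features",
    "ivh_features",
    "SHAPE_FEATURE_NAMES",
    "IVH_FEATURE_NAMES",
]

logger = logging.getLogger(__name__)

SHAPE_FEATURE_NAMES = (
    "shape_volume_mm3",
    "shape_sphericity",
    "shape_spherical_disproportionality",
    "shape_convexity",
    "shape_eccentricity",
    "shape_surface_to_volume_ratio",
)

IVH_FEATURE_NAMES = (
    "ivh_mean",
    "ivh_sd",
    "ivh_variance",
    "ivh_min",
    "ivh_max",
    "ivh_range",
    "ivh_median",
    "ivh_skewness",
    "ivh_kurtosis",
    "ivh_energy",
    "ivh_rms",
    "ivh_mad",
    "ivh_entropy",
    "ivh_uniformity",
    "ivh_v10",
    "ivh_v50",
    "ivh_v90",
    "ivh_i10",
    "ivh_i50",
    "ivh_i90",
)


@dataclass
class ShapeSummary:
    """Morphology of a binary ROI.

    ``surface_area_mm2`` and ``principal_axis_lengths_mm`` are auxiliary;
    the six catalogue features are exposed via :meth:`features`.
    """

    volume_mm3: float
    surface_area_mm2: float
    sphericity: float
    spherical_disproportionality: float
    convexity: float
    eccentricity: float
    surface_to_volume_ratio: float
    principal_axis_lengths_mm: tuple[float, float, float]

    def features(self) -> dict[str, float]:
        return {
            "shape_volume_mm3": self.volume_mm3,
            "shape_sphericity": self.sphericity,
            "shape_spherical_disproportionality": self.spherical_disproportionality,
            "shape_convexity": self.convexity,
            "shape_eccentricity": self.eccentricity,
            "shape_surface_to_volume_ratio": self.surface_to_volume_ratio,
        }


@dataclass
class IVHSummary:
    """First-order and intensity-volume-histogram summary of in-mask SUVs."""

    mean: float
    sd: float
    minimum: float
    maximum: float
    skewness: float
    kurtosis: float
    intensity_entropy: float
    vx: dict[int, float]  # percent of ROI volume at/above relative cut x
    ix: dict[int, float]  # minimum SUV of the hottest x% of the volume
    extra: dict[str, float]

    def features(self) -> dict[str, float]:
        out = {
            "ivh_mean": self.mean,
            "ivh_sd": self.sd,
            "ivh_min": self.minimum,
            "ivh_max": self.maximum,
            "ivh_skewness": self.skewness,
            "ivh_kurtosis": self.kurtosis,
            "ivh_entropy": self.intensity_entropy,
        }
        out.update(self.extra)
        for x in (10, 50, 90):
            out[f"ivh_v{x}"] = self.vx[x]
            out[f"ivh_i{x}"] = self.ix[x]
        return out


def _surface_mesh(
    mask: np.ndarray, spacing: tuple[float, float, float], smoothing_sigma_vox: float = 0.8
) -> tuple[float, float]:
    """(area, enclosed volume) of a lightly smoothed marching-cubes isosurface.

    The binary mask is blurred with a small Gaussian before contouring at 0.5,
    which removes most of the voxelization bias in the area estimate.  The
    enclosed mesh volume is used for sphericity so the isoperimetric bound
    (sphericity <= 1) holds exactly.
    """
    padded = np.pad(mask.astype(float), 4)
    if smoothing_sigma_vox > 0:
        smoothed = ndimage.gaussian_filter(padded, sigma=smoothing_sigma_vox)
        # thin (single-voxel) structures can blur below the contour level;
        # fall back to the raw binary surface there
        if smoothed.max() > 0.5:
            padded = smoothed
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    vol = abs(float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum())) / 6.0
    return area, vol


def voxel_face_surface_area(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Exposed-voxel-face surface area (cross-check for the mesh estimate)."""
    m = mask.astype(bool)
    sx, sy, sz = spacing
    face_areas = (sy * sz, sx * sz, sx * sy)
    total = 0.0
    for axis, fa in enumerate(face_areas):
        padded = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = np.diff(padded.astype(np.int8), axis=axis)
        total += fa * float(np.abs(diff).sum())
    return total


def shape_features(mask: ROIMask) -> ShapeSummary:
    """Six shape descriptors of a binary ROI (plus auxiliary geometry).

    Sphericity is ``pi^(1/3) (6V)^(2/3) / A`` evaluated on a smoothed
    marching-cubes isosurface (mesh area and mesh-enclosed volume, so the
    isoperimetric bound keeps it in (0, 1]); the reported volume and the
    surface-to-volume ratio use the voxel-count volume.  Convexity follows
    the solidity convention: in-mask voxel count over the voxel count of the
    convex-hull image, so digitization bias cancels between numerator and
    denominator.
    Eccentricity is ``sqrt(1 - lam_min / lam_max)`` from the eigenvalues of
    the voxel-coordinate covariance, floored at the quantization variance
    ``spacing^2 / 12`` so planar masks stay defined.
    """
    m = mask.as_bool()
    n = int(m.sum())
    if n == 0:
        raise ValueError("mask is empty")
    if n < 2:
        raise ValueError("shape features need at least 2 voxels (eccentricity)")
    spacing = np.asarray(mask.spacing_mm, dtype=float)
    voxvol = float(np.prod(spacing))
    volume = n * voxvol
    area, mesh_volume = _surface_mesh(m, tuple(spacing))
    sphericity = min(
        1.0, float(np.pi ** (1.0 / 3.0) * (6.0 * mesh_volume) ** (2.0 / 3.0) / area)
    )

    # solidity convention: both numerator and denominator are voxel counts on
    # the same grid, so digitization bias cancels and convexity stays <= 1
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # qhull warns on coplanar input
            hull_img = morphology.convex_hull_image(m)
        n_hull = int(hull_img.sum())
    except QhullError:
        n_hull = 0
    if n_hull < n:
        # degenerate (coplanar/collinear) voxel sets have no 3D hull
        logger.warning("convex hull degenerate; reporting convexity 1.0")
        convexity = 1.0
    else:
        convexity = n / n_hull

    coords = np.argwhere(m) * spacing  # mm coordinates of voxel centers
    cov = np.cov(coords, rowvar=False, ddof=0)
    lam = np.sort(np.linalg.eigvalsh(cov))
    lam_floor = float(spacing.min()) ** 2 / 12.0
    lam = np.maximum(lam, lam_floor)
    eccentricity = float(np.sqrt(1.0 - lam[0] / lam[-1]))
    axes = tuple(float(2.0 * np.sqrt(5.0 * v)) for v in lam[::-1])

    return ShapeSummary(
        volume_mm3=volume,
        surface_area_mm2=area,
        sphericity=sphericity,
        spherical_disproportionality=1.0 / sphericity,
        convexity=convexity,
        eccentricity=eccentricity,
        surface_to_volume_ratio=area / volume,
        principal_axis_lengths_mm=axes,
    )


def ivh_features(
    volume: SUVVolume,
    mask: ROIMask,
    d: DiscretizedROI,
    vx_points: tuple[int, ...] = (10, 50, 90),
    ix_points: tuple[int, ...] = (10, 50, 90),
) -> IVHSummary:
    """Twenty first-order / IVH features on raw in-mask SUVs.

    Intensity entropy is computed on the discretized level histogram
    (``-sum p log2 p``).  For a constant ROI the SD-normalized moments
    (skewness, kurtosis) are reported as 0 with a warning.
    """
    check_geometry(volume, mask)
    vals = volume.values[mask.as_bool()]
    if vals.size == 0:
        raise ValueError("mask is empty")

    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    vmin = float(vals.min())
    vmax = float(vals.max())
    if sd > 0:
        skew = float(stats.skew(vals))
        kurt = float(stats.kurtosis(vals, fisher=False))
    else:
        logger.warning("constant ROI: skewness/kurtosis undefined, reporting 0")
        skew = 0.0
        kurt = 0.0

    hist = d.level_histogram().astype(float)
    p = hist[hist > 0] / hist.sum()
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p**2))

    rng = vmax - vmin
    vx: dict[int, float] = {}
    for x in vx_points:
        thr = vmin + (x / 100.0) * rng
        vx[x] = float((vals >= thr).mean() * 100.0)
    desc = np.sort(vals)[::-1]
    ix: dict[int, float] = {}
    for x in ix_points:
        k = max(1, int(np.ceil(x / 100.0 * vals.size)))
        ix[x] = float(desc[k - 1])

    extra = {
        "ivh_variance": sd**2,
        "ivh_range": rng,
        "ivh_median": float(np.median(vals)),
        "ivh_energy": float(np.sum(vals**2)),
        "ivh_rms": float(np.sqrt(np.mean(vals**2))),
        "ivh_mad": float(np.mean(np.abs(vals - mean))),
        "ivh_uniformity": uniformity,
    }
    return IVHSummary(
        mean=mean,
        sd=sd,
        minimum=vmin,
        maximum=vmax,
        skewness=skew,
        kurtosis=kurt,
        intensity_entropy=entropy,
        vx=vx,
        ix=ix,
        extra=extra,
    )
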