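"""Synthetic tumor-like SUV phantoms with mask and reconstruction variants.

Each case bundles a base volume (an ellipsoidal tumor carrying a smoothed
Gaussian texture field on a uniform background), three correlated
segmentation-mask variants that satisfy a Dice floor, and four image
variants produced by label-specific smoothing and noise (the 3DRP-like
profile carries the largest noise so it is the most divergent).  All
randomness flows from explicit seeds through ``numpy.random.SeedSequence``;
the full bundle is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volio import ROIMask, SUVVolume, write_mask, write_volume

__all__ = [
    "PhantomSpec",
    "ReconProfile",
    "CaseBundle",
    "DEFAULT_RECON_PROFILES",
    "DEFAULT_MASK_LABELS",
    "generate_tumor_volume",
    "make_mask_variants",
    "make_recon_variants",
    "generate_case",
    "generate_cohort",
    "write_case_bundle",
]

logger = logging.getLogger(__name__)

DEFAULT_MASK_LABELS = ("MTV1", "MTV2", "GBSV")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case."""

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_spacing_mm: tuple[float, float, float] = (5.49, 5.49, 3.30)
    tumor_radius_mm: float = 20.0
    suv_background: float = 1.0
    suv_tumor_mean: float = 8.0
    heterogeneity_scale_mm: float = 8.0
    heterogeneity_amp: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor_radius_mm must be positive")
        if self.heterogeneity_scale_mm <= 0:
            raise ValueError("heterogeneity_scale_mm must be positive")
        if self.heterogeneity_amp < 0:
            raise ValueError("heterogeneity_amp must be >= 0")
        if not (self.suv_tumor_mean > self.suv_background >= 0):
            raise ValueError("require suv_tumor_mean > suv_background >= 0")


@dataclass(frozen=True)
class ReconProfile:
    """Smoothing/noise profile emulating one reconstruction style."""

    fwhm_mm: float
    noise_sd: float


#: OSEM-like reference is the identity; the 3DRP-like profile has the
#: largest noise amplitude so it is the most divergent variant.
DEFAULT_RECON_PROFILES: dict[str, ReconProfile] = {
    "OSEM": ReconProfile(fwhm_mm=0.0, noise_sd=0.0),
    "FOREIR": ReconProfile(fwhm_mm=4.0, noise_sd=0.05),
    "FOREFBP": ReconProfile(fwhm_mm=6.0, noise_sd=0.15),
    "3DRP": ReconProfile(fwhm_mm=6.0, noise_sd=0.40),
}


@dataclass
class CaseBundle:
    case_id: str
    spec: PhantomSpec
    base_volume: SUVVolume
    true_mask: ROIMask
    recon_variants: dict[str, SUVVolume]
    mask_variants: dict[str, ROIMask]


def _smooth_field(shape, spacing, scale_mm, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length scale_mm."""
    noise = rng.standard_normal(shape)
    sigma_vox = [scale_mm / s for s in spacing]
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    sd = f.std()
    if sd > 0:
        f /= sd
    return f


def _tumor_mask_array(spec: PhantomSpec) -> np.ndarray:
    shape = spec.grid_shape
    spacing = spec.voxel_spacing_mm
    for axis, (n, s) in enumerate(zip(shape, spacing)):
        if 2.0 * spec.tumor_radius_mm > n * s:
            raise ValueError(
                f"tumor diameter {2 * spec.tumor_radius_mm:.1f} mm exceeds grid extent "
                f"{n * s:.1f} mm along axis {axis}"
            )
    center = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    r2 = sum(((g - c) / spec.tumor_radius_mm) ** 2 for g, c in zip(grids, center))
    return r2 <= 1.0


def generate_tumor_volume(spec: PhantomSpec) -> SUVVolume:
    """Ellipsoidal tumor with a smoothed heterogeneity field on background.

    With ``heterogeneity_amp = 0`` every tumor voxel is exactly
    ``suv_tumor_mean``.  Values are clamped at 0.  Deterministic in
    (spec, spec.seed).
    """
    inside = _tumor_mask_array(spec)
    values = np.full(spec.grid_shape, spec.suv_background, dtype=float)
    values[inside] = spec.suv_tumor_mean
    if spec.heterogeneity_amp > 0:
        rng = np.random.default_rng(spec.seed)
        f = _smooth_field(spec.grid_shape, spec.voxel_spacing_mm,
                          spec.heterogeneity_scale_mm, rng)
        tumor_f = f[inside]
        # rescale so the in-tumor texture has exactly the requested SD
        sd = tumor_f.std()
        if sd > 0:
            tumor_f = (tumor_f - tumor_f.mean()) / sd * spec.heterogeneity_amp
        values[inside] = spec.suv_tumor_mean + tumor_f
    np.maximum(values, 0.0, out=values)
    return SUVVolume(values=values, spacing_mm=spec.voxel_spacing_mm)


def true_tumor_mask(spec: PhantomSpec, label: str = "TRUE") -> ROIMask:
    return ROIMask(
        values=_tumor_mask_array(spec).astype(np.uint8),
        spacing_mm=spec.voxel_spacing_mm,
        label=label,
    )


def _dice_arrays(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def make_mask_variants(
    volume: SUVVolume,
    true_mask: ROIMask,
    perturbation_mm: tuple[float, ...] = (2.5, 4.0, 3.0),
    seed: int = 0,
    labels: tuple[str, ...] = DEFAULT_MASK_LABELS,
    dice_floor: float = 0.75,
    jitter_scale_mm: float = 10.0,
    max_retries: int = 8,
) -> dict[str, ROIMask]:
    """Morphologically perturbed copies of ``true_mask`` passing a Dice floor.

    The signed Euclidean distance field of the mask is perturbed by a smooth
    random field scaled to each variant's jitter magnitude (mm) and
    re-thresholded at zero, which preserves connectedness better than voxel
    flips.  If any variant (against the truth or pairwise) falls below the
    Dice floor, all jitters are halved and the draw retried; failure after
    ``max_retries`` raises.
    """
    if len(perturbation_mm) != len(labels):
        raise ValueError("need one perturbation magnitude per mask label")
    m = true_mask.as_bool()
    if not m.any():
        raise ValueError("true mask is empty")
    spacing = true_mask.spacing_mm
    sdist = ndimage.distance_transform_edt(m, sampling=spacing) - ndimage.distance_transform_edt(
        ~m, sampling=spacing
    )

    jitters = [float(j) for j in perturbation_mm]
    for attempt in range(max_retries + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        variants: dict[str, ROIMask] = {}
        for label, jit in zip(labels, jitters):
            if jit == 0.0:
                arr = m.copy()
            else:
                f = _smooth_field(m.shape, spacing, jitter_scale_mm, rng)
                arr = (sdist + jit * f) > 0
            variants[label] = ROIMask(arr.astype(np.uint8), spacing, label=label)

        arrays = [v.as_bool() for v in variants.values()]
        ok = all(v.any() for v in arrays)
        ok = ok and all(_dice_arrays(m, v) >= dice_floor for v in arrays)
        ok = ok and all(
            _dice_arrays(arrays[i], arrays[j]) >= dice_floor
            for i in range(len(arrays))
            for j in range(i + 1, len(arrays))
        )
        if ok:
            if attempt:
                logger.info(
                    "mask jitter reduced %d time(s) to satisfy Dice floor %.2f",
                    attempt, dice_floor,
                )
            return variants
        jitters = [j / 2.0 for j in jitters]

    raise RuntimeError(
        f"could not satisfy Dice floor {dice_floor} after {max_retries} retries"
    )


def make_recon_variants(
    volume: SUVVolume,
    profiles: dict[str, ReconProfile] | None = None,
    seed: int = 0,
    reference_label: str = "OSEM",
) -> dict[str, SUVVolume]:
    """Four smoothing/noise image variants of ``volume``.

    Exactly four profiles are required and the reference label must map to
    the identity profile (no smoothing, no noise).  Non-reference variants
    are the volume convolved with a profile-specific Gaussian kernel plus
    additive Gaussian noise, clamped at 0.
    """
    if profiles is None:
        profiles = DEFAULT_RECON_PROFILES
    if len(profiles) != 4:
        raise ValueError(f"exactly 4 reconstruction profiles required, got {len(profiles)}")
    if reference_label not in profiles:
        raise ValueError(f"reference profile {reference_label!r} missing")
    ref = profiles[reference_label]
    if ref.fwhm_mm != 0.0 or ref.noise_sd != 0.0:
        raise ValueError("reference profile must be identity-like (fwhm 0, noise 0)")

    fwhm_to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out: dict[str, SUVVolume] = {}
    children = np.random.SeedSequence(seed).spawn(len(profiles))
    for child, (label, prof) in zip(children, sorted(profiles.items())):
        vals = volume.values
        if prof.fwhm_mm > 0:
            sigma_vox = [prof.fwhm_mm * fwhm_to_sigma / s for s in volume.spacing_mm]
            vals = ndimage.gaussian_filter(vals, sigma=sigma_vox, mode="nearest")
        if prof.noise_sd > 0:
            rng = np.random.default_rng(child)
            vals = vals + rng.normal(0.0, prof.noise_sd, size=vals.shape)
        vals = np.maximum(np.array(vals, dtype=float), 0.0)
        out[label] = SUVVolume(values=vals, spacing_mm=volume.spacing_mm, origin=volume.origin)
    return out


def generate_case(
    spec: PhantomSpec,
    case_id: str = "case000",
    perturbation_mm: tuple[float, ...] = (2.5, 4.0, 3.0),
    profiles: dict[str, ReconProfile] | None = None,
    dice_floor: float = 0.75,
    mask_labels: tuple[str, ...] = DEFAULT_MASK_LABELS,
) -> CaseBundle:
    """Full case: base volume + mask variants + recon variants, seeded by spec."""
    base = generate_tumor_volume(spec)
    truth = true_tumor_mask(spec)
    seq = np.random.SeedSequence([spec.seed, 1])
    masks = make_mask_variants(
        base, truth,
        perturbation_mm=perturbation_mm,
        seed=int(seq.generate_state(1)[0]),
        labels=mask_labels,
        dice_floor=dice_floor,
    )
    seq2 = np.random.SeedSequence([spec.seed, 2])
    recons = make_recon_variants(base, profiles=profiles, seed=int(seq2.generate_state(1)[0]))
    return CaseBundle(
        case_id=case_id,
        spec=spec,
        base_volume=base,
        true_mask=truth,
        recon_variants=recons,
        mask_variants=masks,
    )


def generate_cohort(
    n_cases: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    radius_range_mm: tuple[float, float] = (15.0, 28.0),
    amp_range: tuple[float, float] = (0.8, 2.5),
    **case_kwargs,
) -> list[CaseBundle]:
    """Cohort with per-case variation in tumor size and heterogeneity."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    cases = []
    for i in range(n_cases):
        spec = replace(
            base,
            tumor_radius_mm=float(rng.uniform(*radius_range_mm)),
            heterogeneity_amp=float(rng.uniform(*amp_range)),
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0]),
        )
        cases.append(generate_case(spec, case_id=f"case{i:03d}", **case_kwargs))
    return cases


def write_case_bundle(bundle: CaseBundle, out_dir: str | Path) -> dict:
    """Write one bundle as NIfTI files; returns its manifest entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entry = {
        "case_id": bundle.case_id,
        "seed": bundle.spec.seed,
        "spacing_mm": list(bundle.spec.voxel_spacing_mm),
        "recon_variants": {},
        "mask_variants": {},
    }
    for label, vol in bundle.recon_variants.items():
        fn = f"{bundle.case_id}_recon_{label}.nii.gz"
        write_volume(vol, out_dir / fn)
        entry["recon_variants"][label] = fn
    for label, msk in bundle.mask_variants.items():
        fn = f"{bundle.case_id}_mask_{label}.nii.gz"
        write_mask(msk, out_dir / fn)
        entry["mask_variants"][label] = fn
    return entry


def write_cohort(bundles: list[CaseBundle], out_dir: str | Path) -> Path:
    """Write a cohort plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"cases": [write_case_bundle(b, out_dir) for b in bundles]}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
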