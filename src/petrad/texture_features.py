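"""Texture matrices (GLCM, GLRLM, GLSZM, NGTDM) and their 53 features.

All matrices are built from a :class:`~petrad.discretize.DiscretizedROI`
restricted to its mask.  Co-occurrence and run-length statistics are pooled
over the 13 unique one-voxel 3D displacement directions (one representative
per axis-symmetric pair); size zones use 26-connectivity; neighborhood
gray-tone differences use a 7x7 in-plane window restricted to in-mask
neighbors (a 3D 7x7x7 window is available but off by default).

The feature catalogue is fixed at 26 GLCM + 11 GLRLM + 11 GLSZM + 5 NGTDM
named values; see ``GLCM_FEATURE_NAMES`` etc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = [
    "DIRECTIONS_3D",
    "direction_set",
    "build_glcm",
    "glcm_features",
    "build_glrlm",
    "glrlm_features",
    "build_glszm",
    "glszm_features",
    "build_ngtdm",
    "ngtdm_features",
    "texture_features",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "GLSZM_FEATURE_NAMES",
    "NGTDM_FEATURE_NAMES",
]

EPS = 1e-12


def direction_set() -> tuple[tuple[int, int, int], ...]:
    """The 13 unique one-voxel 3D displacements up to sign symmetry.

    All vectors with components in {-1, 0, 1}, excluding the zero vector,
    keeping one representative per +/- pair (the one whose first nonzero
    component is positive).
    """
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                v = (dx, dy, dz)
                if v == (0, 0, 0):
                    continue
                first = next(c for c in v if c != 0)
                if first > 0:
                    dirs.append(v)
    return tuple(dirs)


DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = direction_set()
assert len(DIRECTIONS_3D) == 13


def _crop_to_mask(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Levels and mask cropped to the mask bounding box (cheap, lossless)."""
    idx = np.argwhere(d.mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return d.levels[sl], d.mask[sl]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def _offset_slices(shape, off):
    """Slices (src, dst) selecting voxel pairs separated by ``off``."""
    src, dst = [], []
    for n, o in zip(shape, off):
        if o == 0:
            src.append(slice(0, n))
            dst.append(slice(0, n))
        elif o > 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def build_glcm(
    d: DiscretizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> np.ndarray:
    """Symmetric, normalized Ng x Ng co-occurrence matrix pooled over directions.

    Pairs with either member outside the mask are skipped.  Raises if the ROI
    yields no valid pair (e.g. a single isolated voxel).
    """
    levels, mask = _crop_to_mask(d)
    ng = d.ng
    counts = np.zeros((ng, ng), dtype=np.int64)
    for off in directions:
        src, dst = _offset_slices(levels.shape, off)
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        flat = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng)
        counts += flat
        counts += flat.T  # both orientations -> symmetric matrix
    total = counts.sum()
    if total == 0:
        raise ValueError(
            "GLCM undefined: ROI produced no in-mask voxel pairs "
            "(single-voxel or fully disconnected ROI)"
        )
    return counts / float(total)


GLCM_FEATURE_NAMES = (
    "glcm_joint_maximum",
    "glcm_joint_average",
    "glcm_joint_variance",
    "glcm_entropy",
    "glcm_angular_second_moment",
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_inverse_difference",
    "glcm_inverse_difference_normalized",
    "glcm_inverse_difference_moment",
    "glcm_inverse_difference_moment_normalized",
    "glcm_inverse_variance",
    "glcm_correlation",
    "glcm_autocorrelation",
    "glcm_cluster_tendency",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_difference_average",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_mcc",
)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_features(glcm: np.ndarray) -> dict[str, float]:
    """The 26 co-occurrence features of the catalogue.

    ``glcm_joint_average`` is the second-order mean; ``glcm_entropy`` the
    second-order (joint) entropy.  The matrix must be normalized.
    """
    p = np.asarray(glcm, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalized to sum 1")
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)  # symmetric => px == py
    py = p.sum(axis=0)
    mu = float(np.sum(ii * p))
    mux = float(np.sum(i * px))
    muy = float(np.sum(i * py))
    sigx = float(np.sqrt(np.sum((i - mux) ** 2 * px)))
    sigy = float(np.sqrt(np.sum((i - muy) ** 2 * py)))

    # diagonal/cross-diagonal marginals
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())

    absdiff = np.abs(ii - jj)
    sqdiff = (ii - jj) ** 2

    hxy = _entropy(p.ravel())
    hx = _entropy(px)
    hy = _entropy(py)
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(pxpy[nz])))
    nz2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2])))

    feats: dict[str, float] = {}
    feats["glcm_joint_maximum"] = float(p.max())
    feats["glcm_joint_average"] = mu
    feats["glcm_joint_variance"] = float(np.sum((ii - mu) ** 2 * p))
    feats["glcm_entropy"] = hxy
    feats["glcm_angular_second_moment"] = float(np.sum(p**2))
    feats["glcm_contrast"] = float(np.sum(sqdiff * p))
    feats["glcm_dissimilarity"] = float(np.sum(absdiff * p))
    feats["glcm_inverse_difference"] = float(np.sum(p / (1.0 + absdiff)))
    feats["glcm_inverse_difference_normalized"] = float(np.sum(p / (1.0 + absdiff / ng)))
    feats["glcm_inverse_difference_moment"] = float(np.sum(p / (1.0 + sqdiff)))
    feats["glcm_inverse_difference_moment_normalized"] = float(
        np.sum(p / (1.0 + sqdiff / ng**2))
    )
    off_diag = absdiff > 0
    feats["glcm_inverse_variance"] = float(np.sum(p[off_diag] / sqdiff[off_diag]))
    if sigx > EPS and sigy > EPS:
        feats["glcm_correlation"] = float(
            (np.sum(ii * jj * p) - mux * muy) / (sigx * sigy)
        )
    else:
        feats["glcm_correlation"] = 0.0
    feats["glcm_autocorrelation"] = float(np.sum(ii * jj * p))
    feats["glcm_cluster_tendency"] = float(np.sum((ii + jj - mux - muy) ** 2 * p))
    feats["glcm_cluster_shade"] = float(np.sum((ii + jj - mux - muy) ** 3 * p))
    feats["glcm_cluster_prominence"] = float(np.sum((ii + jj - mux - muy) ** 4 * p))
    sa = float(np.sum(k_sum * p_sum))
    feats["glcm_sum_average"] = sa
    feats["glcm_sum_variance"] = float(np.sum((k_sum - sa) ** 2 * p_sum))
    feats["glcm_sum_entropy"] = _entropy(p_sum)
    da = float(np.sum(k_diff * p_diff))
    feats["glcm_difference_average"] = da
    feats["glcm_difference_variance"] = float(np.sum((k_diff - da) ** 2 * p_diff))
    feats["glcm_difference_entropy"] = _entropy(p_diff)
    denom = max(hx, hy)
    feats["glcm_imc1"] = float((hxy - hxy1) / denom) if denom > EPS else 0.0
    feats["glcm_imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    feats["glcm_mcc"] = _mcc(p, px, py)
    return feats


def _mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Maximal correlation coefficient (sqrt of 2nd-largest eigenvalue of Q)."""
    keep = px > 0
    if keep.sum() < 2:
        return 1.0  # single occupied level: perfect trivial correlation
    pk = p[np.ix_(keep, keep)]
    pxk = px[keep]
    pyk = py[keep]
    q = (pk / pxk[:, None]) @ (pk / pyk[:, None]).T
    ev = np.sort(np.abs(np.linalg.eigvals(q)))
    second = ev[-2] if ev.size >= 2 else 0.0
    return float(np.sqrt(max(0.0, min(1.0, second.real))))


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def build_glrlm(
    d: DiscretizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> np.ndarray:
    """Run-length matrix (Ng x max run length) summed over directions.

    A run is a maximal sequence of in-mask voxels sharing one level along a
    direction; runs break at mask boundaries.  Entries are counts.
    """
    levels, mask = _crop_to_mask(d)
    if not mask.any():
        raise ValueError("empty ROI")
    shape = levels.shape
    runs: dict[tuple[int, int], int] = {}
    coords = np.argwhere(mask)
    coord_set_levels = {}  # (x,y,z) -> level for quick membership
    for x, y, z in coords:
        coord_set_levels[(int(x), int(y), int(z))] = int(levels[x, y, z])

    def in_run(pos, lv):
        return coord_set_levels.get(pos) == lv

    for off in directions:
        for (x, y, z), lv in coord_set_levels.items():
            prev = (x - off[0], y - off[1], z - off[2])
            if in_run(prev, lv):
                continue  # not a run start
            length = 1
            nxt = (x + off[0], y + off[1], z + off[2])
            while in_run(nxt, lv):
                length += 1
                nxt = (nxt[0] + off[0], nxt[1] + off[1], nxt[2] + off[2])
            runs[(lv, length)] = runs.get((lv, length), 0) + 1

    rmax = max(l for (_, l) in runs)
    mat = np.zeros((d.ng, rmax), dtype=np.int64)
    for (lv, length), c in runs.items():
        mat[lv - 1, length - 1] = c
    return mat


GLRLM_FEATURE_NAMES = (
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_glnu",
    "glrlm_rlnu",
    "glrlm_rpc",
    "glrlm_lgre",
    "glrlm_hgre",
    "glrlm_srlge",
    "glrlm_srhge",
    "glrlm_lrlge",
    "glrlm_lrhge",
)


def glrlm_features(glrlm: np.ndarray, n_directions: int = len(DIRECTIONS_3D)) -> dict[str, float]:
    """11 Galloway-family run-length features.

    ``glrlm_rpc`` (run percentage) uses the number of voxels scored, which for
    full-direction pooling is ``n_directions x`` the in-mask voxel count and
    equals the run-length-weighted matrix sum.
    """
    r = np.asarray(glrlm, dtype=float)
    nr = r.sum()
    if nr <= 0:
        raise ValueError("empty run-length matrix")
    ng, rmax = r.shape
    i = np.arange(1, ng + 1)[:, None]
    l = np.arange(1, rmax + 1)[None, :]
    np_voxels_scored = float(np.sum(r * l))

    f: dict[str, float] = {}
    f["glrlm_sre"] = float(np.sum(r / l**2) / nr)
    f["glrlm_lre"] = float(np.sum(r * l**2) / nr)
    f["glrlm_glnu"] = float(np.sum(r.sum(axis=1) ** 2) / nr)
    f["glrlm_rlnu"] = float(np.sum(r.sum(axis=0) ** 2) / nr)
    f["glrlm_rpc"] = float(nr / np_voxels_scored)
    f["glrlm_lgre"] = float(np.sum(r / i**2) / nr)
    f["glrlm_hgre"] = float(np.sum(r * i**2) / nr)
    f["glrlm_srlge"] = float(np.sum(r / (i**2 * l**2)) / nr)
    f["glrlm_srhge"] = float(np.sum(r * i**2 / l**2) / nr)
    f["glrlm_lrlge"] = float(np.sum(r * l**2 / i**2) / nr)
    f["glrlm_lrhge"] = float(np.sum(r * i**2 * l**2) / nr)
    return f


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def build_glszm(d: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix (Ng x max zone size) under 26-connectivity."""
    levels, mask = _crop_to_mask(d)
    if not mask.any():
        raise ValueError("empty ROI")
    zones: dict[tuple[int, int], int] = {}
    present = np.unique(levels[mask])
    for lv in present:
        lab, n = ndimage.label(levels == lv, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones[(int(lv), int(s))] = zones.get((int(lv), int(s)), 0) + 1
    smax = max(s for (_, s) in zones)
    mat = np.zeros((d.ng, smax), dtype=np.int64)
    for (lv, s), c in zones.items():
        mat[lv - 1, s - 1] = c
    return mat


GLSZM_FEATURE_NAMES = (
    "glszm_sae",
    "glszm_lae",
    "glszm_lie",
    "glszm_hie",
    "glszm_lisae",
    "glszm_hisae",
    "glszm_lilae",
    "glszm_hilae",
    "glszm_iv",
    "glszm_szv",
    "glszm_zp",
)


def glszm_features(glszm: np.ndarray) -> dict[str, float]:
    """11 size-zone features (small/large area, low/high intensity, crosses,
    intensity variability, size-zone variability, zone percentage)."""
    z = np.asarray(glszm, dtype=float)
    nz = z.sum()
    if nz <= 0:
        raise ValueError("empty size-zone matrix")
    ng, smax = z.shape
    i = np.arange(1, ng + 1)[:, None]
    s = np.arange(1, smax + 1)[None, :]
    n_voxels = float(np.sum(z * s))

    f: dict[str, float] = {}
    f["glszm_sae"] = float(np.sum(z / s**2) / nz)
    f["glszm_lae"] = float(np.sum(z * s**2) / nz)
    f["glszm_lie"] = float(np.sum(z / i**2) / nz)
    f["glszm_hie"] = float(np.sum(z * i**2) / nz)
    f["glszm_lisae"] = float(np.sum(z / (i**2 * s**2)) / nz)
    f["glszm_hisae"] = float(np.sum(z * i**2 / s**2) / nz)
    f["glszm_lilae"] = float(np.sum(z * s**2 / i**2) / nz)
    f["glszm_hilae"] = float(np.sum(z * i**2 * s**2) / nz)
    f["glszm_iv"] = float(np.sum(z.sum(axis=1) ** 2) / nz)
    f["glszm_szv"] = float(np.sum(z.sum(axis=0) ** 2) / nz)
    f["glszm_zp"] = float(nz / n_voxels)
    return f


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


@dataclass
class NGTDM:
    """Per-level occurrence counts ``n_i`` and summed deviations ``s_i``."""

    n: np.ndarray  # occurrences per level (index 0 -> level 1)
    s: np.ndarray  # summed |level - neighborhood mean| per level
    n_scored: int  # voxels contributing (those with >= 1 in-mask neighbor)


def build_ngtdm(
    d: DiscretizedROI,
    neighborhood_halfwidth: int = 3,
    three_d: bool = False,
) -> NGTDM:
    """Neighborhood gray-tone difference accumulators.

    For each in-mask voxel the average level of its in-mask neighbors inside
    a ``(2h+1) x (2h+1)`` in-plane window (center excluded; ``three_d=True``
    extends the window along the slice axis) is computed; voxels with no
    in-mask neighbor are skipped.
    """
    levels, mask = _crop_to_mask(d)
    if not mask.any():
        raise ValueError("empty ROI")
    h = int(neighborhood_halfwidth)
    size = (2 * h + 1, 2 * h + 1, 2 * h + 1 if three_d else 1)
    maskf = mask.astype(float)
    lv = levels.astype(float) * maskf
    nbr_sum = ndimage.uniform_filter(lv, size=size, mode="constant") * np.prod(size)
    nbr_cnt = ndimage.uniform_filter(maskf, size=size, mode="constant") * np.prod(size)
    # exclude the center voxel itself
    nbr_sum = nbr_sum - lv
    nbr_cnt = np.rint(nbr_cnt - maskf)

    scored = mask & (nbr_cnt > 0.5)
    if not scored.any():
        raise ValueError("NGTDM undefined: every in-mask voxel lacks in-mask neighbors")
    avg = nbr_sum[scored] / nbr_cnt[scored]
    lvls = levels[scored]
    dev = np.abs(lvls - avg)
    n = np.bincount(lvls, minlength=d.ng + 1)[1:].astype(np.int64)
    s = np.zeros(d.ng)
    np.add.at(s, lvls - 1, dev)
    return NGTDM(n=n, s=s, n_scored=int(scored.sum()))


NGTDM_FEATURE_NAMES = (
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_complexity",
    "ngtdm_busyness",
    "ngtdm_strength",
)


def ngtdm_features(m: NGTDM, eps: float = EPS) -> dict[str, float]:
    """Amadasun-King features with an ``eps`` guard on vanishing denominators.

    A perfectly homogeneous ROI has all ``s_i = 0``; coarseness then returns
    the finite sentinel ``1/eps``.
    """
    n_total = m.n.sum()
    if n_total <= 0:
        raise ValueError("empty NGTDM")
    p = m.n / float(n_total)
    s = m.s
    ng = len(p)
    i = np.arange(1, ng + 1)
    occupied = p > 0
    ngp = int(occupied.sum())

    f: dict[str, float] = {}
    f["ngtdm_coarseness"] = float(1.0 / (eps + np.sum(p * s)))

    if ngp > 1:
        ii, jj = np.meshgrid(i, i, indexing="ij")
        pi, pj = np.meshgrid(p, p, indexing="ij")
        both = (pi > 0) & (pj > 0)
        f["ngtdm_contrast"] = float(
            (np.sum(pi[both] * pj[both] * (ii[both] - jj[both]) ** 2) / (ngp * (ngp - 1)))
            * (np.sum(s) / m.n_scored)
        )
        ipi = i * p
        f["ngtdm_busyness"] = float(
            np.sum(p * s)
            / max(eps, np.sum(np.abs(ipi[:, None] - ipi[None, :])[both]))
        )
        ps = p * s
        num = np.abs(ii - jj) * (ps[:, None] + ps[None, :])
        den = m.n_scored * (pi + pj)
        f["ngtdm_complexity"] = float(np.sum(num[both] / den[both]))
        f["ngtdm_strength"] = float(
            np.sum(((pi + pj) * (ii - jj) ** 2)[both]) / (eps + np.sum(s))
        )
    else:
        f["ngtdm_contrast"] = 0.0
        f["ngtdm_busyness"] = 0.0
        f["ngtdm_complexity"] = 0.0
        f["ngtdm_strength"] = 0.0
    return f


# ---------------------------------------------------------------------------
# Aggregate
# ---------------------------------------------------------------------------


def texture_features(
    d: DiscretizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
    neighborhood_halfwidth: int = 3,
    ngtdm_three_d: bool = False,
) -> dict[str, float]:
    """All 53 textural features (26 GLCM + 11 GLRLM + 11 GLSZM + 5 NGTDM)."""
    feats: dict[str, float] = {}
    feats.update(glcm_features(build_glcm(d, directions)))
    feats.update(glrlm_features(build_glrlm(d, directions), n_directions=len(directions)))
    feats.update(glszm_features(build_glszm(d)))
    feats.update(ngtdm_features(build_ngtdm(d, neighborhood_halfwidth, ngtdm_three_d)))
    return feats
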