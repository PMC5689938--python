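"""Volume, mask, and feature-table I/O with geometry validation.

Volumes are kept in a canonical ``(x, y, z)`` voxel-index order with 0-based
integer coordinates; physical geometry is carried as a per-axis spacing in mm
and an origin offset in mm.  NIfTI-1 (``.nii``/``.nii.gz``) and NRRD
(``.nrrd``) files are supported.  Feature tables are long-format CSV with a
JSON mirror.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SUVVolume",
    "ROIMask",
    "FeatureTable",
    "FEATURE_TABLE_COLUMNS",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "read_feature_table",
    "write_feature_table",
]

#: Long-format feature-table schema: one row per (case, variant, feature).
FEATURE_TABLE_COLUMNS = (
    "case_id",
    "segmentation",
    "gray_level",
    "recon",
    "feature_name",
    "value",
)

_VARIANT_KEY = ("case_id", "segmentation", "gray_level", "recon", "feature_name")


@dataclass
class SUVVolume:
    """3D scalar grid of SUV values (g/ml) with physical geometry."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.values.ndim}D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite voxels (NaN/Inf)")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class ROIMask:
    """Binary 3D mask aligned to a :class:`SUVVolume`."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    label: str = ""
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got {arr.ndim}D")
        # any nonzero voxel is foreground
        self.values = (arr != 0).astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)


def check_geometry(volume: SUVVolume, mask: ROIMask, *, rtol: float = 1e-5) -> None:
    """Raise if a mask does not share grid shape and spacing with its volume."""
    if volume.shape != mask.shape:
        raise ValueError(
            f"geometry mismatch: volume shape {volume.shape} vs mask shape {mask.shape}"
        )
    if not np.allclose(volume.spacing_mm, mask.spacing_mm, rtol=rtol):
        raise ValueError(
            f"geometry mismatch: volume spacing {volume.spacing_mm} "
            f"vs mask spacing {mask.spacing_mm}"
        )


# ---------------------------------------------------------------------------
# NIfTI / NRRD readers and writers
# ---------------------------------------------------------------------------


def _is_nrrd(path: Path) -> bool:
    return path.suffix.lower() == ".nrrd"


def _read_any(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nrrd(path):
        return _read_nrrd(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return data, spacing, origin


def read_volume(path: str | Path) -> SUVVolume:
    """Read a 3D scalar volume from NIfTI or NRRD."""
    data, spacing, origin = _read_any(path)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    return SUVVolume(values=data.astype(float), spacing_mm=spacing, origin=origin)


def read_mask(path: str | Path, label: str = "") -> ROIMask:
    """Read a binary mask; any nonzero voxel is coerced to 1."""
    data, spacing, origin = _read_any(path)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: mask contains non-finite voxels")
    return ROIMask(values=data, spacing_mm=spacing, label=label, origin=origin)


def _affine(spacing: tuple, origin: tuple) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: SUVVolume, path: str | Path) -> None:
    path = Path(path)
    if _is_nrrd(path):
        _write_nrrd(path, volume.values.astype(np.float64), volume.spacing_mm, volume.origin)
        return
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine(volume.spacing_mm, volume.origin))
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def write_mask(mask: ROIMask, path: str | Path) -> None:
    path = Path(path)
    if _is_nrrd(path):
        _write_nrrd(path, mask.values.astype(np.uint8), mask.spacing_mm, mask.origin)
        return
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing_mm, mask.origin))
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


# Minimal NRRD codec (raw/gzip encodings, attached data, little-endian).
# SimpleITK/pynrrd are not available in the runtime environment, and the
# subset of NRRD needed here is small enough to implement directly.

_NRRD_TYPES = {
    "double": np.float64,
    "float": np.float32,
    "unsigned char": np.uint8,
    "uchar": np.uint8,
    "short": np.int16,
    "int": np.int32,
}


def _write_nrrd(path: Path, data: np.ndarray, spacing: tuple, origin: tuple) -> None:
    typename = {np.dtype(np.float64): "double", np.dtype(np.uint8): "unsigned char"}[data.dtype]
    dir_strs = []
    for i in range(3):
        vec = [0.0, 0.0, 0.0]
        vec[i] = spacing[i]
        dir_strs.append("(" + ",".join(str(v) for v in vec) + ")")
    header = (
        "NRRD0004\n"
        f"type: {typename}\n"
        "dimension: 3\n"
        "space: left-posterior-superior\n"
        f"sizes: {data.shape[0]} {data.shape[1]} {data.shape[2]}\n"
        f"space directions: {' '.join(dir_strs)}\n"
        "kinds: domain domain domain\n"
        "endian: little\n"
        "encoding: gzip\n"
        f"space origin: ({origin[0]},{origin[1]},{origin[2]})\n"
        "\n"
    )
    payload = gzip.compress(np.asfortranarray(data).tobytes(order="F"))
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


def _read_nrrd(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    raw = path.read_bytes()
    end = raw.find(b"\n\n")
    if end < 0:
        raise ValueError(f"{path}: malformed NRRD header")
    header_lines = raw[:end].decode("ascii", errors="replace").splitlines()
    if not header_lines or not header_lines[0].startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file")
    fields: dict[str, str] = {}
    for line in header_lines[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, val = line.partition(":")
        fields[key.strip().lower()] = val.strip()
    if int(fields.get("dimension", "0")) != 3:
        raise ValueError(f"{path}: expected a 3D image")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    dtype = _NRRD_TYPES.get(fields.get("type", "double"))
    if dtype is None:
        raise ValueError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    encoding = fields.get("encoding", "raw")
    body = raw[end + 2 :]
    if encoding == "gzip":
        body = gzip.decompress(body)
    elif encoding != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    data = np.frombuffer(body, dtype=dtype, count=int(np.prod(sizes)))
    data = data.reshape(sizes, order="F")
    spacing = [1.0, 1.0, 1.0]
    if "space directions" in fields:
        vecs = fields["space directions"].replace("(", " ").replace(")", " ").split()
        for i, v in enumerate(vecs[:3]):
            comps = [float(c) for c in v.split(",")]
            spacing[i] = float(np.linalg.norm(comps))
    origin = (0.0, 0.0, 0.0)
    if "space origin" in fields:
        comps = fields["space origin"].strip("() ").split(",")
        origin = tuple(float(c) for c in comps)
    return np.array(data), tuple(spacing), origin


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Long-format table of feature values per (case, variant) combination.

    Columns: ``case_id, segmentation, gray_level, recon, feature_name, value``.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(FEATURE_TABLE_COLUMNS)))

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table is missing column(s): {', '.join(missing)}")
        self.data = self.data[list(FEATURE_TABLE_COLUMNS)].reset_index(drop=True)
        if len(self.data):
            self.data["gray_level"] = self.data["gray_level"].astype(int)
            self.data["value"] = self.data["value"].astype(float)
            dup = self.data.duplicated(subset=list(_VARIANT_KEY))
            if dup.any():
                row = self.data.loc[dup.idxmax()]
                raise ValueError(
                    "duplicate (case, variant, feature) row: "
                    f"{tuple(row[c] for c in _VARIANT_KEY)}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return sorted(self.data["feature_name"].unique())

    @property
    def case_ids(self) -> list:
        return sorted(self.data["case_id"].unique())

    def subset(self, **criteria) -> "FeatureTable":
        df = self.data
        for col, val in criteria.items():
            df = df[df[col] == val]
        return FeatureTable(df.copy())

    def pivot(self, variant_column: str) -> pd.DataFrame:
        """Wide view: rows (case_id, feature_name), one column per variant."""
        return self.data.pivot_table(
            index=["case_id", "feature_name"],
            columns=variant_column,
            values="value",
            aggfunc="first",
        )

    @staticmethod
    def concat(tables: list["FeatureTable"]) -> "FeatureTable":
        frames = [t.data for t in tables if len(t.data)]
        if not frames:
            return FeatureTable()
        return FeatureTable(pd.concat(frames, ignore_index=True))


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV (or a JSON mirror when given ``.json``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(table.data.to_dict(orient="records"), indent=1))
    else:
        table.data.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
        if df.empty:
            return FeatureTable()
        return FeatureTable(df)
    df = pd.read_csv(path)
    return FeatureTable(df)
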