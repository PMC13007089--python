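"""NIfTI volume I/O, grid validation, resampling and cohort manifests.

All downstream computation happens in voxel space; per-axis spacing (mm)
carries the physical metric, and the affine is kept only so outputs land
in the same world frame as the inputs.  Coordinates are 0-based voxel
indices throughout; distance bins are half-open intervals (lo, hi].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

GROUPS = ("WHO_I", "WHO_II", "GBM")

#: manifest columns, in order
MANIFEST_COLUMNS = ["case_id", "group", "g_storage", "g_loss", "tumor_mask", "brain_mask"]


class GridError(ValueError):
    """Raised when volumes disagree on shape/affine or a grid is malformed."""


@dataclass(frozen=True)
class GridGeometry:
    """Voxel grid: shape, per-axis spacing in mm, and world affine."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise GridError(f"shape must be a positive integer triple, got {self.shape}")
        for ax, sp in enumerate(self.spacing):
            if not np.isfinite(sp):
                raise GridError(f"non-finite spacing on axis {ax}: {sp}")
            if sp <= 0:
                raise GridError(f"non-positive spacing on axis {ax}: {sp}")
        norms = np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)
        if not np.allclose(norms, self.spacing, atol=1e-6):
            raise GridError(
                f"spacing {self.spacing} not recoverable from affine column norms {tuple(norms)}"
            )

    @classmethod
    def isotropic(cls, shape, spacing_mm: float = 3.0) -> "GridGeometry":
        shape = tuple(int(s) for s in shape)
        aff = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
        return cls(shape=shape, spacing=(spacing_mm,) * 3, affine=aff)

    def same_grid_as(self, other: "GridGeometry", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


@dataclass
class ElastogramCase:
    """One subject: G'/G'' volumes (kPa), tumor and brain masks, group label."""

    case_id: str
    group: str
    g_storage: np.ndarray
    g_loss: np.ndarray
    tumor_mask: np.ndarray
    brain_mask: np.ndarray
    geometry: GridGeometry
    #: parenchyma erosion policy for this case (meningioma groups erode by 1 voxel)
    erode_parenchyma: bool | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        vols = [self.g_storage, self.g_loss, self.tumor_mask, self.brain_mask]
        for v in vols:
            if v.shape != self.geometry.shape:
                raise GridError(
                    f"case {self.case_id}: volume shape {v.shape} != grid {self.geometry.shape}"
                )
        self.tumor_mask = self.tumor_mask.astype(np.uint8)
        self.brain_mask = self.brain_mask.astype(np.uint8)
        n_tum = int(self.tumor_mask.sum())
        if n_tum == 0:
            raise ValueError(f"case {self.case_id}: empty tumor mask")
        overlap = int((self.tumor_mask & self.brain_mask).sum()) / n_tum
        if overlap < 0.5:
            raise ValueError(
                f"case {self.case_id}: tumor/brain overlap {overlap:.2f} < 0.5 — masks misaligned?"
            )
        if self.erode_parenchyma is None:
            self.erode_parenchyma = self.group in ("WHO_I", "WHO_II")


@dataclass
class CohortManifest:
    """Cohort table: one record per case with the four volume paths."""

    records: pd.DataFrame
    root: Path | None = None

    def __post_init__(self):
        missing = [c for c in MANIFEST_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        ids = self.records["case_id"]
        if ids.duplicated().any():
            raise ValueError(f"duplicate case ids: {sorted(ids[ids.duplicated()])}")
        bad = set(self.records["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups in manifest: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def iter_cases(self) -> Iterator[ElastogramCase]:
        for _, row in self.records.iterrows():
            yield load_case(row, root=self.root)


def read_volume(path) -> tuple[np.ndarray, GridGeometry]:
    """Read a NIfTI-1/2 volume in native voxel order with its affine."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except nib.filebasedimages.ImageFileError as exc:
        raise GridError(f"{path} is not a NIfTI file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        data = np.squeeze(data)
        if data.ndim != 3:
            raise GridError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    for ax, z in enumerate(zooms):
        if not np.isfinite(z) or z <= 0:
            raise GridError(f"{path}: invalid spacing on axis {ax}: {z}")
    geom = GridGeometry(shape=tuple(data.shape), spacing=tuple(float(z) for z in zooms),
                        affine=np.asarray(img.affine, dtype=float))
    return data, geom


def write_volume(path, data: np.ndarray, geometry: GridGeometry) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), geometry.affine)
    img.header.set_zooms(geometry.spacing)
    nib.save(img, str(path))


def validate_grid(geometry: GridGeometry, reference: GridGeometry, name: str = "volume") -> None:
    """Hard error if a volume does not live on the reference grid."""
    if geometry.shape != reference.shape:
        raise GridError(f"{name}: shape {geometry.shape} != reference {reference.shape}")
    if not np.allclose(geometry.affine, reference.affine, atol=1e-4):
        raise GridError(f"{name}: affine differs from reference beyond 1e-4")


def resample_to_reference(volume: np.ndarray, source: GridGeometry, reference: GridGeometry,
                          order: str = "linear", is_binary: bool = False) -> np.ndarray:
    """Regrid an already-aligned volume onto a reference grid.

    `order` is 'nearest' or 'linear'; binary masks must use nearest so they
    stay binary.  Linear output never exceeds the input range.
    """
    if order not in ("nearest", "linear"):
        raise ValueError(f"order must be 'nearest' or 'linear', got {order!r}")
    if is_binary and order != "nearest":
        raise ValueError("binary masks must be resampled with nearest-neighbor interpolation")
    if source.same_grid_as(reference):
        return volume.copy()
    # map reference voxel index -> world -> source voxel index
    mat = np.linalg.inv(source.affine) @ reference.affine
    out = ndimage.affine_transform(
        np.asarray(volume, dtype=float), mat[:3, :3], offset=mat[:3, 3],
        output_shape=reference.shape, order=0 if order == "nearest" else 1,
        mode="constant", cval=0.0,
    )
    if is_binary:
        out = (out > 0.5).astype(np.uint8)
    return out


def load_mask(path) -> tuple[np.ndarray, GridGeometry]:
    """Load a mask volume, thresholding fractional values at >0.5 into uint8."""
    data, geom = read_volume(path)
    return (np.asarray(data, dtype=float) > 0.5).astype(np.uint8), geom


def load_case(record, root=None) -> ElastogramCase:
    """Assemble an ElastogramCase from one manifest row, validating the grid."""
    root = Path(root) if root is not None else Path(".")

    def _p(col):
        p = Path(record[col])
        return p if p.is_absolute() else root / p

    g_storage, geom = read_volume(_p("g_storage"))
    g_loss, geom_l = read_volume(_p("g_loss"))
    tumor, geom_t = load_mask(_p("tumor_mask"))
    brain, geom_b = load_mask(_p("brain_mask"))
    for g, name in ((geom_l, "g_loss"), (geom_t, "tumor_mask"), (geom_b, "brain_mask")):
        validate_grid(g, geom, name=f"{record['case_id']}/{name}")
    return ElastogramCase(
        case_id=str(record["case_id"]), group=str(record["group"]),
        g_storage=np.asarray(g_storage, dtype=float),
        g_loss=np.asarray(g_loss, dtype=float),
        tumor_mask=tumor, brain_mask=brain, geometry=geom,
    )


def load_manifest(path) -> CohortManifest:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    return CohortManifest(records=df, root=path.parent)


def save_manifest(manifest: CohortManifest, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.records.to_csv(path, index=False)


def save_metrics(df: pd.DataFrame, path) -> None:
    """Tidy per-case metrics table, one row per case x threshold."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def save_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default, allow_nan=True))
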