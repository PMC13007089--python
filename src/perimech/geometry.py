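"""Tumor-interface region geometry.

Derives, from the tumor and brain masks, every spatial domain the analysis
uses: the parenchyma mask (brain minus tumor, optionally eroded by one
voxel), the one-voxel rim immediately outside the tumor, the 0-6 mm
peritumoral shell with its 2 mm skull guard, 2-mm-wide radial distance
bins out to 12 mm, and the axial slice of maximal tumor area.  Distances
are physical (mm), computed with an anisotropy-aware Euclidean distance
transform using the per-axis voxel spacing.  "Skull" is operationalized
as the brain-mask complement: the guard removes voxels within
``guard_mm`` of the brain-mask exterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

# face (6-)connectivity structuring element; thinnest physically adjacent
# layer on anisotropic grids.  26-connectivity available via rim_connectivity.
_FACE = ndimage.generate_binary_structure(3, 1)
_FULL = ndimage.generate_binary_structure(3, 3)


class RegionError(ValueError):
    """A derived region came out empty or inconsistent."""


@dataclass
class RegionMasks:
    parenchyma: np.ndarray        # binary
    rim: np.ndarray               # binary, region r
    shell: np.ndarray             # binary, region p (0-6 mm minus guard)
    guard: np.ndarray             # binary, within guard_mm of brain exterior
    dist_tumor_mm: np.ndarray     # EDT from tumor (0 inside tumor)
    radial_label: np.ndarray      # int, k=1..6 for bins (2(k-1), 2k], 0 elsewhere
    band: np.ndarray              # binary, 0 < d <= radial_max, parenchyma minus guard
    analysis_slice: int           # axial index of maximal tumor area


def anisotropic_edt(mask: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance (mm) from each background voxel to the nearest
    foreground voxel center; 0 on foreground."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RegionError("anisotropic_edt: empty mask, distance undefined")
    if mask.all():
        return np.zeros(mask.shape, dtype=float)
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def make_parenchyma_mask(brain_mask, tumor_mask, erode_voxels: int = 1,
                         apply_erosion: bool = True) -> np.ndarray:
    """Parenchyma = (optionally eroded) brain minus tumor.

    The erosion guards against partial-volume contamination at the
    cortical surface, so it is applied to the brain mask before the
    tumor is subtracted — eroding (brain minus tumor) would also strip
    the peritumoral layer and leave the rim empty.
    """
    brain = np.asarray(brain_mask, dtype=bool)
    tumor = np.asarray(tumor_mask, dtype=bool)
    if apply_erosion and erode_voxels > 0:
        brain = ndimage.binary_erosion(brain, structure=_FACE, iterations=erode_voxels)
    par = brain & ~tumor
    if not par.any():
        raise RegionError("parenchyma mask is empty after erosion")
    return par.astype(np.uint8)


def rim_mask(tumor_mask, parenchyma, connectivity: int = 1) -> np.ndarray:
    """One-voxel layer immediately outside the tumor, inside parenchyma."""
    tumor = np.asarray(tumor_mask, dtype=bool)
    if not tumor.any():
        raise RegionError("rim_mask: empty tumor")
    struct = _FACE if connectivity == 1 else _FULL
    dil = ndimage.binary_dilation(tumor, structure=struct)
    rim = dil & ~tumor & np.asarray(parenchyma, dtype=bool)
    if not rim.any():
        raise RegionError("rim is empty: tumor has no parenchymal neighbors")
    return rim.astype(np.uint8)


def guard_mask(brain_mask, spacing, guard_mm: float = 2.0) -> np.ndarray:
    """Voxels within guard_mm of the brain-mask exterior (skull proxy)."""
    brain = np.asarray(brain_mask, dtype=bool)
    if guard_mm <= 0:
        return np.zeros(brain.shape, dtype=np.uint8)
    # distance from each brain voxel to the nearest exterior voxel center
    dist_ext = ndimage.distance_transform_edt(brain, sampling=spacing)
    return ((dist_ext <= guard_mm) & brain).astype(np.uint8)


def shell_mask(dist_tumor_mm, parenchyma, guard, r_max_mm: float = 6.0) -> np.ndarray:
    """Peritumoral shell: 0 < d <= r_max_mm, in parenchyma, outside the guard."""
    d = np.asarray(dist_tumor_mm, dtype=float)
    shell = (d > 0) & (d <= r_max_mm) & np.asarray(parenchyma, dtype=bool) \
        & ~np.asarray(guard, dtype=bool)
    if not shell.any():
        raise RegionError("peritumoral shell is empty")
    return shell.astype(np.uint8)


def radial_labels(dist_tumor_mm, parenchyma, guard, bin_mm: float = 2.0,
                  r_max_mm: float = 12.0) -> np.ndarray:
    """Concentric distance bins: label k for d in (bin_mm*(k-1), bin_mm*k]."""
    d = np.asarray(dist_tumor_mm, dtype=float)
    domain = (d > 0) & (d <= r_max_mm) & np.asarray(parenchyma, dtype=bool) \
        & ~np.asarray(guard, dtype=bool)
    labels = np.zeros(d.shape, dtype=np.int32)
    # half-open (lo, hi]: ceil(d / bin) lands d exactly on a boundary in the lower bin
    labels[domain] = np.ceil(d[domain] / bin_mm - 1e-12).astype(np.int32)
    return labels


def max_tumor_slice(tumor_mask, axis: int = 2) -> int:
    """Axial index with maximal in-slice tumor area; ties -> lowest index."""
    tumor = np.asarray(tumor_mask, dtype=bool)
    if not tumor.any():
        raise RegionError("max_tumor_slice: empty tumor")
    counts = tumor.sum(axis=tuple(ax for ax in range(3) if ax != axis))
    return int(np.argmax(counts))


def build_region_masks(case, r_max_mm: float = 6.0, guard_mm: float = 2.0,
                       radial_max_mm: float = 12.0, bin_mm: float = 2.0,
                       erode_voxels: int = 1, rim_connectivity: int = 1) -> RegionMasks:
    """Derive all analysis regions for one case.

    Parenchyma erosion follows the case's ``erode_parenchyma`` policy
    (on for meningioma groups, off for GBM).
    """
    spacing = case.geometry.spacing
    par = make_parenchyma_mask(case.brain_mask, case.tumor_mask,
                               erode_voxels=erode_voxels,
                               apply_erosion=bool(case.erode_parenchyma))
    rim = rim_mask(case.tumor_mask, par, connectivity=rim_connectivity)
    guard = guard_mask(case.brain_mask, spacing, guard_mm=guard_mm)
    dist = anisotropic_edt(case.tumor_mask, spacing)
    shell = shell_mask(dist, par, guard, r_max_mm=r_max_mm)
    labels = radial_labels(dist, par, guard, bin_mm=bin_mm, r_max_mm=radial_max_mm)
    band = (labels > 0).astype(np.uint8)
    sl = max_tumor_slice(case.tumor_mask)
    return RegionMasks(parenchyma=par, rim=rim, shell=shell, guard=guard,
                       dist_tumor_mm=dist, radial_label=labels, band=band,
                       analysis_slice=sl)
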