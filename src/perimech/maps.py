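"""Per-case and group-average spatial probability maps.

Each case's thresholded instability slice is cropped to a fixed physical
patch (120 x 120 mm, centered on the tumor centroid of the maximal-area
axial slice), resampled to a uniform 256 x 256 grid, and reduced to
binary occupancy / skeleton / branch-point maps.  Group probability maps
are voxelwise means over the cases of a group; N-maps count how many
cases contributed data at each pixel.  Radius normalization rescales
each case to a common effective tumor radius R* before averaging so the
group topology is compared free of tumor-size confounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .metrics import _NEIGHBOR_KERNEL, slice_threshold_map


@dataclass
class CaseMaps:
    """Binary occupancy/skeleton/branch maps on the common patch grid."""

    occupancy: np.ndarray       # (grid_n, grid_n) bool
    skeleton: np.ndarray
    branch: np.ndarray
    valid: np.ndarray           # pixels whose source voxel lay inside the image
    patch_origin: tuple[float, float]   # mm, lower corner of the patch
    effective_radius_mm: float  # R_eff = sqrt(tumor slice area / pi)
    pixel_mm: float
    normalized: bool = False
    case_id: str = ""
    group: str = ""

    def __post_init__(self):
        if not (self.branch <= self.skeleton).all() or not (self.skeleton <= self.occupancy).all():
            raise ValueError("map subset chain violated: need B <= S <= O pointwise")


@dataclass
class GroupMaps:
    p_occ: np.ndarray
    p_skel: np.ndarray
    p_br: np.ndarray
    n_map: np.ndarray
    group: str
    n_cases: int
    normalized: bool
    #: fixed display ranges for occupancy / skeleton / branch probability
    display_ranges: tuple = ((0.0, 1.0), (0.0, 0.8), (0.0, 0.6))


def _skeleton_and_branch(occ: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """8-connected skeleton of a binary map and its branch points
    (skeleton pixels where three or more skeleton segments converge)."""
    skel = morphology.thin(morphology.skeletonize(occ))
    neighbors = ndimage.convolve(skel.astype(np.int8), _NEIGHBOR_KERNEL,
                                 mode="constant", cval=0)
    branch = skel & (neighbors >= 3)
    return skel, branch


def case_maps(field, masks, case, tau: float = 0.02, patch_mm: float = 120.0,
              grid_n: int = 256) -> CaseMaps:
    """Crop, regrid and binarize one case's thresholded instability slice.

    The patch is centered on the tumor centroid of the analysis slice and
    sampled with nearest neighbor; pixels falling outside the image are
    zero (and marked invalid).  An empty suprathreshold map yields
    all-zero maps with a warning — the case still enters group averages.
    """
    sl = masks.analysis_slice
    sx, sy = case.geometry.spacing[:2]
    binary = slice_threshold_map(field, sl, tau)
    tum2d = case.tumor_mask[:, :, sl].astype(bool)
    if not binary.any():
        warnings.warn(f"case {case.case_id}: empty suprathreshold map at tau={tau}")
    idx = np.argwhere(tum2d)
    centroid_mm = idx.mean(axis=0) * np.array([sx, sy])  # tumor slice centroid
    area_mm2 = idx.shape[0] * sx * sy
    r_eff = float(np.sqrt(area_mm2 / np.pi))

    pix = patch_mm / grid_n
    origin = centroid_mm - patch_mm / 2.0
    centers = origin[:, None] + (np.arange(grid_n) + 0.5)[None, :] * pix  # (2, grid_n)
    ix = np.round(centers[0] / sx).astype(int)
    iy = np.round(centers[1] / sy).astype(int)
    ok_x = (ix >= 0) & (ix < binary.shape[0])
    ok_y = (iy >= 0) & (iy < binary.shape[1])
    valid = ok_x[:, None] & ok_y[None, :]
    occ = np.zeros((grid_n, grid_n), dtype=bool)
    sub = np.ix_(np.flatnonzero(ok_x), np.flatnonzero(ok_y))
    occ[sub] = binary[np.ix_(ix[ok_x], iy[ok_y])]
    skel, branch = _skeleton_and_branch(occ)
    return CaseMaps(occupancy=occ, skeleton=skel, branch=branch, valid=valid,
                    patch_origin=(float(origin[0]), float(origin[1])),
                    effective_radius_mm=r_eff, pixel_mm=pix, normalized=False,
                    case_id=case.case_id, group=case.group)


def radius_normalize(cm: CaseMaps, r_star_mm: float = 20.0) -> CaseMaps:
    """Rescale a case's occupancy about the patch center to the common
    effective radius R*, then recompute skeleton and branch maps (so
    skeletons stay one pixel wide)."""
    if cm.effective_radius_mm <= 0:
        raise ValueError("radius_normalize: non-positive effective radius")
    f = r_star_mm / cm.effective_radius_mm
    if not (0.2 <= f <= 5.0):
        warnings.warn(f"radius_normalize: extreme scale factor {f:.2f} "
                      f"(R_eff={cm.effective_radius_mm:.1f} mm)")
    n = cm.occupancy.shape[0]
    c = (n - 1) / 2.0
    coords = c + (np.arange(n) - c) / f  # output pixel -> input pixel
    ii = np.round(coords).astype(int)
    ok = (ii >= 0) & (ii < n)
    occ = np.zeros_like(cm.occupancy)
    val = np.zeros_like(cm.valid)
    sub_out = np.ix_(np.flatnonzero(ok), np.flatnonzero(ok))
    sub_in = np.ix_(ii[ok], ii[ok])
    occ[sub_out] = cm.occupancy[sub_in]
    val[sub_out] = cm.valid[sub_in]
    skel, branch = _skeleton_and_branch(occ)
    return CaseMaps(occupancy=occ, skeleton=skel, branch=branch, valid=val,
                    patch_origin=cm.patch_origin, effective_radius_mm=r_star_mm,
                    pixel_mm=cm.pixel_mm, normalized=True,
                    case_id=cm.case_id, group=cm.group)


def group_probability_maps(cases: list[CaseMaps], group: str) -> GroupMaps:
    """Voxelwise means of the binary maps over a group's cases."""
    if not cases:
        raise ValueError("group_probability_maps: no cases")
    flags = {cm.normalized for cm in cases}
    if len(flags) > 1:
        raise ValueError("cannot average a mix of normalized and non-normalized maps")
    n_g = len(cases)
    p_occ = np.mean([cm.occupancy for cm in cases], axis=0)
    p_skel = np.mean([cm.skeleton for cm in cases], axis=0)
    p_br = np.mean([cm.branch for cm in cases], axis=0)
    n_map = np.sum([cm.valid for cm in cases], axis=0).astype(int)
    return GroupMaps(p_occ=p_occ, p_skel=p_skel, p_br=p_br, n_map=n_map,
                     group=group, n_cases=n_g, normalized=flags.pop())
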