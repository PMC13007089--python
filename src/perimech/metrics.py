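"""Per-case descriptors of the instability field.

Scalar summaries (median, p95, threshold fractions), histogram entropy,
radial persistence profiles and their AUC, the tail-AUC of the survival
function, and 2D morphology/topology of the thresholded field on the
axial slice of maximal tumor area: isoperimetric ratio, convexity,
skeleton length density and branch-point density, plus the threshold
sweep and morphological-opening robustness variants and the rim-shell
modulus contrasts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure, morphology

from .instability import InstabilityField, damping_ratio, negative_fraction

DEFAULT_THRESHOLDS = (0.015, 0.020, 0.025, 0.030)
PRIMARY_TAU = 0.02

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def scalar_summaries(field: InstabilityField, thresholds=(0.02, 0.05)) -> dict:
    """Median/p95 over valid shell voxels (negatives included) and
    suprathreshold fractions #{I > tau} / #{valid}."""
    vals = field.shell_values
    if vals.size == 0:
        raise ValueError("scalar_summaries: no valid shell voxels")
    out = {"median_I": float(np.median(vals)), "p95_I": float(np.percentile(vals, 95))}
    for tau in thresholds:
        key = f"frac_above_{str(tau).replace('0.', '').ljust(3, '0')}"
        out[key] = float(np.count_nonzero(vals > tau) / vals.size)
    return out


def frac_above(field: InstabilityField, tau: float) -> float:
    vals = field.shell_values
    return float(np.count_nonzero(vals > tau) / vals.size)


def histogram_entropy(field: InstabilityField, n_bins: int = 32,
                      value_range=(0.0, 0.4)) -> float:
    """Shannon entropy (bits) of the I histogram; voxels outside the
    range are excluded, empty bins contribute nothing."""
    vals = field.shell_values
    lo, hi = value_range
    vals = vals[(vals >= lo) & (vals <= hi)]
    if vals.size == 0:
        warnings.warn("histogram_entropy: no voxels inside the histogram range")
        return float("nan")
    counts, _ = np.histogram(vals, bins=n_bins, range=value_range)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def radial_profile(field: InstabilityField, radial_label: np.ndarray,
                   bin_mm: float = 2.0, n_bins: int = 6,
                   tau: float | None = None) -> tuple[np.ndarray, float]:
    """Mean instability in concentric 2-mm distance bins and the area
    under the profile (trapezoid over bin centers).

    With ``tau`` set, each bin mean is restricted to suprathreshold
    (I > tau) voxels — the threshold-sweep variant.  Empty interior bins
    are linearly interpolated from their neighbors; empty leading and
    trailing bins truncate the integral.  Fewer than two occupied bins
    -> (profile, NaN) with a warning.
    """
    labels = np.asarray(radial_label)
    valid = field.band_valid.astype(bool)
    I = field.I
    centers = bin_mm * (np.arange(1, n_bins + 1) - 0.5)
    profile = np.full(n_bins, np.nan)
    for k in range(1, n_bins + 1):
        sel = valid & (labels == k)
        v = I[sel]
        if tau is not None:
            v = v[v > tau]
        if v.size:
            profile[k - 1] = float(v.mean())
    occupied = np.flatnonzero(np.isfinite(profile))
    if occupied.size < 2:
        warnings.warn("radial_profile: fewer than 2 occupied bins, AUC undefined")
        return profile, float("nan")
    first, last = occupied[0], occupied[-1]
    seg = profile[first:last + 1].copy()
    nan = ~np.isfinite(seg)
    if nan.any():  # interior gaps: interpolate over bin centers
        x = centers[first:last + 1]
        seg[nan] = np.interp(x[nan], x[~nan], seg[~nan])
    auc = float(np.trapezoid(seg, centers[first:last + 1]))
    return profile, auc


def tail_auc(field: InstabilityField, t_max: float = 0.30) -> float:
    """Integral of the survival function S(t) = P(I > t) over [0, t_max].

    Closed form: the mean over valid voxels of min(max(I, 0), t_max).
    """
    vals = field.shell_values
    if vals.size == 0:
        raise ValueError("tail_auc: no valid shell voxels")
    return float(np.clip(vals, 0.0, t_max).mean())


def _exposed_edge_perimeter(mask2d: np.ndarray, spacing2d) -> float:
    """Perimeter (mm) by counting exposed pixel edges; an edge crossed
    along axis 0 has length spacing[1] and vice versa."""
    m = np.asarray(mask2d, dtype=bool)
    sx, sy = spacing2d
    pad0 = np.pad(m, ((1, 1), (0, 0)))
    pad1 = np.pad(m, ((0, 0), (1, 1)))
    edges0 = np.count_nonzero(np.diff(pad0.astype(np.int8), axis=0))
    edges1 = np.count_nonzero(np.diff(pad1.astype(np.int8), axis=1))
    return edges0 * sy + edges1 * sx


def slice_morphology(mask2d: np.ndarray, spacing2d,
                     ipr_convention: str = "complexity",
                     perimeter_estimator: str = "edges") -> dict:
    """Isoperimetric ratio and convexity of a thresholded slice map.

    Area and perimeter pool all connected components.  The default IPR
    convention is the complexity ratio P^2/(4 pi A) (>= ~1, larger =
    more irregular); the classical 4 pi A / P^2 is available as
    ``ipr_convention='classical'``.  Convexity = A / area of the convex
    hull of the suprathreshold pixel centers.
    """
    m = np.asarray(mask2d, dtype=bool)
    sx, sy = float(spacing2d[0]), float(spacing2d[1])
    n = int(m.sum())
    if n == 0:
        warnings.warn("slice_morphology: empty suprathreshold map")
        return {"ipr": float("nan"), "convexity": float("nan"), "area_mm2": 0.0}
    area = n * sx * sy
    if perimeter_estimator == "edges":
        per = _exposed_edge_perimeter(m, (sx, sy))
    elif perimeter_estimator == "crofton":
        if not np.isclose(sx, sy):
            raise ValueError("Crofton perimeter requires isotropic in-plane spacing")
        per = float(measure.perimeter_crofton(m, directions=4)) * sx
    else:
        raise ValueError(f"unknown perimeter estimator {perimeter_estimator!r}")
    if ipr_convention == "complexity":
        ipr = per ** 2 / (4.0 * np.pi * area)
    elif ipr_convention == "classical":
        ipr = 4.0 * np.pi * area / per ** 2
    else:
        raise ValueError(f"unknown IPR convention {ipr_convention!r}")
    pts = np.argwhere(m).astype(float) * np.array([sx, sy])
    convexity = float("nan")
    if len(pts) >= 3:
        try:
            hull_area = ConvexHull(pts).volume  # 2D: volume is the area
            if hull_area > 0:
                convexity = area / hull_area
        except QhullError:  # collinear centers
            pass
    return {"ipr": float(ipr), "convexity": convexity, "area_mm2": float(area)}


def skeleton_metrics(mask2d: np.ndarray) -> dict:
    """Skeletonize (2D topology-preserving thinning, 8-connected) and
    report length density (#skeleton / #region pixels) and branch-point
    density (#skeleton pixels with >= 3 skeleton neighbors / #skeleton)."""
    m = np.asarray(mask2d, dtype=bool)
    n_region = int(m.sum())
    if n_region == 0:
        warnings.warn("skeleton_metrics: empty map")
        return {"skel_length_density": float("nan"),
                "branch_point_density": float("nan"),
                "n_skeleton": 0, "n_branch_points": 0}
    # thin() pass removes the rare residual 2x2 block skeletonize can
    # leave, keeping the skeleton strictly one pixel wide
    skel = morphology.thin(morphology.skeletonize(m))
    n_skel = int(skel.sum())
    if n_skel == 0:
        return {"skel_length_density": 0.0, "branch_point_density": float("nan"),
                "n_skeleton": 0, "n_branch_points": 0}
    neighbors = ndimage.convolve(skel.astype(np.int8), _NEIGHBOR_KERNEL,
                                 mode="constant", cval=0)
    n_branch = int(np.count_nonzero(skel & (neighbors >= 3)))
    return {"skel_length_density": n_skel / n_region,
            "branch_point_density": n_branch / n_skel,
            "n_skeleton": n_skel, "n_branch_points": n_branch}


def opening_sensitivity(mask2d: np.ndarray, spacing2d, radius_mm: float = 1.5) -> dict:
    """Skeleton metrics after a light in-plane binary opening (disc
    element, radius round(radius_mm / in-plane spacing) px, minimum 1)."""
    sp = float(np.mean(spacing2d))
    r_px = max(1, int(round(radius_mm / sp)))
    opened = morphology.opening(np.asarray(mask2d, dtype=bool),
                                footprint=morphology.disk(r_px))
    if not opened.any():
        warnings.warn("opening_sensitivity: opening emptied the map")
        return {"skel_length_density": float("nan"),
                "branch_point_density": float("nan"),
                "n_skeleton": 0, "n_branch_points": 0, "opened_empty": True}
    out = skeleton_metrics(opened)
    out["opened_empty"] = False
    return out


def rim_shell_contrast(g_storage, tan_delta, rim, shell) -> dict:
    """Rim-minus-shell differences of median G' and median tan d, with
    the same positivity exclusions as the rim reference."""
    rim = np.asarray(rim, dtype=bool)
    shell = np.asarray(shell, dtype=bool)
    if not rim.any() or not shell.any():
        raise ValueError("rim_shell_contrast: empty region")
    gp = np.asarray(g_storage, dtype=float)
    td = np.asarray(tan_delta, dtype=float)

    def _med(arr, region, positive=True):
        v = arr[region]
        v = v[np.isfinite(v)]
        if positive:
            v = v[v > 0]
        if v.size == 0:
            raise ValueError("rim_shell_contrast: no valid voxels in region")
        return float(np.median(v))

    return {
        "delta_g_prime": _med(gp, rim) - _med(gp, shell),
        "delta_tan_delta": _med(td, rim) - _med(td, shell),
    }


def slice_threshold_map(field: InstabilityField, analysis_slice: int,
                        tau: float, domain: str = "band") -> np.ndarray:
    """Binary {I > tau} map on the analysis slice.

    ``domain`` selects the spatial support: the full 0-12 mm peritumoral
    band (default) or the 0-6 mm shell only.  At 3 mm voxels the shell is
    a two-pixel annulus whose inner layer is pinned near I = 0 by the rim
    reference, so shell-restricted maps degenerate to one-pixel curves;
    the band leaves room for the thickness and branching contrasts the
    morphology metrics are meant to measure.
    """
    I2d = field.I[:, :, analysis_slice]
    if domain == "band":
        dom2d = field.band_valid[:, :, analysis_slice].astype(bool)
    elif domain == "shell":
        dom2d = field.shell[:, :, analysis_slice].astype(bool)
    else:
        raise ValueError(f"unknown morphology domain {domain!r}")
    with np.errstate(invalid="ignore"):
        return ((I2d > tau) & dom2d)


def compute_case_metrics(case, masks, field: InstabilityField, tau: float,
                         config=None) -> dict:
    """All descriptors for one case at one instability threshold.

    Returns one tidy row; ``radial_auc`` is the threshold-independent
    0-12 mm persistence AUC, ``radial_auc_supra`` its suprathreshold
    (sweep) variant at this tau.
    """
    from .pipeline import PipelineConfig  # default parameter bundle
    cfg = config or PipelineConfig()
    spacing2d = case.geometry.spacing[:2]
    row = {"case_id": case.case_id, "group": case.group, "tau": float(tau)}
    row.update(scalar_summaries(field, thresholds=cfg.frac_thresholds))
    row["entropy_bits"] = histogram_entropy(field, n_bins=cfg.entropy_bins,
                                            value_range=cfg.entropy_range)
    profile, auc = radial_profile(field, masks.radial_label, bin_mm=cfg.radial_bin_mm,
                                  n_bins=cfg.n_radial_bins)
    for k, v in enumerate(profile, start=1):
        row[f"radial_mean_{k}"] = float(v)
    row["radial_auc"] = auc
    with warnings.catch_warnings():  # sparse suprathreshold profiles are expected
        warnings.simplefilter("ignore")
        _, auc_supra = radial_profile(field, masks.radial_label, bin_mm=cfg.radial_bin_mm,
                                      n_bins=cfg.n_radial_bins, tau=tau)
    row["radial_auc_supra"] = auc_supra
    row["tail_auc"] = tail_auc(field, t_max=cfg.tail_t_max)

    mask2d = slice_threshold_map(field, masks.analysis_slice, tau,
                                 domain=cfg.morphology_domain)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        row.update(slice_morphology(mask2d, spacing2d,
                                    ipr_convention=cfg.ipr_convention,
                                    perimeter_estimator=cfg.perimeter_estimator))
        sk = skeleton_metrics(mask2d)
        row["skel_length_density"] = sk["skel_length_density"]
        row["branch_point_density"] = sk["branch_point_density"]
        op = opening_sensitivity(mask2d, spacing2d, radius_mm=cfg.opening_radius_mm)
        row["skel_length_density_opened"] = op["skel_length_density"]
        row["branch_point_density_opened"] = op["branch_point_density"]

    row["pneg"] = negative_fraction(field)
    row["shell_voxel_count"] = int(field.valid_mask.sum())
    sl = masks.analysis_slice
    row["tumor_slice_area_mm2"] = float(case.tumor_mask[:, :, sl].sum()
                                        * spacing2d[0] * spacing2d[1])
    td = damping_ratio(case.g_storage, case.g_loss)
    row.update(rim_shell_contrast(case.g_storage, td, masks.rim, masks.shell))
    return row


def threshold_sweep(case, masks, field: InstabilityField,
                    taus=DEFAULT_THRESHOLDS, config=None) -> pd.DataFrame:
    """Per-case metrics at each threshold (one row per tau)."""
    rows = [compute_case_metrics(case, masks, field, tau, config=config)
            for tau in taus]
    return pd.DataFrame(rows)


def across_threshold_medians(sweep: pd.DataFrame,
                             metrics=("radial_auc_supra", "skel_length_density",
                                      "branch_point_density")) -> dict:
    """Across-tau medians of the sweep metrics (single-cutoff guard)."""
    out = {"case_id": sweep["case_id"].iloc[0], "group": sweep["group"].iloc[0]}
    for m in metrics:
        out[f"{m}_med_tau"] = float(sweep[m].median())
    return out
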