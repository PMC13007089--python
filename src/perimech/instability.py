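"""The voxelwise mechanical-instability field.

Instability is the product of a logarithmic viscous contrast and a
phase-lag deviation, both referenced to the tumor rim:

    I(x) = ln( G''(x) / G''_r,med ) * ( tan d(x) - (tan d)_r,med )

where the rim medians are taken over the one-voxel rim after excluding
all zero/negative-modulus voxels.  I(x) > 0 only when the dissipation
magnitude and the phase behavior deviate from the rim reference in the
same direction; counter-directional deviations give I < 0, and mechanical
equilibrium with the reference gives I near 0.

The field is evaluated on the peritumoral shell (0-6 mm); for radial
profiling it is evaluated identically on the 0-12 mm parenchymal band.
Voxels failing positivity are excluded (NaN), never clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RimReference:
    g_loss_med: float          # G''_r,med (kPa)
    tan_delta_med: float       # (tan d)_r,med
    n_valid_rim_voxels: int

    def __post_init__(self):
        if not (self.g_loss_med > 0 and self.tan_delta_med > 0):
            raise ValueError(
                f"rim reference medians must be positive, got "
                f"G''={self.g_loss_med}, tan d={self.tan_delta_med}"
            )
        if self.n_valid_rim_voxels < 1:
            raise ValueError("no valid rim voxels")


@dataclass
class InstabilityField:
    """I on the 0-12 mm band (NaN where undefined) plus masks and reference."""

    I: np.ndarray              # noqa: E741 - field name mirrors the index symbol
    valid_mask: np.ndarray     # shell voxels with positive G' and G''
    shell: np.ndarray
    band_valid: np.ndarray     # same validity on the full radial band
    reference: RimReference

    @property
    def shell_values(self) -> np.ndarray:
        """Valid I values on the peritumoral shell (1D)."""
        return self.I[self.valid_mask.astype(bool)]


def damping_ratio(g_storage, g_loss) -> np.ndarray:
    """tan d = G''/G' where both moduli are positive; NaN elsewhere."""
    gp = np.asarray(g_storage, dtype=float)
    gl = np.asarray(g_loss, dtype=float)
    ok = (gp > 0) & (gl > 0)
    out = np.full(gp.shape, np.nan)
    out[ok] = gl[ok] / gp[ok]
    return out


def rim_reference(g_loss, tan_delta, rim) -> RimReference:
    """Rim medians of G'' and tan d with joint positivity exclusion.

    A voxel invalid for either quantity (non-positive G'' or undefined
    tan d, i.e. non-positive G') is dropped from both medians.
    """
    rim = np.asarray(rim, dtype=bool)
    if not rim.any():
        raise ValueError("rim_reference: empty rim")
    gl = np.asarray(g_loss, dtype=float)[rim]
    td = np.asarray(tan_delta, dtype=float)[rim]
    valid = (gl > 0) & np.isfinite(td) & (td > 0)
    if not valid.any():
        raise ValueError("rim_reference: no valid rim voxels after positivity exclusion")
    return RimReference(
        g_loss_med=float(np.median(gl[valid])),
        tan_delta_med=float(np.median(td[valid])),
        n_valid_rim_voxels=int(valid.sum()),
    )


def instability_map(g_loss, tan_delta, reference: RimReference, shell,
                    band=None, reference_storage: bool = False,
                    g_storage=None) -> InstabilityField:
    """Evaluate I(x) on the shell (and, if given, the wider radial band).

    ``reference_storage=True`` switches the log denominator to the rim
    median of G' (the literal printed-formula variant, for sensitivity
    analysis); the default references G''.
    """
    shell = np.asarray(shell, dtype=bool)
    band_arr = shell if band is None else (np.asarray(band, dtype=bool) | shell)
    gl = np.asarray(g_loss, dtype=float)
    td = np.asarray(tan_delta, dtype=float)

    if reference_storage:
        if g_storage is None:
            raise ValueError("reference_storage=True requires g_storage for the rim median")
        denom = float(np.median(np.asarray(g_storage, dtype=float)[shell]))
    else:
        denom = reference.g_loss_med

    valid_band = band_arr & (gl > 0) & np.isfinite(td)
    I = np.full(gl.shape, np.nan)
    I[valid_band] = np.log(gl[valid_band] / denom) * (td[valid_band] - reference.tan_delta_med)
    return InstabilityField(
        I=I,
        valid_mask=(valid_band & shell).astype(np.uint8),
        shell=shell.astype(np.uint8),
        band_valid=valid_band.astype(np.uint8),
        reference=reference,
    )


def negative_fraction(field: InstabilityField) -> float:
    """pneg: fraction of valid shell voxels with I < 0."""
    vals = field.shell_values
    if vals.size == 0:
        warnings.warn("negative_fraction: no valid shell voxels")
        return float("nan")
    return float(np.count_nonzero(vals < 0) / vals.size)


def compute_field(case, masks, reference_storage: bool = False) -> InstabilityField:
    """Rim reference + instability field for one case's derived regions."""
    td = damping_ratio(case.g_storage, case.g_loss)
    ref = rim_reference(case.g_loss, td, masks.rim)
    return instability_map(case.g_loss, td, ref, masks.shell, band=masks.band,
                           reference_storage=reference_storage, g_storage=case.g_storage)
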