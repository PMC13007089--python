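"""Seeded synthetic elastogram phantoms.

No patient data ships with this package, so the pipeline is exercised on
synthetic cohorts that emulate the three qualitative peritumoral
archetypes seen across tumor grades:

* ``compact`` (WHO I-like): an isotropic rim elevation of dissipation
  decaying exponentially with distance from the tumor boundary —
  radially coherent, spatially compact.
* ``irregular`` (WHO II-like): the compact field restricted to a random
  angular sector, partially disrupted, plus one or two filaments.
* ``branched`` (GBM-like): a short-decay rim plus several thin radial
  filaments (random walks seeded on the tumor boundary) that may
  bifurcate — diffuse, fragmented dissipation.

The phantom is an ellipsoidal "brain" on a 64 x 64 x 32 grid of 3 mm
near-isotropic voxels with a lobulated spherical tumor.  Noise is
multiplicative lognormal: independent smoothed lognormal fields are
placed on the loss modulus G'' and on the damping ratio tan d, and the
storage modulus is derived as G' = G''/tan d (both moduli therefore
lognormal).  Placing the noise on (G'', tan d) rather than (G', G'')
makes the two factors of the instability index independent under the
null, so an amplitude-zero phantom has a sign-symmetric instability
field.  A small dropout fraction of voxels is zeroed to exercise the
non-positive-voxel exclusion rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .geometry import anisotropic_edt, max_tumor_slice
from .volume_io import (CohortManifest, ElastogramCase, GridGeometry,
                        save_manifest, write_volume)

ARCHETYPE_GROUP = {"compact": "WHO_I", "irregular": "WHO_II", "branched": "GBM"}


@dataclass(frozen=True)
class ArchetypeParams:
    """Tissue and elevation parameters for one peritumoral archetype."""

    name: str
    g_prime_base: float = 2.5       # parenchyma G' mean, kPa
    g_loss_base: float = 1.0        # parenchyma G'' mean, kPa
    noise_cv: float = 0.10          # CV of multiplicative lognormal noise
    rim_amplitude: float = 5.0      # fractional elevation of G'' and tan d at the boundary
    decay_length_mm: float = 4.0    # e-folding distance of the rim elevation
    n_tendrils: int = 0             # radial filaments (0 for compact)
    branch_prob: float = 0.0        # per-step bifurcation probability
    tendril_width_mm: float = 2.0   # filament half-width
    tendril_length_mm: float = 12.0  # mean filament extent
    tendril_amplitude: float = 1.2  # fractional elevation along filament cores
    smooth_fwhm_mm: float = 8.0     # correlation length of the noise fields
    sector_width_deg: float = 150.0  # angular sector kept by the irregular archetype
    sector_floor: float = 0.1       # elevation retained outside the sector
    tumor_stiffness_factor: float = 2.0  # tumor-interior G' multiplier
    dropout_frac: float = 0.01      # fraction of brain voxels zeroed in G''

    def __post_init__(self):
        if self.name not in ARCHETYPE_GROUP:
            raise ValueError(f"unknown archetype {self.name!r}")
        if self.rim_amplitude < 0:
            raise ValueError("rim_amplitude must be >= 0")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        for f_name in ("decay_length_mm", "tendril_width_mm", "tendril_length_mm"):
            if getattr(self, f_name) <= 0:
                raise ValueError(f"{f_name} must be positive")

    @classmethod
    def default(cls, name: str) -> "ArchetypeParams":
        if name == "compact":
            return cls(name="compact")
        if name == "irregular":
            return cls(name="irregular", n_tendrils=2, branch_prob=0.2,
                       tumor_stiffness_factor=2.0)
        if name == "branched":
            return cls(name="branched", rim_amplitude=2.8, decay_length_mm=1.5,
                       n_tendrils=6, branch_prob=0.35, tendril_length_mm=14.0,
                       tumor_stiffness_factor=0.6)
        raise ValueError(f"unknown archetype {name!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one phantom: grid, brain ellipsoid, tumor ball, seed."""

    grid: GridGeometry = field(default_factory=lambda: GridGeometry.isotropic((64, 64, 32), 3.0))
    brain_semiaxes_mm: tuple[float, float, float] = (85.0, 85.0, 42.0)
    tumor_center_vox: tuple[float, float, float] = (38.0, 32.0, 16.0)
    tumor_radius_mm: float = 15.0
    lobulation: float = 0.15        # low-order spherical-harmonic boundary perturbation
    seed: int = 0

    def __post_init__(self):
        if self.tumor_radius_mm < 2 * min(self.grid.spacing[:2]):
            raise ValueError("tumor radius must span >= 2 in-plane voxels")


def _coords_mm(shape, spacing):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij")


def _smoothed_lognormal(shape, spacing, cv, fwhm_mm, rng) -> np.ndarray:
    """Unit-mean multiplicative lognormal field with coefficient of
    variation ``cv`` and Gaussian spatial correlation ``fwhm_mm``."""
    if cv <= 0:
        return np.ones(shape)
    g = rng.standard_normal(shape)
    sigma_vox = [fwhm_mm / 2.355 / s for s in spacing]
    if any(s > 0 for s in sigma_vox):
        g = ndimage.gaussian_filter(g, sigma=sigma_vox)
        sd = g.std()
        if sd > 0:
            g = g / sd
    s_ln = np.sqrt(np.log1p(cv ** 2))
    return np.exp(s_ln * g - 0.5 * s_ln ** 2)


def _lobulated_tumor(spec: PhantomSpec, rng) -> np.ndarray:
    """Tumor mask: sphere with a low-order spherical-harmonic radius
    perturbation of amplitude ``lobulation``."""
    shape, spacing = spec.grid.shape, spec.grid.spacing
    xs, ys, zs = _coords_mm(shape, spacing)
    cx, cy, cz = (c * s for c, s in zip(spec.tumor_center_vox, spacing))
    dx, dy, dz = xs - cx, ys - cy, zs - cz
    r = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    if spec.lobulation > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(np.divide(dz, r, out=np.zeros_like(r), where=r > 0), -1, 1))
        phi = np.arctan2(dy, dx)
        pert = np.zeros(shape)
        for n in (2, 3):
            for m in range(-n, n + 1):
                coef = rng.standard_normal()
                pert += coef * np.real(special.sph_harm_y(n, m, theta, phi))
        peak = np.abs(pert).max()
        if peak > 0:
            pert = pert / peak
        radius = spec.tumor_radius_mm * (1.0 + spec.lobulation * pert)
    else:
        radius = np.full(shape, spec.tumor_radius_mm)
    tumor = r <= radius
    if not tumor.any():
        raise ValueError("zero-volume tumor")
    return tumor


def _paint_tendrils(tumor, spec: PhantomSpec, params: ArchetypeParams, rng,
                    n_tendrils: int) -> np.ndarray:
    """Elevation field of thin radial filaments in the axial plane of the
    tumor-center slice, thickened in 3D by the filament half-width.

    Each filament is a random walk started on the tumor boundary, stepped
    outward with angular jitter; at every step it bifurcates with
    probability ``branch_prob``.
    """
    shape, spacing = spec.grid.shape, spec.grid.spacing
    if n_tendrils <= 0:
        return np.zeros(shape)
    z0 = max_tumor_slice(tumor)
    center = np.array(spec.tumor_center_vox[:2]) * np.array(spacing[:2])
    hit = np.zeros(shape, dtype=bool)
    step_mm = 3.0
    tum2d = tumor[:, :, z0]

    def inside_tumor(p_mm):
        i = int(round(p_mm[0] / spacing[0]))
        j = int(round(p_mm[1] / spacing[1]))
        if 0 <= i < shape[0] and 0 <= j < shape[1]:
            return bool(tum2d[i, j])
        return False

    def mark(p_mm):
        i = int(round(p_mm[0] / spacing[0]))
        j = int(round(p_mm[1] / spacing[1]))
        if 0 <= i < shape[0] and 0 <= j < shape[1]:
            hit[i, j, z0] = True

    for _ in range(n_tendrils):
        ang = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(ang), np.sin(ang)])
        # march from the center to the boundary of the (lobulated) tumor
        pos = center.copy()
        while inside_tumor(pos + direction * 1.0):
            pos = pos + direction * 1.0
        length = params.tendril_length_mm * rng.uniform(0.7, 1.3)
        walkers = [(pos.copy(), direction.copy(), length)]
        while walkers:
            p, d, remaining = walkers.pop()
            while remaining > 0:
                jitter = rng.normal(0.0, np.deg2rad(20.0))
                ca, sa = np.cos(jitter), np.sin(jitter)
                d = np.array([ca * d[0] - sa * d[1], sa * d[0] + ca * d[1]])
                for t in np.linspace(0, step_mm, 7):
                    mark(p + d * t)
                p = p + d * step_mm
                remaining -= step_mm
                if remaining > 0 and rng.random() < params.branch_prob:
                    split = rng.choice([-1.0, 1.0]) * np.deg2rad(rng.uniform(60.0, 100.0))
                    cb, sb = np.cos(split), np.sin(split)
                    d2 = np.array([cb * d[0] - sb * d[1], sb * d[0] + cb * d[1]])
                    walkers.append((p.copy(), d2, remaining))
    if not hit.any():
        return np.zeros(shape)
    d_hit = anisotropic_edt(hit, spacing)
    return np.exp(-((d_hit / params.tendril_width_mm) ** 2))


def generate_phantom(spec: PhantomSpec, params: ArchetypeParams) -> ElastogramCase:
    """One deterministic synthetic case for a given seed."""
    shape, spacing = spec.grid.shape, spec.grid.spacing
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_lob, rng_gl, rng_td, rng_drop, rng_tend, rng_sect = \
        (np.random.default_rng(s) for s in streams)

    xs, ys, zs = _coords_mm(shape, spacing)
    bc = np.array([(n - 1) / 2.0 * s for n, s in zip(shape, spacing)])
    brain = (((xs - bc[0]) / spec.brain_semiaxes_mm[0]) ** 2
             + ((ys - bc[1]) / spec.brain_semiaxes_mm[1]) ** 2
             + ((zs - bc[2]) / spec.brain_semiaxes_mm[2]) ** 2) <= 1.0
    tumor = _lobulated_tumor(spec, rng_lob)
    if (tumor & ~brain).any():
        raise ValueError("tumor breaches the brain boundary")

    dist = anisotropic_edt(tumor, spacing)
    elev = np.exp(-dist / params.decay_length_mm)
    elev[tumor] = 0.0

    if params.name == "irregular":
        phi = np.arctan2(ys - spec.tumor_center_vox[1] * spacing[1],
                         xs - spec.tumor_center_vox[0] * spacing[0])
        phi0 = rng_sect.uniform(-np.pi, np.pi)
        half = np.deg2rad(params.sector_width_deg) / 2.0
        dphi = np.angle(np.exp(1j * (phi - phi0)))
        elev = np.where(np.abs(dphi) <= half, elev, params.sector_floor * elev)
    tendril_elev = _paint_tendrils(tumor, spec, params, rng_tend, params.n_tendrils)
    # amplitude-weighted union of the isotropic rim term and the filament term
    amp = np.maximum(params.rim_amplitude * elev,
                     params.tendril_amplitude * tendril_elev)
    amp[tumor] = 0.0

    g_loss = params.g_loss_base * _smoothed_lognormal(shape, spacing, params.noise_cv,
                                                      params.smooth_fwhm_mm, rng_gl)
    tan_base = params.g_loss_base / params.g_prime_base
    tan_d = tan_base * _smoothed_lognormal(shape, spacing, params.noise_cv,
                                           params.smooth_fwhm_mm, rng_td)
    boost = 1.0 + amp
    g_loss = g_loss * boost
    tan_d = tan_d * boost
    g_storage = g_loss / tan_d

    # tumor interior: distinct moduli (stiff meningioma-like, soft GBM-like)
    g_storage[tumor] = params.tumor_stiffness_factor * g_storage[tumor]

    if params.dropout_frac > 0:
        drop = rng_drop.random(shape) < params.dropout_frac
        g_loss[drop & brain] = 0.0

    g_storage[~brain] = 0.0
    g_loss[~brain] = 0.0

    return ElastogramCase(
        case_id=f"{params.name}_{spec.seed}", group=ARCHETYPE_GROUP[params.name],
        g_storage=g_storage, g_loss=g_loss,
        tumor_mask=tumor.astype(np.uint8), brain_mask=brain.astype(np.uint8),
        geometry=spec.grid,
    )


def case_spec(case_seed: int, grid: GridGeometry | None = None) -> PhantomSpec:
    """Per-case phantom geometry: tumor radius, position and lobulation
    drawn deterministically from the case seed."""
    grid = grid or GridGeometry.isotropic((64, 64, 32), 3.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(case_seed), 797]))
    radius = rng.uniform(12.0, 18.0)
    center = np.array([(grid.shape[0] - 1) / 2.0, (grid.shape[1] - 1) / 2.0,
                       (grid.shape[2] - 1) / 2.0])
    offset = rng.uniform(-4.0, 4.0, size=2)  # voxels, in-plane
    center[:2] += offset
    return PhantomSpec(grid=grid, tumor_center_vox=tuple(center),
                       tumor_radius_mm=float(radius), lobulation=0.15,
                       seed=int(case_seed))


def make_cohort_cases(n_per_group=(10, 5, 13), base_seed: int = 42,
                      params_by_archetype: dict | None = None,
                      grid: GridGeometry | None = None) -> list[ElastogramCase]:
    """In-memory synthetic cohort; per-case seeds = base_seed + case index."""
    if any(n < 1 for n in n_per_group):
        raise ValueError("need n >= 1 per group")
    params_by_archetype = params_by_archetype or {
        name: ArchetypeParams.default(name) for name in ARCHETYPE_GROUP
    }
    cases = []
    idx = 0
    for name, n in zip(("compact", "irregular", "branched"), n_per_group):
        for _ in range(n):
            seed = base_seed + idx
            spec = case_spec(seed, grid=grid)
            case = generate_phantom(spec, params_by_archetype[name])
            case.case_id = f"{name}_{idx:03d}"
            cases.append(case)
            idx += 1
    return cases


def generate_cohort(n_per_group=(10, 5, 13), base_seed: int = 42,
                    out_dir="cohort", params_by_archetype: dict | None = None,
                    grid: GridGeometry | None = None) -> CohortManifest:
    """Write a synthetic cohort (NIfTI volumes + manifest CSV + parameter
    sidecars) and return its manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params_by_archetype = params_by_archetype or {
        name: ArchetypeParams.default(name) for name in ARCHETYPE_GROUP
    }
    cases = make_cohort_cases(n_per_group, base_seed, params_by_archetype, grid)
    records = []
    for i, case in enumerate(cases):
        stem = case.case_id
        paths = {}
        for kind, vol in (("g_storage", case.g_storage), ("g_loss", case.g_loss),
                          ("tumor_mask", case.tumor_mask), ("brain_mask", case.brain_mask)):
            p = out_dir / f"{stem}_{kind}.nii.gz"
            write_volume(p, vol, case.geometry)
            paths[kind] = p.name
        name = case.case_id.rsplit("_", 1)[0]
        sidecar = {"case_id": case.case_id, "group": case.group,
                   "seed": base_seed + i, "params": asdict(params_by_archetype[name])}
        (out_dir / f"{stem}_params.json").write_text(json.dumps(sidecar, indent=2))
        records.append({"case_id": case.case_id, "group": case.group, **paths,
                        "seed": base_seed + i})
    manifest = CohortManifest(records=pd.DataFrame(records), root=out_dir)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def null_params(noise: bool = True, name: str = "compact") -> ArchetypeParams:
    """Amplitude-zero phantom parameters for null-field checks."""
    base = ArchetypeParams.default(name)
    return replace(base, rim_amplitude=0.0, n_tendrils=0,
                   noise_cv=base.noise_cv if noise else 0.0,
                   dropout_frac=base.dropout_frac if noise else 0.0)
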