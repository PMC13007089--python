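"""End-to-end orchestration: synth -> compute -> compare.

Every tunable constant of the analysis lives in :class:`PipelineConfig`
with its default value; all randomness flows from one base seed, and a
rerun with the same config and seed reproduces every output table
exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, instability, maps, metrics, stats, synthetic
from .volume_io import CohortManifest, load_manifest, save_json, save_metrics, write_volume

BOOTSTRAP_METRICS = ("radial_auc", "skel_length_density", "branch_point_density")


@dataclass
class PipelineConfig:
    """All analysis constants, at their defaults."""

    thresholds: tuple = metrics.DEFAULT_THRESHOLDS      # instability cutoffs
    primary_tau: float = metrics.PRIMARY_TAU            # 0.02
    frac_thresholds: tuple = (0.02, 0.05)
    shell_r_max_mm: float = 6.0
    guard_mm: float = 2.0
    radial_max_mm: float = 12.0
    radial_bin_mm: float = 2.0
    n_radial_bins: int = 6
    patch_mm: float = 120.0
    grid_n: int = 256
    r_star_mm: float = 20.0
    entropy_bins: int = 32
    entropy_range: tuple = (0.0, 0.4)
    tail_t_max: float = 0.30
    opening_radius_mm: float = 1.5
    bootstrap_n_iter: int = 10_000
    morphology_domain: str = "band"      # slice-topology support: band (0-12 mm) | shell
    ipr_convention: str = "complexity"
    perimeter_estimator: str = "edges"
    rim_connectivity: int = 1
    erode_voxels: int = 1
    erosion_policy: str = "per_case"     # per_case | always | never
    reference_storage: bool = False      # literal printed-formula variant
    n_per_group: tuple = (10, 5, 13)
    base_seed: int = 42

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def process_case(case, config: PipelineConfig | None = None):
    """Regions, instability field and the full threshold sweep for one case."""
    cfg = config or PipelineConfig()
    if cfg.erosion_policy == "always":
        case.erode_parenchyma = True
    elif cfg.erosion_policy == "never":
        case.erode_parenchyma = False
    masks = geometry.build_region_masks(
        case, r_max_mm=cfg.shell_r_max_mm, guard_mm=cfg.guard_mm,
        radial_max_mm=cfg.radial_max_mm, bin_mm=cfg.radial_bin_mm,
        erode_voxels=cfg.erode_voxels, rim_connectivity=cfg.rim_connectivity)
    fld = instability.compute_field(case, masks, reference_storage=cfg.reference_storage)
    sweep = metrics.threshold_sweep(case, masks, fld, taus=cfg.thresholds, config=cfg)
    return masks, fld, sweep


def compute_cohort(cases, config: PipelineConfig | None = None):
    """Per-case metrics (rows per case x threshold) and primary-tau case maps."""
    cfg = config or PipelineConfig()
    rows, case_map_list = [], []
    for case in cases:
        masks, fld, sweep = process_case(case, cfg)
        rows.append(sweep)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = maps.case_maps(fld, masks, case, tau=cfg.primary_tau,
                                patch_mm=cfg.patch_mm, grid_n=cfg.grid_n)
        case_map_list.append(cm)
    table = pd.concat(rows, ignore_index=True)
    return table, case_map_list


def compare_cohort(table: pd.DataFrame, case_map_list, config: PipelineConfig | None = None,
                   seed: int = 0):
    """Group statistics, bootstrap, associations and probability maps."""
    cfg = config or PipelineConfig()
    primary = table[np.isclose(table["tau"], cfg.primary_tau)].reset_index(drop=True)
    kw, pw = stats.compare_groups(primary)

    boots = {}
    for i, metric in enumerate(BOOTSTRAP_METRICS):
        vals = {g: primary.loc[primary["group"] == g, metric].dropna().to_numpy()
                for g in stats.GROUP_ORDER}
        boots[metric] = stats.bootstrap_ordering(vals, metric=metric,
                                                 n_iter=cfg.bootstrap_n_iter,
                                                 seed=seed + i)
    assoc = stats.association_suite(primary)

    group_maps, group_maps_norm = {}, {}
    for g in stats.GROUP_ORDER:
        cms = [cm for cm in case_map_list if cm.group == g]
        if not cms:
            continue
        group_maps[g] = maps.group_probability_maps(cms, g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cms_norm = [maps.radius_normalize(cm, r_star_mm=cfg.r_star_mm) for cm in cms]
        group_maps_norm[g] = maps.group_probability_maps(cms_norm, g)

    sweep_medians = pd.DataFrame([
        metrics.across_threshold_medians(table[table["case_id"] == cid])
        for cid in table["case_id"].unique()
    ])
    return {"kruskal": kw, "pairwise": pw, "bootstrap": boots, "associations": assoc,
            "group_maps": group_maps, "group_maps_normalized": group_maps_norm,
            "sweep_medians": sweep_medians}


def run(config: PipelineConfig | None = None, out_dir="results", seed: int | None = None,
        manifest: CohortManifest | None = None, write_fields: bool = False) -> dict:
    """Full pipeline: synthesize (or load) a cohort, compute per-case
    metrics, compare groups, and write the artifact tree under out_dir."""
    cfg = config or PipelineConfig()
    seed = cfg.base_seed if seed is None else seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if manifest is None:
        cases = synthetic.make_cohort_cases(cfg.n_per_group, base_seed=seed)
    else:
        cases = list(manifest.iter_cases())

    table, case_map_list = compute_cohort(cases, cfg)
    save_metrics(table, out_dir / "case_metrics.csv")

    if write_fields:
        for case in cases:
            masks, fld, _ = process_case(case, cfg)
            write_volume(out_dir / f"{case.case_id}_instability.nii.gz",
                         fld.I, case.geometry)

    results = compare_cohort(table, case_map_list, cfg, seed=seed)
    results["kruskal"].to_csv(out_dir / "kruskal_wallis.csv", index=False)
    results["pairwise"].to_csv(out_dir / "pairwise_tests.csv", index=False)
    results["associations"].to_csv(out_dir / "associations.csv", index=False)
    results["sweep_medians"].to_csv(out_dir / "threshold_sweep_medians.csv", index=False)
    save_json({m: asdict(b) for m, b in results["bootstrap"].items()},
              out_dir / "bootstrap.json")
    for tag, gm_dict in (("physical", results["group_maps"]),
                         ("normalized", results["group_maps_normalized"])):
        for g, gm in gm_dict.items():
            np.savetxt(out_dir / f"pmap_{tag}_{g}_occupancy.csv", gm.p_occ,
                       delimiter=",", fmt="%.6f")
    save_json({"config": asdict(cfg), "config_hash": cfg.config_hash(), "seed": seed,
               "n_cases": len(cases)}, out_dir / "run_manifest.json")
    results["case_metrics"] = table
    results["case_maps"] = case_map_list
    return results
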