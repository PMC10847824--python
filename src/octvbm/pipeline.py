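"""End-to-end orchestration: register -> group maps -> voxel-wise
comparison -> multiplicity correction -> overlays.

The pipeline consumes either a directory of exported maps plus a
covariate table, or one of the built-in synthetic presets, and writes
every result together with a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .io import (
    ThicknessMap,
    read_covariates,
    read_thickness_map,
    write_thickness_map,
)
from .mapping import build_group_stack, fovea_exclusion_mask, percentage_change_map
from .registration import register_scan, target_from_scan
from .synthetic import EffectSpec, TemplateSpec, cohort_stacks, make_cohort, template_target
from .voxstats import GLMSpec, cluster_table, render_overlay, voxelwise_glm
from .geometry import ScanGeometry

log = logging.getLogger("octvbm")

PRESETS = ("null", "atrophy-disc")


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Defaults follow the standard analysis settings: alpha 0.05, minimum
    cluster extent 9 voxels (8-connectivity), central fovea exclusion of
    500 um, age/sex/retina covariates.
    """

    out_dir: str = "octvbm-results"
    input_dir: Optional[str] = None
    preset: Optional[str] = None            # "null" | "atrophy-disc"
    n_per_group: int = 30
    n_ascans: int = 128                     # preset grid crop for speed
    layers: Tuple[str, ...] = ("RNFL", "GCIPL", "INL")
    covariates: Tuple[str, ...] = ("age", "sex", "retina")
    eye_policy: str = "average-within-subject"
    target_policy: str = "designated-reference"
    reference_group: str = "HC"
    alpha: float = 0.05
    min_cluster_voxels: int = 9
    connectivity: int = 8
    fovea_exclusion_radius_um: float = 500.0
    rescale_thickness: bool = False
    color_range_um: float = 5.0
    color_range_pct: float = 15.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["layers"] = list(self.layers)
        d["covariates"] = list(self.covariates)
        return d


def validate_config(config: dict) -> dict:
    """Check a raw config mapping; returns a report, never raises.

    Report fields: ``valid``, ``problems`` (list of messages) and
    ``unknown_keys``.
    """
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(config) - known)
    problems: List[str] = []
    merged = {**{f.name: getattr(PipelineConfig(), f.name)
                 for f in dataclasses.fields(PipelineConfig)}, **config}
    if not (0.0 < float(merged["alpha"]) < 1.0):
        problems.append(f"alpha must be in (0, 1), got {merged['alpha']}")
    if int(merged["min_cluster_voxels"]) < 1:
        problems.append("min_cluster_voxels must be >= 1")
    if int(merged["connectivity"]) not in (4, 8):
        problems.append(f"connectivity must be 4 or 8, "
                        f"got {merged['connectivity']}")
    if float(merged["fovea_exclusion_radius_um"]) < 0:
        problems.append("fovea_exclusion_radius_um must be >= 0")
    if merged["eye_policy"] not in ("average-within-subject", "eye-level"):
        problems.append(f"unknown eye_policy {merged['eye_policy']!r}")
    if merged["preset"] is not None and merged["preset"] not in PRESETS:
        problems.append(f"unknown preset {merged['preset']!r}; "
                        f"choose from {PRESETS}")
    if merged["preset"] is None and merged["input_dir"] is None:
        problems.append("either preset or input_dir is required")
    if merged["input_dir"] is not None and \
            not Path(merged["input_dir"]).exists():
        problems.append(f"input_dir {merged['input_dir']!r} does not exist")
    bad_layers = set(merged["layers"]) - {"RNFL", "GCIPL", "INL", "Retina"}
    if bad_layers:
        problems.append(f"unknown layers {sorted(bad_layers)}")
    return {"valid": not problems and not unknown,
            "problems": problems, "unknown_keys": unknown}


def _preset_cohort(cfg: PipelineConfig):
    spec = TemplateSpec(geometry=ScanGeometry().crop_columns(cfg.n_ascans))
    if cfg.preset == "null":
        groups = [("HC", cfg.n_per_group, []),
                  ("MS", cfg.n_per_group, [])]
    elif cfg.preset == "atrophy-disc":
        fovea = spec.resolved_fovea()
        disc = EffectSpec(layer="GCIPL", shape="disc", delta_um=-5.0,
                          center=(fovea[0], fovea[1] + 25), radius=8.0,
                          units="voxel")
        groups = [("HC", cfg.n_per_group, []),
                  ("MS", cfg.n_per_group, [disc])]
    else:
        raise ConfigError(f"unknown preset {cfg.preset!r}")
    cohort = make_cohort(spec, groups, jitter_rows=1, jitter_cols=5,
                         seed=cfg.seed)
    return spec, cohort


def _load_input_scans(cfg: PipelineConfig):
    """Read maps named ``<subject>_<eye>_<layer>.tsv`` plus
    covariates.csv from the input directory."""
    root = Path(cfg.input_dir)
    cov = read_covariates(root / "covariates.csv")
    scans: Dict[Tuple[str, str], Dict[str, ThicknessMap]] = {}
    for path in sorted(root.glob("*.tsv")):
        tm = read_thickness_map(path)
        if tm.subject_id is None:
            raise ConfigError(f"{path.name}: sidecar lacks subject_id")
        key = (tm.subject_id, tm.eye or "OU")
        scans.setdefault(key, {})[tm.layer] = tm
    missing = [k for k, v in scans.items() if "Retina" not in v]
    if missing:
        raise ConfigError(f"scans without a Retina map: {missing}")
    return cov, scans


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Rerunning with the same config and inputs is bit-identical for all
    deterministic stages (everything except PNG metadata).
    """
    report = validate_config(config.to_dict())
    if not report["valid"]:
        raise ConfigError("; ".join(report["problems"] +
                                    [f"unknown key {k}" for k in
                                     report["unknown_keys"]]))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "version": __version__,
                      "stages": {}}

    # stage 1: inputs ------------------------------------------------------
    if config.preset is not None:
        spec, cohort = _preset_cohort(config)
        target = template_target(spec)
        stacks = cohort_stacks(cohort, register=True, target=target)
        n_scans = len(cohort.scans)
        geometry = spec.geometry
    else:
        cov, scans = _load_input_scans(config)
        n_scans = len(scans)
        from .io import flip_to_left

        flipped = {k: {layer: flip_to_left(m) for layer, m in v.items()}
                   for k, v in scans.items()}
        first = next(iter(flipped.values()))
        geometry = first["Retina"].geometry
        from .registration import detect_fovea, detect_fovea_subvoxel
        from .geometry import TargetGrid

        fov = detect_fovea(first["Retina"])
        target = TargetGrid(n_rows=geometry.n_bscans,
                            n_cols=geometry.n_ascans, fovea_position=fov,
                            source="designated-reference", geometry=geometry,
                            fovea_subvoxel=
                            detect_fovea_subvoxel(first["Retina"]))
        per_layer: Dict[str, list] = {}
        for key, maps in flipped.items():
            registered, _ = register_scan(maps, None, target,
                                          rescale_thickness=
                                          config.rescale_thickness)
            for layer, m in registered.items():
                per_layer.setdefault(layer, []).append(m)
        stacks = {layer: build_group_stack(maps_list, cov,
                                           eye_policy=config.eye_policy)
                  for layer, maps_list in per_layer.items()}
    log.info("stage register: %d scans -> target %s", n_scans, target.shape)
    manifest["stages"]["register"] = {"n_scans": n_scans,
                                      "target_fovea":
                                      list(target.fovea_position)}

    # stage 2: group maps --------------------------------------------------
    maps_dir = out / "groupmaps"
    maps_dir.mkdir(exist_ok=True)
    groups = list(pd.unique(stacks["Retina"].covariates["group"]))
    for layer, stack in stacks.items():
        for grp in groups:
            sel = (stack.covariates["group"] == grp).values
            mean = stack.subset(np.flatnonzero(sel)).mean_map()
            tm = ThicknessMap(values=mean, layer=layer,
                              laterality="left-normalized",
                              geometry=stack.geometry, registered=True,
                              subject_id=f"groupmean-{grp}")
            write_thickness_map(tm, maps_dir / f"{grp}_{layer}.tsv")
    log.info("stage groupmap: %d layers x %d groups", len(stacks),
             len(groups))
    manifest["stages"]["groupmap"] = {"groups": groups,
                                      "layers": sorted(stacks)}

    # stage 3: voxel-wise statistics --------------------------------------
    fmask = fovea_exclusion_mask(target,
                                 radius_um=config.fovea_exclusion_radius_um,
                                 geometry=geometry)
    spec_glm = GLMSpec(covariates=config.covariates, contrast="two-group-t",
                       reference_group=config.reference_group,
                       alpha=config.alpha,
                       min_cluster_voxels=config.min_cluster_voxels,
                       connectivity=config.connectivity)
    stats_dir = out / "voxstats"
    stats_dir.mkdir(exist_ok=True)
    hc_label = config.reference_group if config.reference_group in groups \
        else groups[0]
    cluster_counts: Dict[str, Dict[str, int]] = {}
    for layer in config.layers:
        stack = stacks[layer]
        retina = stacks["Retina"]
        cluster_counts[layer] = {}
        for grp in groups:
            if grp == hc_label:
                continue
            sel = stack.covariates["group"].isin([hc_label, grp]).values
            idx = np.flatnonzero(sel)
            sms = voxelwise_glm(stack.subset(idx), retina.subset(idx),
                                spec_glm, fmask)
            hc_stack = stack.subset(np.flatnonzero(
                (stack.covariates["group"] == hc_label).values))
            pt_stack = stack.subset(np.flatnonzero(
                (stack.covariates["group"] == grp).values))
            pct = percentage_change_map(pt_stack, hc_stack)
            tag = f"{layer}_{grp}-vs-{hc_label}"
            np.savetxt(stats_dir / f"{tag}_t.tsv", sms.stat, delimiter="\t")
            np.savetxt(stats_dir / f"{tag}_p.tsv", sms.p, delimiter="\t")
            np.savetxt(stats_dir / f"{tag}_sig.tsv",
                       sms.sig.astype(int), delimiter="\t", fmt="%d")
            np.savetxt(stats_dir / f"{tag}_clusters.tsv", sms.clusters,
                       delimiter="\t", fmt="%d")
            np.savetxt(stats_dir / f"{tag}_pct.tsv", pct, delimiter="\t")
            cluster_table(sms).to_csv(stats_dir / f"{tag}_clusters.csv",
                                      index=False)
            render_overlay(sms, sms.diff, color_range=config.color_range_um,
                           units="um", title=tag,
                           path=stats_dir / f"{tag}_overlay.png")
            n_clusters = int(sms.clusters.max())
            cluster_counts[layer][grp] = n_clusters
            log.info("stage voxstats: %s -> %d significant voxels, "
                     "%d clusters", tag, sms.n_significant, n_clusters)
    manifest["stages"]["voxstats"] = {
        "alpha": config.alpha,
        "min_cluster_voxels": config.min_cluster_voxels,
        "connectivity": config.connectivity,
        "fovea_exclusion_radius_um": config.fovea_exclusion_radius_um,
        "significant_clusters": cluster_counts,
    }

    manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    log.info("pipeline complete: %s", out)
    return out
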