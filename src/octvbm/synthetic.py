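"""Synthetic macular scans with known ground truth.

The generator emulates the geometry and gross anatomy of a macular
volume acquisition so every pipeline stage is testable without patient
data:

* 25 B-scans x 1024 A-scans over a 20 deg x 20 deg field (240 um between
  B-scans), configurable;
* a foveal pit — all inner layers vanish smoothly at the fovea, making
  total retinal thickness a unique minimum there;
* RNFL thickness increasing toward the optic nerve head (the low-column
  side after left-normalization);
* a perifoveal GCIPL annulus;
* additive per-voxel Gaussian measurement noise (default SD 1.5 um, at
  the scale of repeated-scan variability of commercial devices);
* integer inter-subject fovea-position jitter;
* group-level focal effects (discs, annuli, sectors) injected as signed
  thickness deltas with the ground-truth masks recorded.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, GeometryError
from .geometry import ScanGeometry, TargetGrid, grid_distance_um
from .io import BoundarySet, ThicknessMap
from .reliability import RetestStack

INNER_LAYERS = ("RNFL", "GCIPL", "INL")


@dataclass(frozen=True)
class TemplateSpec:
    """Parameters of the noise-free anatomical template.

    Thickness fields (um) at grid position x with distance r from the
    fovea:

    * pit factor  s(r) = 1 - exp(-(r / pit_radius_um)^2)
    * RNFL  = (rnfl_base + rnfl_onh_gradient_um_per_mm * d_onh_mm) * s
      where d_onh is the distance from the temporal (high-column) edge
    * GCIPL = (gcipl_base + gcipl_annulus_amp * exp(-((r - r0)/w)^2)) * s
    * INL   = inl_base * s
    * Retina = RNFL + GCIPL + INL + outer_um
    """

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    fovea_center: Optional[Tuple[int, int]] = None   # default: grid centre
    pit_radius_um: float = 750.0
    rnfl_base_um: float = 18.0
    rnfl_onh_gradient_um_per_mm: float = 4.0
    gcipl_base_um: float = 45.0
    gcipl_annulus_amp_um: float = 28.0
    gcipl_annulus_r_um: float = 1100.0
    gcipl_annulus_width_um: float = 600.0
    inl_base_um: float = 32.0
    outer_um: float = 180.0
    ilm_offset_um: float = 120.0
    noise_sd_um: float = 1.5

    def resolved_fovea(self) -> Tuple[int, int]:
        if self.fovea_center is not None:
            return self.fovea_center
        g = self.geometry
        return (g.n_bscans // 2, g.n_ascans // 2)


@dataclass(frozen=True)
class EffectSpec:
    """A focal ground-truth effect injected into one group's maps."""

    layer: str
    shape: str                      # "disc" | "annulus" | "sector"
    delta_um: float
    center: Optional[Tuple[float, float]] = None     # grid coords
    radius: float = 8.0
    radius_inner: float = 0.0
    units: str = "voxel"            # "voxel" (index distance) or "um"
    col_range: Optional[Tuple[int, int]] = None      # for "sector"

    def mask(self, geometry: ScanGeometry,
             fovea: Tuple[int, int]) -> np.ndarray:
        center = self.center if self.center is not None else fovea
        shape = geometry.shape
        if self.shape == "sector":
            m = np.zeros(shape, dtype=bool)
            c0, c1 = self.col_range or (0, shape[1])
            m[:, c0:c1] = True
            return m
        if self.units == "um":
            dist = grid_distance_um(shape, center, geometry)
        elif self.units == "voxel":
            rows = np.arange(shape[0])[:, None] - center[0]
            cols = np.arange(shape[1])[None, :] - center[1]
            dist = np.hypot(rows, cols)
        else:
            raise DegenerateInputError(f"unknown units {self.units!r}")
        if self.shape == "disc":
            m = dist <= self.radius
        elif self.shape == "annulus":
            m = (dist >= self.radius_inner) & (dist <= self.radius)
        else:
            raise DegenerateInputError(f"unknown shape {self.shape!r}")
        if not m.any():
            raise GeometryError("effect shape lies outside the grid")
        return m


@dataclass
class SubjectScan:
    """One simulated subject scan plus its ground truth."""

    subject_id: str
    group: str
    maps: Dict[str, ThicknessMap]
    boundaries: BoundarySet
    true_jitter: Tuple[int, int]


@dataclass
class Cohort:
    """A simulated multi-group cohort with ground truth attached."""

    scans: List[SubjectScan]
    covariates: pd.DataFrame
    template_spec: TemplateSpec
    effect_masks: Dict[str, Dict[str, np.ndarray]]   # group -> layer -> mask


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------

def _component_fields(spec: TemplateSpec,
                      fovea: Tuple[int, int]) -> Dict[str, np.ndarray]:
    g = spec.geometry
    r = grid_distance_um(g.shape, fovea, g)
    pit = 1.0 - np.exp(-((r / spec.pit_radius_um) ** 2))
    # distance from the temporal (high-column) edge, in mm: the ONH sits
    # on the low-column side after left-normalization
    x_from_temporal_mm = ((g.n_ascans - 1 - np.arange(g.n_ascans))
                          * g.col_pitch_um / 1000.0)[None, :]
    x_from_temporal_mm = np.broadcast_to(x_from_temporal_mm, g.shape)
    rnfl = (spec.rnfl_base_um
            + spec.rnfl_onh_gradient_um_per_mm * x_from_temporal_mm) * pit
    annulus = spec.gcipl_annulus_amp_um * np.exp(
        -(((r - spec.gcipl_annulus_r_um) / spec.gcipl_annulus_width_um) ** 2))
    gcipl = (spec.gcipl_base_um + annulus) * pit
    inl = spec.inl_base_um * pit
    outer = np.full(g.shape, spec.outer_um)
    return {"RNFL": rnfl, "GCIPL": gcipl, "INL": inl, "outer": outer}


def _maps_and_boundaries(components: Dict[str, np.ndarray],
                         spec: TemplateSpec,
                         subject_id: Optional[str] = None,
                         ) -> Tuple[Dict[str, ThicknessMap], BoundarySet]:
    g = spec.geometry
    rnfl, gcipl, inl = (components[k] for k in INNER_LAYERS)
    outer = components["outer"]
    retina = rnfl + gcipl + inl + outer
    # the ILM dips where the retina is thin, producing the pit profile
    finite_max = np.nanmax(retina)
    ilm = spec.ilm_offset_um + (finite_max - retina) * 0.6
    surfaces = {
        "ILM": ilm,
        "RNFL/GCL": ilm + rnfl,
        "IPL/INL": ilm + rnfl + gcipl,
        "INL/OPL": ilm + rnfl + gcipl + inl,
        "BM": ilm + retina,
    }
    boundaries = BoundarySet(surfaces=surfaces, geometry=g,
                             laterality="left-normalized")
    maps = {}
    for layer, values in (("RNFL", rnfl), ("GCIPL", gcipl), ("INL", inl),
                          ("Retina", retina)):
        maps[layer] = ThicknessMap(values=values.copy(), layer=layer,
                                   laterality="left-normalized", geometry=g,
                                   subject_id=subject_id)
    return maps, boundaries


def make_template(spec: Optional[TemplateSpec] = None,
                  ) -> Tuple[Dict[str, ThicknessMap], BoundarySet]:
    """Noise-free template maps and boundary set.

    The Retina map has its unique (smoothed) minimum at the configured
    fovea centre.
    """
    spec = spec or TemplateSpec()
    fovea = spec.resolved_fovea()
    components = _component_fields(spec, fovea)
    return _maps_and_boundaries(components, spec)


def template_target(spec: Optional[TemplateSpec] = None) -> TargetGrid:
    """Target space anchored on the template anatomy.

    The target fovea is *detected* from the template Retina map with the
    default detector rather than copied from the spec, so subject and
    target landmarks share any smoothing-induced offset and the
    recovered translation equals minus the true jitter exactly.
    """
    from .registration import target_from_scan

    spec = spec or TemplateSpec()
    maps, boundaries = make_template(spec)
    return target_from_scan(maps, boundaries)


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

def _shift2d(arr: np.ndarray, jitter: Tuple[int, int]) -> np.ndarray:
    dr, dc = int(jitter[0]), int(jitter[1])
    out = np.full_like(arr, np.nan)
    r0, r1 = max(0, dr), min(arr.shape[0], arr.shape[0] + dr)
    c0, c1 = max(0, dc), min(arr.shape[1], arr.shape[1] + dc)
    if r1 > r0 and c1 > c0:
        out[r0:r1, c0:c1] = arr[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    return out


def sample_subject(spec: TemplateSpec,
                   jitter: Tuple[int, int] = (0, 0),
                   noise_sd_um: Optional[float] = None,
                   rng: Optional[np.random.Generator] = None,
                   seed: Optional[int] = None,
                   subject_id: Optional[str] = None,
                   effects: Sequence[EffectSpec] = (),
                   latent_offsets: Optional[Dict[str, np.ndarray]] = None,
                   ) -> SubjectScan:
    """Draw one subject: template shifted by an integer fovea jitter,
    optional focal effects, plus independent Gaussian noise per layer.

    Noise is added to the RNFL/GCIPL/INL/outer components independently
    (so the Retina map is their consistent sum) and clipped at zero; the
    boundary set is rebuilt from the noisy components, so the anatomical
    surface order always holds.
    """
    g = spec.geometry
    if abs(jitter[0]) >= g.n_bscans or abs(jitter[1]) >= g.n_ascans:
        raise GeometryError(f"jitter {jitter} out of grid range")
    if rng is None:
        rng = np.random.default_rng(seed)
    sd = spec.noise_sd_um if noise_sd_um is None else noise_sd_um

    fovea = spec.resolved_fovea()
    components = _component_fields(spec, fovea)
    for eff in effects:
        mask = eff.mask(g, fovea)
        components[eff.layer] = components[eff.layer] + eff.delta_um * mask
    if latent_offsets:
        for layer, off in latent_offsets.items():
            components[layer] = components[layer] + off
    shifted_fovea = (fovea[0] + jitter[0], fovea[1] + jitter[1])
    out = {}
    for name, values in components.items():
        v = _shift2d(values, jitter)
        if sd > 0:
            v = v + rng.normal(0.0, sd, size=v.shape)
        out[name] = np.clip(v, 0.0, None)
    maps, boundaries = _maps_and_boundaries(out, spec,
                                            subject_id=subject_id)
    if not (0 <= shifted_fovea[0] < g.n_bscans
            and 0 <= shifted_fovea[1] < g.n_ascans):
        raise GeometryError(f"jitter {jitter} pushes the fovea off-grid")
    return SubjectScan(subject_id=subject_id or "subject",
                       group="", maps=maps, boundaries=boundaries,
                       true_jitter=(int(jitter[0]), int(jitter[1])))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _draw_covariates(rng: np.random.Generator, group: str,
                     n: int) -> pd.DataFrame:
    """Cohort-plausible covariates; HC rows carry explicit NaN for the
    disease scores."""
    age = np.clip(rng.normal(35.0, 10.0, size=n), 18.0, 70.0)
    sex = np.where(rng.random(n) < 0.4, "M", "F")
    if group == "HC":
        edss = np.full(n, np.nan)
        duration = np.full(n, np.nan)
    else:
        edss = np.clip(rng.normal(1.5, 1.0, size=n), 0.0, 9.5)
        duration = np.clip(rng.normal(5.0, 4.0, size=n), 0.0, 40.0)
    return pd.DataFrame({"group": group, "age": age, "sex": sex,
                         "edss": edss, "disease_duration": duration})


def make_cohort(spec: TemplateSpec,
                groups: Sequence[Tuple[str, int, Sequence[EffectSpec]]],
                noise_sd_um: Optional[float] = None,
                jitter_rows: int = 0,
                jitter_cols: int = 0,
                seed: int = 0) -> Cohort:
    """Simulate a multi-group cohort.

    ``groups`` is a list of (label, n_subjects, effects).  Each subject
    gets an integer fovea jitter drawn uniformly from
    ``[-jitter_rows, +jitter_rows] x [-jitter_cols, +jitter_cols]``,
    the group's focal effects, and fresh measurement noise.  Overlapping
    effects on one layer sum.  Ground-truth effect masks are recorded
    per group and layer.
    """
    labels = [g[0] for g in groups]
    if len(set(labels)) != len(labels):
        raise DegenerateInputError(f"duplicate group labels {labels}")
    rng = np.random.default_rng(seed)
    fovea = spec.resolved_fovea()
    scans: List[SubjectScan] = []
    cov_frames = []
    effect_masks: Dict[str, Dict[str, np.ndarray]] = {}
    sid = 0
    for label, n, effects in groups:
        masks: Dict[str, np.ndarray] = {}
        for eff in effects:
            m = eff.mask(spec.geometry, fovea)
            masks[eff.layer] = masks.get(eff.layer, np.zeros_like(m)) | m
        effect_masks[label] = masks
        cov = _draw_covariates(rng, label, n)
        cov.insert(0, "subject_id", [f"S{sid + i:04d}" for i in range(n)])
        cov.insert(1, "eye", "OS")
        cov_frames.append(cov)
        for i in range(n):
            jr = int(rng.integers(-jitter_rows, jitter_rows + 1)) \
                if jitter_rows else 0
            jc = int(rng.integers(-jitter_cols, jitter_cols + 1)) \
                if jitter_cols else 0
            scan = sample_subject(spec, jitter=(jr, jc),
                                  noise_sd_um=noise_sd_um, rng=rng,
                                  subject_id=f"S{sid:04d}", effects=effects)
            scan.group = label
            scans.append(scan)
            sid += 1
    covariates = pd.concat(cov_frames, ignore_index=True)
    return Cohort(scans=scans, covariates=covariates, template_spec=spec,
                  effect_masks=effect_masks)


def make_retest(spec: TemplateSpec, n_subjects: int = 10,
                between_sd_um: float = 5.0, within_sd_um: float = 1.5,
                n_sessions: int = 2, layer: str = "GCIPL",
                seed: int = 0) -> RetestStack:
    """Same-day repeated scans with known variance components.

    Each subject has a latent deviation from the template (per-voxel
    Gaussian, SD ``between_sd_um``) measured ``n_sessions`` times with
    independent noise (SD ``within_sd_um``); the ground-truth ICC is
    ``between^2 / (between^2 + within^2)`` and the ground-truth Sw is
    ``within_sd_um``.
    """
    if n_subjects < 2:
        raise DegenerateInputError("retest needs >= 2 subjects")
    rng = np.random.default_rng(seed)
    maps, _ = make_template(spec)
    base = maps[layer].values
    shape = base.shape
    data = np.empty((n_subjects, n_sessions) + shape)
    for i in range(n_subjects):
        latent = base + rng.normal(0.0, between_sd_um, size=shape)
        for s in range(n_sessions):
            data[i, s] = latent + rng.normal(0.0, within_sd_um, size=shape)
    return RetestStack(data=data, layer=layer, same_day=True)


# ---------------------------------------------------------------------------
# convenience: cohort -> registered group stacks
# ---------------------------------------------------------------------------

def cohort_stacks(cohort: Cohort, register: bool = True,
                  target: Optional[TargetGrid] = None,
                  ) -> Dict[str, "GroupStack"]:
    """Register every cohort scan (when asked) and build one GroupStack
    per layer, eye-level (one synthetic eye per subject)."""
    from .mapping import build_group_stack
    from .registration import register_scan

    spec = cohort.template_spec
    if register:
        target = target or template_target(spec)
    per_layer: Dict[str, list] = {k: [] for k in
                                  ("RNFL", "GCIPL", "INL", "Retina")}
    for scan in cohort.scans:
        if register:
            maps, _ = register_scan(scan.maps, scan.boundaries, target)
        else:
            maps = {k: m.copy_with(registered=True)
                    for k, m in scan.maps.items()}
        for layer, m in maps.items():
            per_layer[layer].append(m)
    return {layer: build_group_stack(maps_list, cohort.covariates,
                                     eye_policy="eye-level")
            for layer, maps_list in per_layer.items()}
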