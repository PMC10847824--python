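"""Spatial normalization of macular scans to a common target space.

The normalization has two parts:

1. a global 2D en-face translation that moves the subject's fovea (the
   thinnest retinal point) onto the target fovea, and
2. a per-A-line 1D affine ``z -> a*z + b`` in depth that maps the
   subject's ILM and BM onto the target's ILM and BM exactly.

The translation is integer-valued on the en-face grid by default, so
registration never interpolates thickness values; cells translated in
from outside the field are marked invalid.  The depth affine aligns
depth *coordinates* for correspondence — layer thickness values are NOT
rescaled by its slope by default (``rescale_thickness=False``), since
total retinal thickness is later used as a per-voxel covariate and would
be meaningless if registration normalized it away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DegenerateInputError, FoveaError, GeometryError, LateralityError
from .geometry import ScanGeometry, TargetGrid
from .io import BoundarySet, OCTVolume, ThicknessMap

#: Physical width of the fovea-detection smoothing kernel.  Specified in
#: micrometres so the effective kernel is isotropic on the strongly
#: anisotropic B-scan x A-scan grid; wide enough that measurement noise
#: cannot move the integer landmark (the pit is hundreds of um wide).
FOVEA_SMOOTH_SIGMA_UM = 400.0


@dataclass
class RegistrationTransform:
    """One en-face translation plus per-A-line depth affine for a scan."""

    translation: Tuple[int, int]  # (d_row, d_col), added to subject coords
    scale: Optional[np.ndarray] = field(default=None, repr=False)   # a
    offset: Optional[np.ndarray] = field(default=None, repr=False)  # b
    target: Optional[TargetGrid] = None

    def to_json_dict(self) -> dict:
        d = {"translation": list(self.translation)}
        if self.scale is not None:
            d["scale"] = np.where(np.isfinite(self.scale), self.scale,
                                  None).tolist()
            d["offset"] = np.where(np.isfinite(self.offset), self.offset,
                                   None).tolist()
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "RegistrationTransform":
        scale = offset = None
        if "scale" in d:
            scale = np.array(
                [[np.nan if v is None else v for v in row] for row in d["scale"]],
                dtype=float)
            offset = np.array(
                [[np.nan if v is None else v for v in row] for row in d["offset"]],
                dtype=float)
        return cls(translation=tuple(d["translation"]), scale=scale,
                   offset=offset)


# ---------------------------------------------------------------------------
# intensity-domain steps
# ---------------------------------------------------------------------------

def normalize_intensity(v: OCTVolume, reference_mean: float,
                        reference_sd: float,
                        mask: Optional[np.ndarray] = None) -> OCTVolume:
    """Affine-standardize volume intensities to a reference mean/SD.

    The map is monotone affine, so the rank order of voxel intensities is
    preserved.  ``mask`` (same shape as the volume) restricts the
    statistics to retina voxels when provided.
    """
    data = v.intensity if mask is None else v.intensity[mask]
    mu, sd = float(np.mean(data)), float(np.std(data))
    if sd == 0.0:
        raise DegenerateInputError("volume has zero intensity variance")
    a = reference_sd / sd
    out = (v.intensity - mu) * a + reference_mean
    return OCTVolume(intensity=out, geometry=v.geometry,
                     laterality=v.laterality, subject_id=v.subject_id,
                     session_id=v.session_id)


def extract_retina(v: OCTVolume, b: BoundarySet,
                   background: float = np.nan) -> OCTVolume:
    """Mask intensities outside the [ILM, BM] band of each A-line."""
    if b.geometry.shape != v.geometry.shape:
        raise GeometryError("boundary geometry does not match volume")
    depth = v.depth_axis_um()[None, :, None]                 # (1, D, 1)
    ilm = b.surfaces["ILM"][:, None, :]                      # (B, 1, A)
    bm = b.surfaces["BM"][:, None, :]
    inside = (depth >= ilm) & (depth <= bm)                  # NaN bounds -> False
    out = np.where(inside, v.intensity, background)
    return OCTVolume(intensity=out, geometry=v.geometry,
                     laterality=v.laterality, subject_id=v.subject_id,
                     session_id=v.session_id)


# ---------------------------------------------------------------------------
# landmark + transform estimation
# ---------------------------------------------------------------------------

def _nan_gaussian(values: np.ndarray, sigma: Tuple[float, float]) -> np.ndarray:
    """Gaussian smoothing that ignores NaN cells (normalized convolution)."""
    valid = np.isfinite(values)
    filled = np.where(valid, values, 0.0)
    num = gaussian_filter(filled, sigma=sigma, mode="nearest")
    den = gaussian_filter(valid.astype(float), sigma=sigma, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 1e-12] = np.nan
    out[~valid] = np.nan
    return out


#: Depth (um above the smoothed minimum) of the sub-level set used for
#: the sub-voxel pit centroid.
FOVEA_CENTROID_DEPTH_UM = 10.0


def _smoothed_retina(retina: ThicknessMap,
                     smooth_sigma_um: float) -> np.ndarray:
    if retina.layer != "Retina":
        raise FoveaError("fovea detection requires a Retina-layer map")
    if not retina.validity_mask.any():
        raise FoveaError("all-invalid retina map: no fovea")
    if smooth_sigma_um <= 0:
        return retina.values
    g = retina.geometry
    sigma = (smooth_sigma_um / g.row_pitch_um,
             smooth_sigma_um / g.col_pitch_um)
    return _nan_gaussian(retina.values, sigma)


def detect_fovea_subvoxel(retina: ThicknessMap,
                          smooth_sigma_um: float = FOVEA_SMOOTH_SIGMA_UM,
                          ) -> Tuple[float, float]:
    """Continuous fovea position: centre of mass of the pit bottom.

    After smoothing, voxels within :data:`FOVEA_CENTROID_DEPTH_UM` of
    the minimum are weighted by their depth below that cutoff and the
    weighted centroid is returned.  The estimator is translation
    equivariant, so *differences* of sub-voxel positions between two
    scans of the same anatomy recover integer shifts exactly.
    """
    from scipy.ndimage import label as _cc_label

    smoothed = _smoothed_retina(retina, smooth_sigma_um)
    vmin = np.nanmin(smoothed)
    w = (vmin + FOVEA_CENTROID_DEPTH_UM) - smoothed
    w = np.where(np.isfinite(w) & (w > 0), w, 0.0)
    # keep only the pit containing the global minimum: the sub-level set
    # may also touch other shallow regions of the map
    labels, _ = _cc_label(w > 0, structure=np.ones((3, 3), dtype=int))
    argmin = np.unravel_index(np.nanargmin(np.where(np.isfinite(smoothed),
                                                    smoothed, np.inf)),
                              smoothed.shape)
    w = np.where(labels == labels[argmin], w, 0.0)
    total = w.sum()
    rows = np.arange(w.shape[0])[:, None]
    cols = np.arange(w.shape[1])[None, :]
    return (float((w * rows).sum() / total),
            float((w * cols).sum() / total))


def detect_fovea(retina: ThicknessMap,
                 smooth_sigma_um: float = FOVEA_SMOOTH_SIGMA_UM,
                 ) -> Tuple[int, int]:
    """Locate the fovea as the thinnest point of the retina map.

    The map is smoothed with a Gaussian of physical width
    ``smooth_sigma_um`` (converted to per-axis voxel sigmas) before the
    argmin, which makes the integer landmark stable against measurement
    noise.  Ties are broken by the centroid of the minimum set, rounded
    to the nearest grid point.
    """
    smoothed = _smoothed_retina(retina, smooth_sigma_um)
    vmin = np.nanmin(smoothed)
    min_set = np.argwhere(np.isfinite(smoothed) & (smoothed <= vmin + 1e-12))
    centroid = min_set.mean(axis=0)
    r, c = int(np.rint(centroid[0])), int(np.rint(centroid[1]))
    return (r, c)


def compute_global_translation(subject_fovea: Tuple[float, float],
                               target: TargetGrid) -> Tuple[int, int]:
    """Integer grid shift moving the subject fovea onto the target fovea.

    Accepts integer or sub-voxel positions; when the target carries a
    sub-voxel fovea estimate the difference is formed at sub-voxel
    precision and then rounded, so a landmark bias shared by subject and
    target cancels before rounding.
    """
    subvoxel_input = any(isinstance(v, (float, np.floating))
                         for v in subject_fovea)
    if subvoxel_input and getattr(target, "fovea_subvoxel", None) is not None:
        t_r, t_c = target.fovea_subvoxel
    else:
        t_r, t_c = target.fovea_position
    return (int(np.rint(t_r - subject_fovea[0])),
            int(np.rint(t_c - subject_fovea[1])))


def apply_translation(values: np.ndarray, translation: Tuple[int, int],
                      out_shape: Optional[Tuple[int, int]] = None,
                      fill: float = np.nan) -> np.ndarray:
    """Shift a 2D array by integer (d_row, d_col) without interpolation.

    Cells translated from outside the source field are filled with
    ``fill`` (NaN = invalid).
    """
    dr, dc = int(translation[0]), int(translation[1])
    src = np.asarray(values, dtype=float)
    out_shape = src.shape if out_shape is None else out_shape
    out = np.full(out_shape, fill, dtype=float)
    # destination cell (i, j) takes source cell (i - dr, j - dc)
    r0_dst, r1_dst = max(0, dr), min(out_shape[0], src.shape[0] + dr)
    c0_dst, c1_dst = max(0, dc), min(out_shape[1], src.shape[1] + dc)
    if r1_dst > r0_dst and c1_dst > c0_dst:
        out[r0_dst:r1_dst, c0_dst:c1_dst] = \
            src[r0_dst - dr:r1_dst - dr, c0_dst - dc:c1_dst - dc]
    return out


def fit_aline_affine(subject_ilm: float, subject_bm: float,
                     target_ilm: float, target_bm: float,
                     ) -> Tuple[float, float]:
    """Depth affine (a, b) mapping one subject A-line onto the target.

    Anchored at the two boundary surfaces: subject ILM maps to target
    ILM and subject BM to target BM exactly.
    """
    span = subject_bm - subject_ilm
    if not np.isfinite(span) or span <= 0:
        raise DegenerateInputError(
            f"degenerate A-line: subject retinal span {span!r} <= 0")
    if target_bm - target_ilm <= 0:
        raise DegenerateInputError("degenerate target retinal span")
    a = (target_bm - target_ilm) / span
    b = target_ilm - a * subject_ilm
    return (a, b)


def fit_aline_affine_grid(subject_ilm: np.ndarray, subject_bm: np.ndarray,
                          target_ilm: np.ndarray, target_bm: np.ndarray,
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized per-A-line affine; degenerate A-lines flagged NaN."""
    span = subject_bm - subject_ilm
    tspan = target_bm - target_ilm
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where((span > 0) & (tspan > 0), tspan / span, np.nan)
        b = target_ilm - a * subject_ilm
    return a, b


def register_scan(maps: Dict[str, ThicknessMap],
                  boundaries: Optional[BoundarySet],
                  target: TargetGrid,
                  rescale_thickness: bool = False,
                  smooth_sigma_um: float = FOVEA_SMOOTH_SIGMA_UM,
                  ) -> Tuple[Dict[str, ThicknessMap], RegistrationTransform]:
    """Register one scan's four layer maps to the target space.

    All maps must be left-normalized and share one geometry; a single
    translation (from the Retina-map fovea) is applied to all four maps,
    and the per-A-line depth affine is stored in the transform.  With
    ``rescale_thickness=False`` (default) thickness values are carried
    over unchanged from the boundary differences.
    """
    if "Retina" not in maps:
        raise GeometryError("registration needs the Retina map")
    for m in maps.values():
        if m.laterality != "left-normalized":
            raise LateralityError(
                "maps must be flipped to left-eye orientation before "
                "registration")
    fovea = detect_fovea_subvoxel(maps["Retina"],
                                  smooth_sigma_um=smooth_sigma_um)
    translation = compute_global_translation(fovea, target)

    if boundaries is not None:
        ilm_t = apply_translation(boundaries.surfaces["ILM"], translation,
                                  out_shape=target.shape)
        bm_t = apply_translation(boundaries.surfaces["BM"], translation,
                                 out_shape=target.shape)
    else:
        # maps-only registration: no depth anchors, affine left identity
        ilm_t = apply_translation(maps["Retina"].values * 0.0, translation,
                                  out_shape=target.shape)
        bm_t = ilm_t
    if boundaries is not None and target.ilm_depth is not None \
            and target.bm_depth is not None:
        a, b = fit_aline_affine_grid(ilm_t, bm_t,
                                     target.ilm_depth, target.bm_depth)
    else:
        a = np.where(np.isfinite(ilm_t), 1.0, np.nan)
        b = np.where(np.isfinite(ilm_t), 0.0, np.nan)

    transform = RegistrationTransform(translation=translation, scale=a,
                                      offset=b, target=target)
    registered: Dict[str, ThicknessMap] = {}
    tgt_geometry = target.geometry or maps["Retina"].geometry
    for layer, m in maps.items():
        values = apply_translation(m.values, translation,
                                   out_shape=target.shape)
        if rescale_thickness:
            values = values * a
        registered[layer] = ThicknessMap(
            values=values, layer=layer, laterality="left-normalized",
            geometry=tgt_geometry.crop_columns(target.n_cols)
            if tgt_geometry.shape != target.shape else tgt_geometry,
            registered=True, subject_id=m.subject_id, eye=m.eye)
    return registered, transform


# ---------------------------------------------------------------------------
# target-space construction
# ---------------------------------------------------------------------------

def target_from_scan(maps: Dict[str, ThicknessMap], boundaries: BoundarySet,
                     smooth_sigma_um: float = FOVEA_SMOOTH_SIGMA_UM,
                     source: str = "designated-reference") -> TargetGrid:
    """Target space anchored on one designated reference scan."""
    fovea = detect_fovea(maps["Retina"], smooth_sigma_um=smooth_sigma_um)
    subvox = detect_fovea_subvoxel(maps["Retina"],
                                   smooth_sigma_um=smooth_sigma_um)
    g = maps["Retina"].geometry
    return TargetGrid(n_rows=g.n_bscans, n_cols=g.n_ascans,
                      fovea_position=fovea, source=source, geometry=g,
                      ilm_depth=boundaries.surfaces["ILM"].copy(),
                      bm_depth=boundaries.surfaces["BM"].copy(),
                      fovea_subvoxel=subvox)


def build_mean_template(scans: Sequence[Tuple[Dict[str, ThicknessMap],
                                              BoundarySet]],
                        reference_index: int = 0,
                        smooth_sigma_um: float = FOVEA_SMOOTH_SIGMA_UM,
                        ) -> TargetGrid:
    """Cohort-mean target space.

    Registers every scan to a designated reference scan, averages the
    translated ILM/BM surfaces and re-anchors the target on the average
    (one re-registration pass).  Returns the resulting TargetGrid.
    """
    if not scans:
        raise GeometryError("empty scan list")
    ref_maps, ref_bounds = scans[reference_index]
    target = target_from_scan(ref_maps, ref_bounds,
                              smooth_sigma_um=smooth_sigma_um)

    def _mean_surfaces(tgt: TargetGrid):
        ilms, bms, retinas = [], [], []
        for maps, bounds in scans:
            fov = detect_fovea_subvoxel(maps["Retina"],
                                        smooth_sigma_um=smooth_sigma_um)
            tr = compute_global_translation(fov, tgt)
            ilms.append(apply_translation(bounds.surfaces["ILM"], tr,
                                          out_shape=tgt.shape))
            bms.append(apply_translation(bounds.surfaces["BM"], tr,
                                         out_shape=tgt.shape))
            retinas.append(apply_translation(maps["Retina"].values, tr,
                                             out_shape=tgt.shape))
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # grid margins may be invalid in every scan after translation
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return (np.nanmean(ilms, axis=0), np.nanmean(bms, axis=0),
                    np.nanmean(retinas, axis=0))

    ilm_mean, bm_mean, retina_mean = _mean_surfaces(target)
    mean_map = ThicknessMap(values=retina_mean, layer="Retina",
                            laterality="left-normalized",
                            geometry=ref_maps["Retina"].geometry)
    fovea = detect_fovea(mean_map, smooth_sigma_um=smooth_sigma_um)
    subvox = detect_fovea_subvoxel(mean_map,
                                   smooth_sigma_um=smooth_sigma_um)
    target = TargetGrid(n_rows=target.n_rows, n_cols=target.n_cols,
                        fovea_position=fovea, source="cohort-mean-template",
                        geometry=target.geometry,
                        ilm_depth=ilm_mean, bm_depth=bm_mean,
                        fovea_subvoxel=subvox)
    # one re-registration pass against the averaged anatomy
    ilm_mean, bm_mean, _ = _mean_surfaces(target)
    target.ilm_depth = ilm_mean
    target.bm_depth = bm_mean
    return target
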