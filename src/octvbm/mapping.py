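"""Group map stacks, percentage-change maps and standard OCT parameters.

A :class:`GroupStack` collects the registered maps of one layer into a
``subject x row x col`` array joined to the covariate table, which is
what the voxel-wise statistics operate on.  Standard summary parameters
(macular layer volumes, peripapillary ring sectors) are provided for
sensitivity comparisons against the voxel-wise results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, GeometryError, StackError
from .geometry import ScanGeometry, TargetGrid, grid_distance_um
from .io import RingProfile, ThicknessMap, validate_covariates


@dataclass
class GroupStack:
    """Aligned subject x row x col thickness array for one layer."""

    layer: str
    data: np.ndarray                      # (n, rows, cols), NaN = invalid
    covariates: pd.DataFrame              # one row per stack entry
    geometry: Optional[ScanGeometry] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise StackError("stack data must be 3D (subject, row, col)")
        if len(self.covariates) != self.data.shape[0]:
            raise StackError(
                f"covariate rows ({len(self.covariates)}) != stack entries "
                f"({self.data.shape[0]})")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return self.data.shape[1:]

    @property
    def validity(self) -> np.ndarray:
        """Per-voxel count of valid subjects."""
        return np.isfinite(self.data).sum(axis=0)

    def mean_map(self) -> np.ndarray:
        valid = np.isfinite(self.data)
        counts = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(valid, self.data, 0.0).sum(axis=0) / counts
        out[counts == 0] = np.nan
        return out

    def subset(self, index) -> "GroupStack":
        index = np.asarray(index)
        return GroupStack(layer=self.layer, data=self.data[index],
                          covariates=self.covariates.iloc[index]
                          .reset_index(drop=True),
                          geometry=self.geometry)


@dataclass
class FoveaMask:
    """Boolean exclusion mask around the target fovea (True = excluded)."""

    mask: np.ndarray
    radius_um: float


def build_group_stack(maps: Sequence[ThicknessMap], cov: pd.DataFrame,
                      eye_policy: str = "average-within-subject",
                      ) -> GroupStack:
    """Assemble registered maps of one layer into a group stack.

    With ``average-within-subject`` the two eye maps of a subject are
    voxel-wise averaged over mutually valid voxels, so the stack has one
    entry per subject; ``eye-level`` keeps one entry per eye.
    """
    if not maps:
        raise StackError("no maps given")
    layer = maps[0].layer
    shape = maps[0].values.shape
    for m in maps:
        if m.layer != layer:
            raise StackError(f"mixed layers: {layer} vs {m.layer}")
        if m.values.shape != shape:
            raise StackError("maps registered to different grids")
        if not m.registered:
            raise StackError(
                f"map for subject {m.subject_id!r} is not registered")
        if m.subject_id is None:
            raise StackError("every map needs a subject_id")
    cov = validate_covariates(cov)

    if eye_policy == "eye-level":
        rows, data = [], []
        for m in maps:
            sel = cov[cov["subject_id"] == m.subject_id]
            if m.eye is not None and "eye" in sel.columns and \
                    (sel["eye"] == m.eye).any():
                sel = sel[sel["eye"] == m.eye]
            if sel.empty:
                raise StackError(f"no covariates for subject {m.subject_id!r}")
            row = sel.iloc[0].copy()
            row["eye"] = m.eye
            rows.append(row)
            data.append(m.values)
        table = pd.DataFrame(rows).reset_index(drop=True)
        return GroupStack(layer=layer, data=np.stack(data), covariates=table,
                          geometry=maps[0].geometry)

    if eye_policy != "average-within-subject":
        raise StackError(f"unknown eye policy {eye_policy!r}")

    by_subject: Dict[str, list] = {}
    order = []
    for m in maps:
        if m.subject_id not in by_subject:
            order.append(m.subject_id)
        by_subject.setdefault(m.subject_id, []).append(m.values)
    data, rows = [], []
    for sid in order:
        stack = np.stack(by_subject[sid])
        valid = np.isfinite(stack)
        counts = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = np.where(valid, stack, 0.0).sum(axis=0) / counts
        avg[counts == 0] = np.nan
        data.append(avg)
        sel = cov[cov["subject_id"] == sid]
        if sel.empty:
            raise StackError(f"no covariates for subject {sid!r}")
        row = sel.iloc[0].copy()
        row["eye"] = "OU" if len(by_subject[sid]) > 1 else row.get("eye", "OU")
        rows.append(row)
    table = pd.DataFrame(rows).reset_index(drop=True)
    return GroupStack(layer=layer, data=np.stack(data), covariates=table,
                      geometry=maps[0].geometry)


def percentage_change_map(patient_stack: GroupStack,
                          hc_stack: GroupStack) -> np.ndarray:
    """Voxel-wise percent change of the patient group versus controls:
    ``(mean_patient - mean_HC) / mean_HC * 100``.

    Voxels where the control mean is zero (or invalid) come back NaN.
    """
    if patient_stack.layer != hc_stack.layer:
        raise StackError("percentage change requires matching layers")
    if patient_stack.grid_shape != hc_stack.grid_shape:
        raise StackError("stacks on different grids")
    mean_p = patient_stack.mean_map()
    mean_h = hc_stack.mean_map()
    valid_h = np.isfinite(mean_h) & (mean_h != 0)
    if not valid_h.any():
        raise DegenerateInputError("control mean map is zero/invalid everywhere")
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = (mean_p - mean_h) / mean_h * 100.0
    pct[~valid_h] = np.nan
    return pct


def fovea_exclusion_mask(target: TargetGrid, radius_um: float = 500.0,
                         geometry: Optional[ScanGeometry] = None) -> FoveaMask:
    """Central-fovea exclusion mask: True on voxels whose centre lies
    within ``radius_um`` of the target fovea (radius 0 = empty mask)."""
    if radius_um < 0:
        raise DegenerateInputError("radius must be >= 0")
    g = geometry or target.geometry
    if g is None:
        raise GeometryError("target has no geometry for distance computation")
    if g.shape != target.shape:
        g = g.crop_columns(target.n_cols)
    dist = grid_distance_um(target.shape, target.fovea_position, g)
    if radius_um == 0:
        mask = np.zeros(target.shape, dtype=bool)
    else:
        mask = dist <= radius_um
    return FoveaMask(mask=mask, radius_um=radius_um)


def macular_layer_volume(tm: ThicknessMap, region: str = "full-field",
                         diameter_mm: Optional[float] = None,
                         center: Optional[Tuple[float, float]] = None,
                         ) -> float:
    """Macular layer volume in mm^3: sum of thickness x voxel area over
    the region (``full-field`` or ``circle`` of ``diameter_mm`` centred
    on ``center``, default the grid centre)."""
    g = tm.geometry
    valid = tm.validity_mask
    if region == "circle":
        if diameter_mm is None:
            raise DegenerateInputError("circle region needs diameter_mm")
        if center is None:
            center = ((g.n_bscans - 1) / 2.0, (g.n_ascans - 1) / 2.0)
        dist = grid_distance_um(tm.values.shape, center, g)
        valid = valid & (dist <= diameter_mm * 1000.0 / 2.0)
    elif region != "full-field":
        raise DegenerateInputError(f"unknown region {region!r}")
    if not valid.any():
        raise DegenerateInputError("no valid voxels in requested region")
    thickness_mm = tm.values[valid] / 1000.0
    return float(np.sum(thickness_mm) * g.voxel_area_mm2)


def _sector_mean(ring: RingProfile, start_deg: float, end_deg: float) -> float:
    """Circular mean of the profile over the wrapped arc [start, end]."""
    ang = ring.angles_deg()
    start, end = start_deg % 360.0, end_deg % 360.0
    if start <= end:
        sel = (ang >= start) & (ang <= end)
    else:
        sel = (ang >= start) | (ang <= end)
    if sel.sum() < 1:
        raise GeometryError(
            f"ring profile too coarse for sector [{start_deg}, {end_deg}]")
    return float(np.nanmean(ring.values[sel]))


def peripapillary_sectors(ring: RingProfile,
                          temporal_deg: Tuple[float, float] = (315.0, 45.0),
                          pmb_deg: Tuple[float, float] = (324.0, 36.0),
                          ) -> Dict[str, float]:
    """Global, temporal-quadrant and papillomacular-bundle mean thickness
    of a peripapillary ring profile (left-normalized angles, 0 deg =
    temporal)."""
    return {
        "global": float(np.nanmean(ring.values)),
        "temporal": _sector_mean(ring, *temporal_deg),
        "PMB": _sector_mean(ring, *pmb_deg),
    }
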