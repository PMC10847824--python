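"""Scan geometry and target-space grids.

A macular volume scan is a stack of B-scans (rows of the en-face grid),
each composed of A-scans (columns).  The default geometry matches a
common spectral-domain acquisition: 25 B-scans x 1024 A-scans covering a
20 deg x 20 deg field, 240 um between B-scans, 3.87 um axial sampling.

Conventions
-----------
* row index = B-scan, 0 = most superior; column index = A-scan position,
  0-based.
* Degrees are converted to retinal distance with a configurable factor
  (default 288 um/deg).
* After left-normalization the optic nerve head lies on the low-column
  side of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import GeometryError

#: Default conversion between visual angle and retinal distance.
UM_PER_DEGREE_DEFAULT = 288.0


@dataclass(frozen=True)
class ScanGeometry:
    """Geometry of one en-face acquisition grid.

    Parameters
    ----------
    n_bscans, n_ascans
        Grid shape (rows, columns); both must be >= 2.
    field_deg
        (horizontal, vertical) field of view in degrees.
    bscan_spacing_um
        Distance between adjacent B-scans in micrometres.
    axial_resolution_um
        Depth sampling interval in micrometres.
    um_per_degree
        Conversion factor used when reporting mm^2 / mm^3 quantities.
    """

    n_bscans: int = 25
    n_ascans: int = 1024
    field_deg: Tuple[float, float] = (20.0, 20.0)
    bscan_spacing_um: float = 240.0
    axial_resolution_um: float = 3.87
    um_per_degree: float = UM_PER_DEGREE_DEFAULT

    def __post_init__(self) -> None:
        if self.n_bscans < 2 or self.n_ascans < 2:
            raise GeometryError("grid counts must be >= 2")
        if self.bscan_spacing_um <= 0 or self.axial_resolution_um <= 0:
            raise GeometryError("spacings must be > 0")
        if self.field_deg[0] <= 0 or self.field_deg[1] <= 0:
            raise GeometryError("field of view must be > 0 degrees")
        if self.um_per_degree <= 0:
            raise GeometryError("um_per_degree must be > 0")

    @property
    def shape(self) -> Tuple[int, int]:
        """En-face grid shape ``(n_bscans, n_ascans)``."""
        return (self.n_bscans, self.n_ascans)

    @property
    def row_pitch_um(self) -> float:
        """Distance between adjacent rows (B-scans) in um."""
        return self.bscan_spacing_um

    @property
    def col_pitch_um(self) -> float:
        """Distance between adjacent columns (A-scans) in um."""
        return self.field_deg[0] * self.um_per_degree / self.n_ascans

    @property
    def voxel_area_mm2(self) -> float:
        """En-face area of one voxel in mm^2 (anisotropy respected)."""
        return (self.row_pitch_um / 1000.0) * (self.col_pitch_um / 1000.0)

    def crop_columns(self, n_ascans: int) -> "ScanGeometry":
        """Geometry of a grid down-sampled/cropped to ``n_ascans`` columns
        spanning the same horizontal field."""
        return ScanGeometry(
            n_bscans=self.n_bscans,
            n_ascans=n_ascans,
            field_deg=self.field_deg,
            bscan_spacing_um=self.bscan_spacing_um,
            axial_resolution_um=self.axial_resolution_um,
            um_per_degree=self.um_per_degree,
        )

    def to_dict(self) -> dict:
        return {
            "n_bscans": self.n_bscans,
            "n_ascans": self.n_ascans,
            "field_deg": list(self.field_deg),
            "bscan_spacing_um": self.bscan_spacing_um,
            "axial_resolution_um": self.axial_resolution_um,
            "um_per_degree": self.um_per_degree,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            n_bscans=int(d["n_bscans"]),
            n_ascans=int(d["n_ascans"]),
            field_deg=tuple(d.get("field_deg", (20.0, 20.0))),
            bscan_spacing_um=float(d.get("bscan_spacing_um", 240.0)),
            axial_resolution_um=float(d.get("axial_resolution_um", 3.87)),
            um_per_degree=float(d.get("um_per_degree", UM_PER_DEGREE_DEFAULT)),
        )


@dataclass
class TargetGrid:
    """Common analysis space every scan is registered to.

    Optionally carries reference ILM/BM depth surfaces so that the
    per-A-line depth affine can be anchored to the target anatomy; when
    absent the depth affine is left as identity.
    """

    n_rows: int
    n_cols: int
    fovea_position: Tuple[int, int]
    source: str = "designated-reference"  # or "cohort-mean-template"
    geometry: Optional[ScanGeometry] = None
    ilm_depth: Optional[np.ndarray] = field(default=None, repr=False)
    bm_depth: Optional[np.ndarray] = field(default=None, repr=False)
    #: optional continuous landmark estimate; lets registration form the
    #: subject-target difference at sub-voxel precision before rounding
    fovea_subvoxel: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        r, c = self.fovea_position
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise GeometryError(
                f"fovea position {self.fovea_position} outside "
                f"{self.n_rows}x{self.n_cols} grid"
            )
        for name in ("ilm_depth", "bm_depth"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.n_rows, self.n_cols):
                    raise GeometryError(f"{name} shape {arr.shape} != grid")
                setattr(self, name, arr)

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)


def grid_distance_um(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    geometry: ScanGeometry,
) -> np.ndarray:
    """Euclidean distance (um) of every voxel centre from ``center``
    (given in grid coordinates), on an anisotropic grid."""
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    return np.hypot(rows * geometry.row_pitch_um, cols * geometry.col_pitch_um)
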