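"""Portable I/O for thickness maps, boundary sets, volumes and covariates.

Formats
-------
grid-tsv
    Rectangular tab-separated floats plus a JSON sidecar (``<stem>.json``)
    holding layer, laterality, geometry and units.  Lossless round-trip.
float-tiff
    32-bit float TIFF, same sidecar convention.
nifti
    ``.nii``/``.nii.gz`` single 2D image, same sidecar convention.
raw-bin+json
    Volumes as float32 C-order binary plus a JSON header.
csv
    Covariate tables (pandas), one row per subject/eye.

Invalid cells are always encoded as NaN, never zero: zeros would bias
every downstream group statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import (
    GeometryError,
    LateralityError,
    MetadataError,
    SegmentationError,
)
from .geometry import ScanGeometry

LAYERS = ("RNFL", "GCIPL", "INL", "Retina")
SURFACES = ("ILM", "RNFL/GCL", "IPL/INL", "INL/OPL", "BM")
LATERALITIES = ("OD", "OS", "left-normalized")

#: CovariateTable columns expected by the statistics stages.
COVARIATE_COLUMNS = ("subject_id", "eye", "group", "age", "sex", "edss",
                     "disease_duration")


@dataclass
class ThicknessMap:
    """2D en-face grid of layer thickness in micrometres.

    NaN marks invalid cells (failed segmentation, translated from outside
    the field ...).  ``validity_mask`` is derived from the values.
    """

    values: np.ndarray
    layer: str
    laterality: str
    geometry: ScanGeometry
    registered: bool = False
    subject_id: Optional[str] = None
    eye: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GeometryError("thickness map must be 2D")
        if self.layer not in LAYERS:
            raise MetadataError(f"unknown layer {self.layer!r}")
        if self.laterality not in LATERALITIES:
            raise LateralityError(f"unknown laterality {self.laterality!r}")
        if self.values.shape != self.geometry.shape:
            raise GeometryError(
                f"values shape {self.values.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        neg = np.isfinite(self.values) & (self.values < 0)
        if neg.any():
            # negative thickness is physically impossible; flag invalid
            self.values = self.values.copy()
            self.values[neg] = np.nan

    @property
    def validity_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy_with(self, **kw) -> "ThicknessMap":
        return replace(self, **kw)


@dataclass
class BoundarySet:
    """Per-A-line depth (um from the volume top) of the five segmented
    surfaces of one scan.  Invalid A-lines carry NaN in every surface."""

    surfaces: Dict[str, np.ndarray]
    geometry: ScanGeometry
    laterality: str

    def __post_init__(self) -> None:
        if set(self.surfaces) != set(SURFACES):
            raise MetadataError(
                f"boundary set needs surfaces {SURFACES}, got "
                f"{sorted(self.surfaces)}"
            )
        if self.laterality not in LATERALITIES:
            raise LateralityError(f"unknown laterality {self.laterality!r}")
        shp = self.geometry.shape
        for name in SURFACES:
            arr = np.asarray(self.surfaces[name], dtype=float)
            if arr.shape != shp:
                raise GeometryError(f"surface {name} shape {arr.shape} != {shp}")
            self.surfaces[name] = arr
        self.validate_order()

    @property
    def validity_mask(self) -> np.ndarray:
        m = np.ones(self.geometry.shape, dtype=bool)
        for name in SURFACES:
            m &= np.isfinite(self.surfaces[name])
        return m

    def validate_order(self) -> None:
        """Anatomical order ILM <= RNFL/GCL <= IPL/INL <= INL/OPL <= BM must
        hold at every valid A-line."""
        valid = self.validity_mask
        for upper, lower in zip(SURFACES[:-1], SURFACES[1:]):
            bad = valid & (self.surfaces[upper] > self.surfaces[lower] + 1e-9)
            if bad.any():
                coords = np.argwhere(bad)[:5].tolist()
                raise SegmentationError(
                    f"surface order violated ({upper} > {lower}) at A-lines "
                    f"{coords} (first 5 shown)"
                )


@dataclass
class OCTVolume:
    """Raw intensity volume, indexed (bscan, depth, ascan)."""

    intensity: np.ndarray
    geometry: ScanGeometry
    laterality: str
    subject_id: Optional[str] = None
    session_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise GeometryError("volume must be 3D (bscan, depth, ascan)")
        nb, _, na = self.intensity.shape
        if (nb, na) != (self.geometry.n_bscans, self.geometry.n_ascans):
            raise GeometryError(
                f"volume en-face shape ({nb},{na}) does not match geometry "
                f"{self.geometry.shape}"
            )
        if self.laterality not in LATERALITIES:
            raise LateralityError(f"unknown laterality {self.laterality!r}")

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[1]

    def depth_axis_um(self) -> np.ndarray:
        return np.arange(self.n_depth) * self.geometry.axial_resolution_um


@dataclass
class RingProfile:
    """Circular peripapillary thickness profile (um).

    ``start_angle_deg`` is the angle of sample 0 and ``direction`` the
    sign of increasing sample index; by convention 0 deg points at the
    temporal sector of a left-normalized eye.
    """

    values: np.ndarray
    diameter_deg: float = 12.0
    start_angle_deg: float = 0.0
    direction: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 12:
            raise GeometryError("ring profile needs >= 12 samples")
        if self.direction not in (-1, 1):
            raise MetadataError("direction must be +1 or -1")

    @property
    def n_samples(self) -> int:
        return self.values.size

    def angles_deg(self) -> np.ndarray:
        k = np.arange(self.n_samples)
        return np.mod(
            self.start_angle_deg + self.direction * 360.0 * k / self.n_samples,
            360.0,
        )


# ---------------------------------------------------------------------------
# thickness-map file I/O
# ---------------------------------------------------------------------------

_FORMAT_BY_SUFFIX = {
    ".tsv": "grid-tsv",
    ".tif": "float-tiff",
    ".tiff": "float-tiff",
    ".nii": "nifti",
    ".gz": "nifti",
}


def _sidecar_path(path: Path) -> Path:
    name = path.name
    if name.endswith(".nii.gz"):
        return path.with_name(name[: -len(".nii.gz")] + ".json")
    return path.with_suffix(".json")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    fmt = _FORMAT_BY_SUFFIX.get(path.suffix.lower())
    if fmt is None:
        raise MetadataError(f"cannot infer map format from {path.name!r}")
    return fmt


def write_thickness_map(tm: ThicknessMap, path, fmt: Optional[str] = None) -> Path:
    """Write a map plus its JSON sidecar; returns the data path."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "grid-tsv":
        np.savetxt(path, tm.values, delimiter="\t", fmt="%.17g")
    elif fmt == "float-tiff":
        import tifffile

        tifffile.imwrite(path, tm.values.astype(np.float32))
    elif fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(tm.values.astype(np.float32), np.eye(4)),
                 str(path))
    else:
        raise MetadataError(f"unsupported map format {fmt!r}")
    sidecar = {
        "layer": tm.layer,
        "laterality": tm.laterality,
        "units": "um",
        "registered": tm.registered,
        "geometry": tm.geometry.to_dict(),
    }
    if tm.subject_id is not None:
        sidecar["subject_id"] = tm.subject_id
    if tm.eye is not None:
        sidecar["eye"] = tm.eye
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_thickness_map(path, fmt: Optional[str] = None) -> ThicknessMap:
    """Read a thickness map in grid-tsv / float-tiff / nifti format.

    The JSON sidecar (layer, laterality, geometry) is mandatory; NaN and
    negative cells come back flagged invalid.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise MetadataError(f"missing sidecar {sc_path.name} for {path.name}")
    sidecar = json.loads(sc_path.read_text())
    for key in ("layer", "laterality", "geometry"):
        if key not in sidecar:
            raise MetadataError(f"sidecar {sc_path.name} lacks {key!r}")

    if fmt == "grid-tsv":
        values = np.loadtxt(path, delimiter="\t", ndmin=2)
    elif fmt == "float-tiff":
        import tifffile

        values = np.asarray(tifffile.imread(path), dtype=float)
    elif fmt == "nifti":
        import nibabel as nib

        values = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
        values = values.reshape(values.shape[0], values.shape[1])
    else:
        raise MetadataError(f"unsupported map format {fmt!r}")

    geometry = ScanGeometry.from_dict(sidecar["geometry"])
    if values.shape != geometry.shape:
        raise GeometryError(
            f"{path.name}: data shape {values.shape} does not match sidecar "
            f"geometry {geometry.shape}"
        )
    return ThicknessMap(
        values=values,
        layer=sidecar["layer"],
        laterality=sidecar["laterality"],
        geometry=geometry,
        registered=bool(sidecar.get("registered", False)),
        subject_id=sidecar.get("subject_id"),
        eye=sidecar.get("eye"),
    )


# ---------------------------------------------------------------------------
# volume file I/O (raw-bin + json)
# ---------------------------------------------------------------------------

def write_volume(v: OCTVolume, path) -> Path:
    """Write a volume as float32 C-order binary plus JSON header."""
    path = Path(path)
    v.intensity.astype(np.float32).tofile(path)
    header = {
        "dialect": "raw-bin+json",
        "dtype": "float32",
        "order": "C",
        "shape": list(v.intensity.shape),
        "axes": ["bscan", "depth", "ascan"],
        "laterality": v.laterality,
        "subject_id": v.subject_id,
        "session_id": v.session_id,
        "geometry": v.geometry.to_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(header, indent=1))
    return path


def read_volume(path, dialect: str = "raw-bin+json") -> OCTVolume:
    """Read an intensity volume.

    Only the portable raw-bin+json dialect is implemented; vendor export
    dialects are out of scope for this build.
    """
    if dialect != "raw-bin+json":
        raise NotImplementedError(
            f"volume dialect {dialect!r} is not available; use raw-bin+json"
        )
    path = Path(path)
    hdr_path = _sidecar_path(path)
    if not hdr_path.exists():
        raise MetadataError(f"missing header {hdr_path.name} for {path.name}")
    hdr = json.loads(hdr_path.read_text())
    shape = tuple(int(s) for s in hdr["shape"])
    expected = int(np.prod(shape)) * 4
    raw = np.fromfile(path, dtype=np.float32)
    if raw.size * 4 != expected:
        raise IOError(
            f"{path.name}: expected {expected} bytes "
            f"({shape} float32), found {raw.size * 4}"
        )
    return OCTVolume(
        intensity=raw.reshape(shape).astype(float),
        geometry=ScanGeometry.from_dict(hdr["geometry"]),
        laterality=hdr["laterality"],
        subject_id=hdr.get("subject_id"),
        session_id=hdr.get("session_id"),
    )


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a covariate table.

    Requires ``subject_id`` and ``group``; ``eye`` defaults to "OU".
    Missing values stay as NaN (explicit marker), never silently filled.
    Subject ids must be unique per eye.
    """
    df = df.copy()
    if "subject_id" not in df.columns:
        raise MetadataError("covariate table needs a subject_id column")
    if "group" not in df.columns:
        raise MetadataError("covariate table needs a group column")
    if "eye" not in df.columns:
        df["eye"] = "OU"
    dup = df.duplicated(subset=["subject_id", "eye"])
    if dup.any():
        raise MetadataError(
            f"duplicate subject/eye rows: "
            f"{df.loc[dup, ['subject_id', 'eye']].values.tolist()}"
        )
    for col in ("age", "edss", "disease_duration"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "sex" in df.columns:
        bad = ~df["sex"].isin(["M", "F"]) & df["sex"].notna()
        if bad.any():
            raise MetadataError(
                f"sex must be M/F, got {df.loc[bad, 'sex'].unique().tolist()}"
            )
    return df


def read_covariates(path) -> pd.DataFrame:
    return validate_covariates(pd.read_csv(path))


def write_covariates(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    validate_covariates(df).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def flip_to_left(obj):
    """Mirror a right-eye (OD) object into left-eye orientation.

    OD inputs are mirrored along the A-scan (column) axis so that the
    optic nerve head ends up on the low-column side, and relabelled
    ``left-normalized``.  OS and already-normalized inputs keep their
    values and are only relabelled.  Idempotent.
    """
    if isinstance(obj, ThicknessMap):
        if obj.laterality == "OD":
            return obj.copy_with(values=obj.values[:, ::-1].copy(),
                                 laterality="left-normalized")
        return obj.copy_with(laterality="left-normalized")
    if isinstance(obj, BoundarySet):
        if obj.laterality == "OD":
            surfaces = {k: v[:, ::-1].copy() for k, v in obj.surfaces.items()}
        else:
            surfaces = {k: v.copy() for k, v in obj.surfaces.items()}
        return BoundarySet(surfaces=surfaces, geometry=obj.geometry,
                           laterality="left-normalized")
    if isinstance(obj, OCTVolume):
        if obj.laterality == "OD":
            intensity = obj.intensity[:, :, ::-1].copy()
        else:
            intensity = obj.intensity.copy()
        return OCTVolume(intensity=intensity, geometry=obj.geometry,
                         laterality="left-normalized",
                         subject_id=obj.subject_id, session_id=obj.session_id)
    raise LateralityError(f"cannot flip object of type {type(obj).__name__}")


def thickness_from_boundaries(b: BoundarySet) -> Dict[str, ThicknessMap]:
    """Layer thickness maps from the five boundary surfaces.

    RNFL = RNFL/GCL - ILM; GCIPL = IPL/INL - RNFL/GCL;
    INL = INL/OPL - IPL/INL; Retina = BM - ILM.  Invalid A-lines
    propagate as NaN into every map.
    """
    b.validate_order()
    invalid = ~b.validity_mask
    pairs = {
        "RNFL": ("RNFL/GCL", "ILM"),
        "GCIPL": ("IPL/INL", "RNFL/GCL"),
        "INL": ("INL/OPL", "IPL/INL"),
        "Retina": ("BM", "ILM"),
    }
    out: Dict[str, ThicknessMap] = {}
    for layer, (lower, upper) in pairs.items():
        values = b.surfaces[lower] - b.surfaces[upper]
        values = np.where(invalid, np.nan, values)
        # clamp tiny negative round-off from the order tolerance
        values = np.where(np.isfinite(values) & (values < 0), 0.0, values)
        out[layer] = ThicknessMap(values=values, layer=layer,
                                  laterality=b.laterality,
                                  geometry=b.geometry)
    return out
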