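"""Volume and annotation I/O with faithful geometry metadata.

Volumes are carried as a 4D ``(x, y, z, phase)`` intensity grid plus
axis-aligned world geometry (isotropic or anisotropic voxel spacing in mm
and a world origin). World position of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing``; oblique affines are rejected rather than
silently mishandled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from fwhmvasc._errors import FormatError, ValidationError

__all__ = [
    "VolumeSeries",
    "AnnotationSet",
    "read_series",
    "write_series",
    "read_annotations",
    "write_annotations",
    "write_measurements",
    "read_measurements",
    "MEASUREMENT_COLUMNS",
]


@dataclass(frozen=True)
class VolumeSeries:
    """A time-resolved angiographic acquisition.

    Parameters
    ----------
    intensities
        4D array indexed ``(x, y, z, phase)``; finite and non-negative.
    spacing_mm
        Voxel edge lengths along x, y, z, strictly positive.
    origin_mm
        World coordinates of the centre of voxel ``(0, 0, 0)``.
    phase_interval_s
        Time between consecutive dynamic phases (temporal resolution).
    """

    intensities: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    phase_interval_s: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 4:
            raise FormatError(
                f"expected a 4D (x, y, z, phase) array, got {arr.ndim} dimensions"
                + ("; the phase axis is missing" if arr.ndim == 3 else "")
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("intensities must be finite")
        if np.any(arr < 0):
            raise ValidationError("intensities must be non-negative")
        spacing = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        if np.any(spacing <= 0):
            raise ValidationError("voxel spacing must be strictly positive")
        origin = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)
        if self.phase_interval_s <= 0:
            raise ValidationError("phase_interval_s must be strictly positive")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def n_phases(self) -> int:
        return self.intensities.shape[3]

    @property
    def phase_times_s(self) -> np.ndarray:
        """Acquisition times ``k * phase_interval_s`` of each phase."""
        return np.arange(self.n_phases) * self.phase_interval_s

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]

    def phase(self, index: int) -> np.ndarray:
        """One 3D phase volume."""
        return self.intensities[..., index]

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Inclusive world-space bounding box spanned by voxel centres."""
        lo = self.origin_mm
        hi = self.origin_mm + (np.array(self.shape) - 1) * self.spacing_mm
        return lo, hi

    def world_to_voxel(self, point_mm: Sequence[float]) -> np.ndarray:
        """Continuous voxel index of a world-space point."""
        p = np.asarray(point_mm, dtype=np.float64).reshape(3)
        return (p - self.origin_mm) / self.spacing_mm

    def contains(self, point_mm: Sequence[float]) -> bool:
        lo, hi = self.world_bounds()
        p = np.asarray(point_mm, dtype=np.float64).reshape(3)
        return bool(np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9))


@dataclass(frozen=True)
class AnnotationSet:
    """Operator inputs for one case.

    ``profile_line`` is the pair of world-space endpoints of the
    signal-intensity profile crossing the residual aneurysm;
    ``neck_points`` are the most proximal and most distal points of the
    aneurysm neck; ``seed_point`` lies inside the target lumen;
    ``projection_normal`` defines the 2D measurement projection plane.
    """

    profile_line: tuple[np.ndarray, np.ndarray]
    neck_points: tuple[np.ndarray, np.ndarray] | None = None
    seed_point: np.ndarray | None = None
    projection_normal: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.profile_line[0], dtype=np.float64).reshape(3)
        b = np.asarray(self.profile_line[1], dtype=np.float64).reshape(3)
        if np.allclose(a, b):
            raise ValidationError("profile_line endpoints must be distinct")
        object.__setattr__(self, "profile_line", (a, b))
        if self.neck_points is not None:
            p = np.asarray(self.neck_points[0], dtype=np.float64).reshape(3)
            d = np.asarray(self.neck_points[1], dtype=np.float64).reshape(3)
            if np.allclose(p, d):
                raise ValidationError("neck points must be distinct")
            object.__setattr__(self, "neck_points", (p, d))
        if self.seed_point is not None:
            object.__setattr__(
                self,
                "seed_point",
                np.asarray(self.seed_point, dtype=np.float64).reshape(3),
            )
        if self.projection_normal is not None:
            n = np.asarray(self.projection_normal, dtype=np.float64).reshape(3)
            if abs(np.linalg.norm(n) - 1.0) > 1e-9:
                raise ValidationError("projection_normal must have unit norm")
            object.__setattr__(self, "projection_normal", n)

    def validate_inside(self, series: VolumeSeries) -> None:
        """Check that every annotated point lies inside the volume."""
        points = list(self.profile_line)
        if self.neck_points is not None:
            points += list(self.neck_points)
        if self.seed_point is not None:
            points.append(self.seed_point)
        for p in points:
            if not series.contains(p):
                raise ValidationError(
                    f"annotated point {p.tolist()} lies outside the volume bounding box"
                )


def _axis_aligned_geometry(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract (spacing, origin) from an affine, rejecting oblique ones."""
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(rot))):
        raise FormatError(
            "oblique affine: only axis-aligned volumes are supported; "
            "resample to an axis-aligned grid first"
        )
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        raise FormatError("affine has a zero diagonal scale")
    return spacing, affine[:3, 3].copy()


def read_series(path: str | Path, phase_interval_s: float | None = None) -> VolumeSeries:
    """Read a 4D NIfTI file or a DICOM series directory.

    For NIfTI the phase interval comes from the header's time step unless
    overridden; for DICOM it is inferred from acquisition times. A 3D
    input without a phase axis is a format error.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path, phase_interval_s)
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        raise FormatError(
            f"{path.name} is a 3D volume: the phase axis (4th dimension) is missing"
        )
    if data.ndim != 4:
        raise FormatError(f"{path.name}: expected 4D data, got {data.ndim}D")
    spacing, origin = _axis_aligned_geometry(img.affine)
    if phase_interval_s is None:
        zooms = img.header.get_zooms()
        phase_interval_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return VolumeSeries(data, spacing, origin, phase_interval_s)


def write_series(series: VolumeSeries, path: str | Path) -> None:
    """Write a :class:`VolumeSeries` as 4D NIfTI with geometry in the header."""
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(series.spacing_mm)
    affine[:3, 3] = series.origin_mm
    img = nib.Nifti1Image(series.intensities.astype(np.float64), affine)
    img.header.set_zooms(tuple(series.spacing_mm) + (series.phase_interval_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def _read_dicom_dir(path: Path, phase_interval_s: float | None) -> VolumeSeries:
    """Assemble one dynamic series from a directory of single-frame DICOMs.

    Slices are grouped into phases by acquisition time and ordered along
    the slice normal; inconsistent slice spacing is a format error.
    """
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".json")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise FormatError(f"no readable DICOM files in {path}")

    def acq_time(ds) -> str:
        return str(getattr(ds, "AcquisitionTime", getattr(ds, "AcquisitionNumber", "0")))

    phases: dict[str, list] = {}
    for ds in datasets:
        phases.setdefault(acq_time(ds), []).append(ds)
    phase_keys = sorted(phases)
    if len(phase_keys) < 2:
        raise FormatError("DICOM directory holds a single phase: phase axis missing")

    volumes = []
    spacing = origin = None
    for key in phase_keys:
        slices = phases[key]
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
        dz = np.diff(zpos)
        if len(dz) and (np.max(dz) - np.min(dz)) > 1e-3:
            raise FormatError("inconsistent slice spacing within a DICOM phase")
        px = [float(v) for v in slices[0].PixelSpacing]
        this_spacing = np.array([px[1], px[0], dz[0] if len(dz) else 1.0])
        this_origin = np.array([float(v) for v in slices[0].ImagePositionPatient])
        if spacing is None:
            spacing, origin = this_spacing, this_origin
        elif not np.allclose(spacing, this_spacing):
            raise FormatError("inconsistent voxel spacing across DICOM phases")
        # pixel_array is (row, col) = (y, x); transpose to (x, y) then stack z
        vol = np.stack([ds.pixel_array.T.astype(np.float64) for ds in slices], axis=2)
        volumes.append(vol)
    data = np.stack(volumes, axis=3)

    if phase_interval_s is None:
        try:
            times = np.array([float(k) for k in phase_keys])
            dt = np.diff(times)
            phase_interval_s = float(np.mean(dt)) if len(dt) and np.all(dt > 0) else 1.0
        except ValueError:
            phase_interval_s = 1.0
    return VolumeSeries(data, spacing, origin, phase_interval_s)


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    """Serialize an :class:`AnnotationSet` to a JSON file (one per case)."""
    payload: dict = {
        "profile_line": [ann.profile_line[0].tolist(), ann.profile_line[1].tolist()]
    }
    if ann.neck_points is not None:
        payload["neck_points"] = [ann.neck_points[0].tolist(), ann.neck_points[1].tolist()]
    if ann.seed_point is not None:
        payload["seed_point"] = ann.seed_point.tolist()
    if ann.projection_normal is not None:
        payload["projection_normal"] = ann.projection_normal.tolist()
    Path(path).write_text(json.dumps(payload, indent=2))


def read_annotations(path: str | Path) -> AnnotationSet:
    payload = json.loads(Path(path).read_text())
    if "profile_line" not in payload:
        raise FormatError(f"{path}: annotation file lacks 'profile_line'")
    return AnnotationSet(
        profile_line=tuple(payload["profile_line"]),
        neck_points=tuple(payload["neck_points"]) if "neck_points" in payload else None,
        seed_point=payload.get("seed_point"),
        projection_normal=payload.get("projection_normal"),
    )


#: Fixed column order of the measurement CSV.
MEASUREMENT_COLUMNS = [
    "case_id",
    "neck_length_mm",
    "largest_diameter_mm",
    "smallest_diameter_mm",
    "parent_artery_diameter_mm",
    "residual_volume_mm3",
]


def write_measurements(records: Sequence[dict], path: str | Path) -> None:
    """Write measurement records as CSV in the fixed documented column order.

    Each record carries a ``case_id`` plus the :class:`ResidualMeasurement`
    fields; floats are written at full precision and row order follows the
    input order. An empty record list yields a header-only CSV.
    """
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            rec = dataclasses.asdict(rec)
        rows.append({col: rec.get(col) for col in MEASUREMENT_COLUMNS})
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"measurement CSV lacks columns: {missing}")
    return df[MEASUREMENT_COLUMNS]
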