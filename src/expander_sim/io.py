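"""Volume I/O: the internal volumetric format and a DICOM CT import adapter.

Internal format: one compressed ``.npz`` per volume (array under ``values``,
or one boolean array per structure) plus a JSON sidecar carrying spacing,
origin, axis names and kind. Round-trip stable and dependency-light; DICOM
is an optional import path (CT series -> density grid through the HU
calibration).
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path

import numpy as np

from .errors import FormatError
from .grids import AXES, DensityGrid, DoseGrid, Grid3D, StructureSet
from .synthphantom import HUCalibration, hu_to_density

_KINDS = {"density": DensityGrid, "dose": DoseGrid}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_volume(path, grid: Grid3D, kind: str | None = None) -> Path:
    """Write a grid as ``<path>.npz`` + ``<path>.json``; returns the npz path."""
    path = Path(path).with_suffix(".npz")
    if kind is None:
        kind = "dose" if isinstance(grid, DoseGrid) else "density"
    if kind not in _KINDS:
        raise FormatError(f"unknown volume kind {kind!r}")
    np.savez_compressed(path, values=grid.values)
    meta = {
        "kind": kind,
        "spacing_mm": [float(s) for s in grid.spacing],
        "origin_mm": [float(o) for o in grid.origin],
        "axes": list(AXES),
        "shape": list(grid.shape),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_volume(path) -> tuple[Grid3D, dict]:
    """Load an internal-format volume; raises :class:`FormatError` on damage."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"malformed sidecar {sidecar}: {e}") from e
    for key in ("kind", "spacing_mm", "origin_mm", "shape"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing field {key!r}")
    if meta["kind"] not in _KINDS:
        raise FormatError(f"unknown volume kind {meta['kind']!r}")
    try:
        with np.load(path) as npz:
            values = npz["values"]
    except (zipfile.BadZipFile, OSError, KeyError, ValueError) as e:
        raise FormatError(f"malformed volume file {path}: {e}") from e
    if list(values.shape) != list(meta["shape"]):
        raise FormatError(f"array shape {values.shape} does not match sidecar "
                          f"shape {meta['shape']}")
    cls = _KINDS[meta["kind"]]
    return cls(values, meta["spacing_mm"], meta["origin_mm"]), meta


def save_structures(path, structures: StructureSet) -> Path:
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, **{k: v for k, v in structures.masks.items()})
    meta = {
        "kind": "structures",
        "spacing_mm": [float(s) for s in structures.spacing],
        "origin_mm": [float(o) for o in structures.origin],
        "axes": list(AXES),
        "structures": structures.names,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_structures(path) -> StructureSet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = _sidecar_path(path)
    if not path.exists() or not sidecar.exists():
        raise FormatError(f"structure set files missing at {path}")
    try:
        meta = json.loads(sidecar.read_text())
        with np.load(path) as npz:
            masks = {k: npz[k] for k in meta["structures"]}
    except (zipfile.BadZipFile, OSError, KeyError, ValueError,
            json.JSONDecodeError) as e:
        raise FormatError(f"malformed structure set {path}: {e}") from e
    return StructureSet(masks, meta["spacing_mm"], meta["origin_mm"])


def load_dicom_series(directory, calibration: HUCalibration | None = None
                      ) -> tuple[DensityGrid, dict]:
    """Import a DICOM CT series as a density grid.

    Slices are sorted by their z position; stored values are rescaled to HU
    (slope/intercept) and converted to physical density through the
    configured piecewise-linear calibration. Pixel rows map to the vertical
    axis and columns to the lateral axis of the package convention.
    """
    try:
        import pydicom
    except ImportError as e:  # pragma: no cover
        raise FormatError("DICOM support requires pydicom") from e
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise FormatError(f"no DICOM files in {directory}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
            z = float(ds.ImagePositionPatient[2])
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            hu = ds.pixel_array.astype(float) * slope + intercept
            slices.append((z, hu, ds))
        except Exception as e:
            raise FormatError(f"malformed DICOM file {f}: {e}") from e
    slices.sort(key=lambda t: t[0])
    first = slices[0][2]
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1:
        dz = slices[1][0] - slices[0][0]
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    # DICOM pixel_array is (row, col); package order is (lateral, vertical, z)
    hu_vol = np.stack([np.transpose(hu) for _, hu, _ in slices], axis=-1)
    rho = hu_to_density(hu_vol, calibration)
    rho = np.clip(rho, a_min=0.0, a_max=None)
    x0, y0, _ = (float(v) for v in first.ImagePositionPatient)
    origin = (x0, y0, slices[0][0])
    grid = DensityGrid(rho, (col_mm, row_mm, dz), origin)
    meta = {"n_slices": len(slices), "source": str(directory)}
    return grid, meta
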