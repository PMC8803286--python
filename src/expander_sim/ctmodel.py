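"""Density-grid editing: artefact correction, port overrides, port shifting.

These are the CT manipulations that turn a raw phantom (or patient CT) into
the per-fraction computational patients of the robustness study:

* streak-artefact correction — breast voxels on artefacted slices replaced
  with the mean breast density of artefact-free slices;
* metal override — nominal densities (titanium 4.0, magnet 8.0 g/cm^3)
  assigned inside the contoured port;
* internal port error (IPE) — rigid translation of the port masks and their
  densities, with vacated voxels backfilled from the local background;
* tissue-equivalent override — the "ignore the port" planning scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CorrectionError, DisplacementError, StructureError
from .grids import AXES, DensityGrid, StructureSet
from .synthphantom import TissueModel


@dataclass(frozen=True)
class Shift:
    """A rigid translation in mm along (lateral, vertical, longitudinal)."""

    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite([self.dx, self.dy, self.dz])):
            raise ValueError("shift components must be finite")

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm([self.dx, self.dy, self.dz]))

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)

    def __add__(self, other: "Shift") -> "Shift":
        return Shift(self.dx + other.dx, self.dy + other.dy, self.dz + other.dz)

    def __neg__(self) -> "Shift":
        return Shift(-self.dx, -self.dy, -self.dz)

    def voxels(self, spacing) -> tuple[int, int, int]:
        """Nearest-voxel rounding of the shift on a given lattice."""
        return tuple(int(v) for v in np.rint(self.as_array() / np.asarray(spacing)))


ZERO_SHIFT = Shift(0.0, 0.0, 0.0)


def _breast_mask(structures: StructureSet) -> np.ndarray:
    body = structures["body"]
    other = np.zeros_like(body)
    for name in ("implant", "lung", "heart", "port_core", "port_shell"):
        if name in structures:
            other |= structures[name]
    return body & ~other


def _port_mask(structures: StructureSet) -> np.ndarray:
    if "port_core" not in structures or "port_shell" not in structures:
        raise StructureError("port_core and port_shell masks are required")
    return structures["port_core"] | structures["port_shell"]


def mean_breast_density(grid: DensityGrid, structures: StructureSet,
                        exclude_slices=()) -> float:
    """Mean density over breast-tissue voxels, optionally skipping z-slices."""
    breast = _breast_mask(structures).copy()
    for k in exclude_slices:
        breast[:, :, k] = False
    if not breast.any():
        raise CorrectionError("no artefact-free slice containing breast tissue")
    return float(grid.values[breast].mean())


def correct_artefacts(grid: DensityGrid, structures: StructureSet,
                      artefact_slices) -> DensityGrid:
    """Replace breast-tissue densities on artefacted z-slices.

    Breast voxels (body excluding implant, port, lung, heart) on the listed
    slices are set to the mean breast density computed over the remaining
    slices. All other voxels are untouched; an empty slice list is a no-op.
    """
    grid.require_same_geometry(structures, "grid and structures")
    out = grid.copy()
    artefact_slices = sorted(set(int(k) for k in artefact_slices or ()))
    if not artefact_slices:
        return out
    fill = mean_breast_density(grid, structures, exclude_slices=artefact_slices)
    breast = _breast_mask(structures)
    for k in artefact_slices:
        sl = breast[:, :, k]
        vals = out.values[:, :, k]
        vals[sl] = fill
        out.values[:, :, k] = vals
    return out


def override_port_densities(grid: DensityGrid, structures: StructureSet,
                            tissues: TissueModel | None = None) -> DensityGrid:
    """Assign nominal metal densities inside the port (shell 4.0, core 8.0).

    Idempotent; voxels outside the port masks are unchanged.
    """
    tissues = tissues or TissueModel()
    _port_mask(structures)  # raises if masks missing
    out = grid.copy()
    out.values[structures["port_shell"]] = tissues.titanium
    out.values[structures["port_core"]] = tissues.magnet
    return out


def override_port_as_tissue(grid: DensityGrid, structures: StructureSet,
                            tissues: TissueModel | None = None) -> DensityGrid:
    """Override the whole port with breast-equivalent density (ignore-the-port)."""
    tissues = tissues or TissueModel()
    port = _port_mask(structures)
    out = grid.copy()
    out.values[port] = tissues.breast
    return out


def _translate_mask(mask: np.ndarray, iv: tuple[int, int, int]) -> np.ndarray:
    """Integer-voxel translation with zero fill (no wrap-around)."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(iv):
        n = mask.shape[ax]
        if abs(d) >= n:
            return out
        if d >= 0:
            src[ax] = slice(0, n - d)
            dst[ax] = slice(d, n)
        else:
            src[ax] = slice(-d, n)
            dst[ax] = slice(0, n + d)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def shift_port(grid: DensityGrid, structures: StructureSet, shift: Shift
               ) -> tuple[DensityGrid, StructureSet]:
    """Translate the port (masks and densities) by a measured displacement.

    The shift is rounded to the nearest voxel. Vacated voxels are backfilled
    with the local background (implant density inside the implant, mean breast
    density elsewhere); destination voxels are overwritten with the port
    densities. Port voxel counts are conserved. Raises
    :class:`DisplacementError` if the shifted port would leave the body.
    """
    grid.require_same_geometry(structures, "grid and structures")
    core = structures["port_core"] if "port_core" in structures else None
    port = _port_mask(structures)
    shell = structures["port_shell"]
    iv = shift.voxels(grid.spacing)
    if iv == (0, 0, 0):
        return grid.copy(), structures.copy()

    # out-of-grid check per axis, naming the offending direction
    idx = np.argwhere(port)
    for ax, d in enumerate(iv):
        lo, hi = idx[:, ax].min() + d, idx[:, ax].max() + d
        if lo < 0 or hi >= grid.shape[ax]:
            raise DisplacementError(
                f"port shifted outside the grid along the {AXES[ax]} axis",
                axis=AXES[ax])

    new_core = _translate_mask(core, iv)
    new_shell = _translate_mask(shell, iv)
    new_port = new_core | new_shell
    body = structures["body"]
    if not np.all(body[new_port]):
        ax = int(np.argmax(np.abs(iv)))
        raise DisplacementError(
            f"port shifted outside the body (dominant shift axis: {AXES[ax]})",
            axis=AXES[ax])

    rho_core = float(grid.values[core].mean())
    rho_shell = float(grid.values[shell].mean())
    implant = structures["implant"] if "implant" in structures else np.zeros_like(port)
    rho_implant = (float(grid.values[implant & ~port].mean())
                   if (implant & ~port).any() else mean_breast_density(grid, structures))
    rho_breast = mean_breast_density(grid, structures)

    out = grid.copy()
    vacated = port & ~new_port
    out.values[vacated & implant] = rho_implant
    out.values[vacated & ~implant] = rho_breast
    out.values[new_shell] = rho_shell
    out.values[new_core] = rho_core

    new_structures = structures.copy()
    new_structures.masks["port_core"] = new_core
    new_structures.masks["port_shell"] = new_shell
    return out, new_structures
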