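"""Voxel containers: density grids, dose grids, and structure sets.

Axis convention (fixed throughout the package):

* axis 0 — **lateral** (x): patient left is +x.
* axis 1 — **vertical** (y): anterior is +y.
* axis 2 — **longitudinal** (z): superior is +z.

All world coordinates are millimetres at voxel centres; ``origin`` is the
world position of voxel ``(0, 0, 0)``. Densities are g/cm^3, doses Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, StructureError

AXES = ("lateral", "vertical", "longitudinal")


def _as_triplet(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(3)
    return a


@dataclass
class Grid3D:
    """A scalar field on a regular 3-D voxel lattice."""

    values: np.ndarray
    spacing: np.ndarray  # mm per axis
    origin: np.ndarray   # mm, world position of voxel (0, 0, 0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = _as_triplet(self.spacing)
        self.origin = _as_triplet(self.origin)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("grid values must be finite")
        if np.any(self.values < 0):
            raise GeometryError("grid values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of world coordinates of all voxel centres."""
        xs, ys, zs = (self.axis_coords(i) for i in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (…, 3) to continuous voxel-index coordinates."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def same_geometry(self, other: "Grid3D | StructureSet", atol: float = 1e-6) -> bool:
        return (
            self.shape == tuple(other.shape)
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_geometry(self, other, what: str = "grids") -> None:
        if not self.same_geometry(other):
            raise GeometryError(f"{what} are not co-registered "
                                f"(shape/spacing/origin mismatch)")

    def copy(self):
        return type(self)(self.values.copy(), self.spacing.copy(), self.origin.copy())


class DensityGrid(Grid3D):
    """Physical density (g/cm^3) on a voxel lattice — the computational patient."""


class DoseGrid(Grid3D):
    """Absorbed dose (Gy) co-registered with a :class:`DensityGrid`."""


@dataclass
class StructureSet:
    """Named boolean masks sharing one grid geometry.

    Masks are stored as full geometric regions and may overlap (the port sits
    inside the implant, the implant inside the body); tissue assignment
    resolves overlaps by priority at phantom-generation time.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    spacing: np.ndarray = None
    origin: np.ndarray = None

    def __post_init__(self):
        self.spacing = _as_triplet(self.spacing)
        self.origin = _as_triplet(self.origin)
        for name, m in self.masks.items():
            self.masks[name] = np.asarray(m, dtype=bool)
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise GeometryError(f"structure masks have inconsistent shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        if not self.masks:
            raise StructureError("empty structure set has no shape")
        return next(iter(self.masks.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise StructureError(f"structure {name!r} not in set "
                                 f"(have {sorted(self.masks)})") from None

    def add(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        if self.masks and mask.shape != self.shape:
            raise GeometryError(f"mask {name!r} shape {mask.shape} != {self.shape}")
        self.masks[name] = mask

    def copy(self) -> "StructureSet":
        return StructureSet({k: v.copy() for k, v in self.masks.items()},
                            self.spacing.copy(), self.origin.copy())
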