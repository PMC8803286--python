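"""Synthetic thorax/expander phantoms and HU-density conversion.

The phantom stands in for a planning CT of a post-mastectomy patient with a
saline tissue expander: an ellipsoidal body, ipsilateral lung and heart
ellipsoids, a spherical saline implant on the anterior chest, and a metal
injection port (a magnet core inside a titanium shell, modelled as coaxial
cylinders with their axis anterior-posterior) at the implant centre. The PTV
is the clinical-margin expansion around the implant-bearing chest wall,
truncated inside the skin.

Geometry parameters are given for a **left**-sided case; a right-sided
configuration mirrors every structure across the midsagittal plane (the
phantom is schematic, not anatomical). All lengths in mm, densities g/cm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, ConfigurationError
from .grids import DensityGrid, StructureSet


@dataclass(frozen=True)
class TissueModel:
    """Physical densities (g/cm^3) of the phantom's materials.

    The metal port densities default to the nominal override values used for
    planning: 4.0 for the titanium shell and 8.0 for the magnet core.
    """

    air: float = 0.001
    lung: float = 0.26
    breast: float = 0.95
    saline: float = 1.00
    rib: float = 1.40
    titanium: float = 4.0
    magnet: float = 8.0

    def __post_init__(self):
        order = [self.air, self.lung, self.breast]
        if not (self.air < self.lung < self.breast <= self.saline
                < self.rib < self.titanium < self.magnet):
            raise ConfigurationError(
                "tissue densities must satisfy "
                "air < lung < breast <= saline < rib < titanium < magnet; "
                f"got {self}")
        del order


@dataclass(frozen=True)
class HUCalibration:
    """Piecewise-linear HU → physical-density table.

    Default anchors: air (−1000, 0.001), water (0, 1.0), and the two metal
    override points (3926, 4.0) and (10248, 8.0). The two metal anchors are
    not collinear with the water point, so a table (not a single slope) is
    required.
    """

    anchors: tuple[tuple[float, float], ...] = (
        (-1000.0, 0.001),
        (0.0, 1.0),
        (3926.0, 4.0),
        (10248.0, 8.0),
    )

    def __post_init__(self):
        if len(self.anchors) < 2:
            raise CalibrationError("calibration needs at least 2 (HU, density) anchors")
        hu = np.array([a[0] for a in self.anchors], dtype=float)
        rho = np.array([a[1] for a in self.anchors], dtype=float)
        if np.any(np.diff(hu) <= 0):
            raise CalibrationError("HU anchor values must be strictly increasing")
        if np.any(np.diff(rho) < 0):
            raise CalibrationError("anchor densities must be non-decreasing")


def hu_to_density(hu, cal: HUCalibration | None = None):
    """Convert HU to physical density (g/cm^3) by piecewise-linear interpolation.

    Values outside the anchor range are clamped to the end anchors. Accepts
    scalars or arrays.
    """
    cal = cal or HUCalibration()
    xs = np.array([a[0] for a in cal.anchors], dtype=float)
    ys = np.array([a[1] for a in cal.anchors], dtype=float)
    out = np.interp(np.asarray(hu, dtype=float), xs, ys)
    return float(out) if np.isscalar(hu) else out


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of the synthetic phantom (left-sided convention; mm)."""

    grid_shape: tuple[int, int, int] = (128, 128, 64)
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5)
    laterality: str = "left"

    # ellipsoids: (center, semi-axes), world mm; x>0 is the ipsilateral side
    body_center: tuple[float, float, float] = (0.0, -20.0, 0.0)
    body_semiaxes: tuple[float, float, float] = (145.0, 90.0, 76.0)
    lung_center: tuple[float, float, float] = (60.0, -40.0, 0.0)
    lung_semiaxes: tuple[float, float, float] = (45.0, 50.0, 58.0)
    heart_center: tuple[float, float, float] = (15.0, -35.0, -10.0)
    heart_semiaxes: tuple[float, float, float] = (35.0, 32.0, 38.0)

    implant_center: tuple[float, float, float] = (55.0, 25.0, 0.0)
    implant_radius: float = 35.0
    port_core_radius: float = 6.0
    port_core_length: float = 10.0
    port_shell_thickness: float = 2.0
    skin_thickness: float = 5.0
    ptv_margin: float = 5.0

    artefact_slices: tuple[int, ...] | None = None
    artefact_amplitude: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.laterality not in ("left", "right"):
            raise ConfigurationError(f"laterality must be left|right, got {self.laterality!r}")
        for name in ("implant_radius", "port_core_radius", "port_core_length",
                     "port_shell_thickness", "skin_thickness"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.ptv_margin < 0:
            raise ConfigurationError("ptv_margin must be >= 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel_size must be positive")
        # port (core + shell) fully inside the implant sphere: the farthest
        # corner of the shell cylinder must lie inside implant_radius
        r_out = self.port_core_radius + self.port_shell_thickness
        h_out = self.port_core_length / 2 + self.port_shell_thickness
        if math.hypot(r_out, h_out) >= self.implant_radius:
            raise ConfigurationError(
                "containment violated: port (core+shell) does not fit inside implant "
                f"(shell corner radius {math.hypot(r_out, h_out):.1f} mm >= "
                f"implant radius {self.implant_radius} mm)")

    def mirrored(self) -> "PhantomConfig":
        """The same phantom on the opposite laterality (x-coordinates negated)."""
        flip = lambda c: (-c[0], c[1], c[2])
        return replace(
            self,
            laterality="right" if self.laterality == "left" else "left",
            body_center=flip(self.body_center),
            lung_center=flip(self.lung_center),
            heart_center=flip(self.heart_center),
            implant_center=flip(self.implant_center),
        )


def _grid_origin(config: PhantomConfig) -> np.ndarray:
    """Origin that centres the grid on world (0, 0, 0), symmetric in x."""
    shape = np.asarray(config.grid_shape, dtype=float)
    h = np.asarray(config.voxel_size, dtype=float)
    return -(shape - 1) / 2 * h


def _ellipsoid_mask(coords, center, semiaxes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
            + ((z - cz) / az) ** 2) <= 1.0


def generate_phantom(config: PhantomConfig | None = None,
                     tissues: TissueModel | None = None
                     ) -> tuple[DensityGrid, StructureSet]:
    """Rasterize the phantom: density grid plus structure masks.

    Masks are geometric regions and may nest (port ⊂ implant ⊂ body); the
    density assignment resolves overlap by priority
    (core > shell > implant > lung > heart > body) so that every voxel
    carries exactly one tissue density. Deterministic for a fixed config.
    """
    config = config or PhantomConfig()
    tissues = tissues or TissueModel()

    origin = _grid_origin(config)
    h = np.asarray(config.voxel_size, dtype=float)
    nx, ny, nz = config.grid_shape
    x = origin[0] + h[0] * np.arange(nx)
    y = origin[1] + h[1] * np.arange(ny)
    z = origin[2] + h[2] * np.arange(nz)
    gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")
    coords = (gx, gy, gz)

    # geometry fields are explicit world coordinates; `PhantomConfig.mirrored()`
    # is the supported way to obtain the opposite-laterality phantom
    c = config

    body = _ellipsoid_mask(coords, c.body_center, c.body_semiaxes)
    lung = _ellipsoid_mask(coords, c.lung_center, c.lung_semiaxes) & body
    heart = _ellipsoid_mask(coords, c.heart_center, c.heart_semiaxes) & body

    icx, icy, icz = c.implant_center
    r2 = (gx - icx) ** 2 + (gy - icy) ** 2 + (gz - icz) ** 2
    implant = r2 <= c.implant_radius ** 2

    # port: coaxial cylinders, axis along y (anterior-posterior)
    rad2 = (gx - icx) ** 2 + (gz - icz) ** 2
    half_core = c.port_core_length / 2
    r_core = c.port_core_radius
    r_out = r_core + c.port_shell_thickness
    half_out = half_core + c.port_shell_thickness
    core = (rad2 <= r_core ** 2) & (np.abs(gy - icy) <= half_core)
    shell = (rad2 <= r_out ** 2) & (np.abs(gy - icy) <= half_out) & ~core

    if not np.all(body[implant]):
        raise ConfigurationError("containment violated: implant is not fully "
                                 "inside body")
    if (core | shell).any() and not np.all(implant[core | shell]):
        raise ConfigurationError("containment violated: port is not fully "
                                 "inside implant")

    # PTV: margin expansion of the implant-bearing chest wall, kept inside the
    # skin (body eroded by skin_thickness)
    dist_out = ndimage.distance_transform_edt(~implant, sampling=h)
    expanded = dist_out <= c.ptv_margin
    dist_in = ndimage.distance_transform_edt(body, sampling=h)
    interior = dist_in > c.skin_thickness
    ptv = expanded & interior

    rho = np.full(config.grid_shape, tissues.air, dtype=float)
    rho[body] = tissues.breast
    rho[heart] = tissues.breast  # heart is soft tissue at this density tier
    rho[lung] = tissues.lung
    rho[implant] = tissues.saline
    rho[shell] = tissues.titanium
    rho[core] = tissues.magnet

    if config.artefact_slices:
        rng = np.random.default_rng(config.seed)
        breast_only = body & ~implant & ~lung & ~heart
        for k in config.artefact_slices:
            sl = breast_only[:, :, k]
            noise = 1.0 + config.artefact_amplitude * rng.standard_normal(sl.sum())
            vals = rho[:, :, k]
            vals[sl] = np.clip(vals[sl] * noise, tissues.air, tissues.rib)
            rho[:, :, k] = vals

    grid = DensityGrid(rho, h, origin)
    structures = StructureSet(
        {
            "body": body,
            "lung": lung,
            "heart": heart,
            "implant": implant,
            "port_core": core,
            "port_shell": shell,
            "ptv": ptv,
        },
        spacing=h,
        origin=origin,
    )
    return grid, structures
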