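"""Simplified divergent-beam photon dose engine and plan builders.

The engine is a deliberately transparent stand-in for a clinical dose
calculation: per beam, the pre-scatter dose at a voxel is

    dose(v) = weight * inside_aperture(v) * (SAD / r(v))^2
              * exp(-mu_w * d_rad(v))

where ``r(v)`` is the source-voxel distance, ``d_rad`` the radiological depth
(water-equivalent cm, i.e. the line integral of density from the source), and
``mu_w`` an effective 6 MV-like linear attenuation coefficient for water
(0.049 cm^-1 by default). Attenuation therefore scales with mass density
only — crude for high-Z metal, but it reproduces the inverse-square falloff,
depth attenuation and the dose shadow that a dense port casts, which is what
the robustness comparison needs. A single isotropic Gaussian blur (sigma 5 mm
default) stands in for scatter and electron transport; there is no buildup
region.

Radiological depth inside :func:`compute_beam_dose` is evaluated on a
beam-anchored fan lattice (cumulative sum along each fan ray) and
interpolated to the voxels; the exact voxel-traversal integral is available
separately as :func:`radiological_path` and serves as its oracle.

Three plan builders emulate the study's delivery techniques: half-blocked
parallel-opposed tangents with anterior flash, a 230-degree conformal arc,
and full-rotation conformal fan beams at successive couch positions
(helical-like). Arc/helical weights are uniform — no inverse optimization —
and plan quality is set afterwards by :func:`normalize_plan` (PTV D90% equal
to the prescription dose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import NormalizationError, PlanError
from .grids import DensityGrid, DoseGrid, StructureSet

MU_WATER_PER_CM = 0.049     # effective linear attenuation, 6 MV-like, water
SCATTER_SIGMA_MM = 5.0
DEFAULT_SAD_MM = 1000.0


# --------------------------------------------------------------------------
# beam geometry


@dataclass(frozen=True, eq=False)
class Aperture:
    """Beam's-eye-view opening at the isocenter plane (mm).

    Either a rectangle ``(u0, u1, v0, v1)`` or a boolean cell mask on a
    regular BEV lattice. ``u`` is the in-plane transverse BEV axis, ``v`` the
    longitudinal one.
    """

    rect: tuple[float, float, float, float] | None = None
    mask: np.ndarray | None = None
    mask_u0: float = 0.0
    mask_v0: float = 0.0
    mask_cell: float = 2.5

    def __post_init__(self):
        if (self.rect is None) == (self.mask is None):
            raise PlanError("aperture needs exactly one of rect or mask")
        if self.rect is not None:
            u0, u1, v0, v1 = self.rect
            if not (u1 > u0 and v1 > v0):
                raise PlanError(f"degenerate rectangular aperture {self.rect}")

    @property
    def is_empty(self) -> bool:
        if self.rect is not None:
            u0, u1, v0, v1 = self.rect
            return not (u1 > u0 and v1 > v0)
        return not self.mask.any()

    def contains(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if self.rect is not None:
            u0, u1, v0, v1 = self.rect
            return (u >= u0) & (u <= u1) & (v >= v0) & (v <= v1)
        iu = np.rint((u - self.mask_u0) / self.mask_cell).astype(int)
        iv = np.rint((v - self.mask_v0) / self.mask_cell).astype(int)
        nu, nv = self.mask.shape
        ok = (iu >= 0) & (iu < nu) & (iv >= 0) & (iv < nv)
        out = np.zeros(u.shape, dtype=bool)
        out[ok] = self.mask[iu[ok], iv[ok]]
        return out

    def v_extent(self) -> tuple[float, float]:
        if self.rect is not None:
            return self.rect[2], self.rect[3]
        rows = np.any(self.mask, axis=0)
        idx = np.flatnonzero(rows)
        return (self.mask_v0 + self.mask_cell * (idx[0] - 0.5),
                self.mask_v0 + self.mask_cell * (idx[-1] + 0.5))


@dataclass(frozen=True)
class Beam:
    """One divergent photon beam.

    Gantry 0 deg places the source anterior (+y); 90 deg at patient left
    (+x). The BEV basis is ``e_u = (cos g, -sin g, 0)``, ``e_v = z``; for
    opposed beams ``e_u`` flips sign, so the same physical half-plane has
    opposite u sign in the two views.
    """

    gantry_deg: float
    isocenter: tuple[float, float, float]
    aperture: Aperture
    weight: float = 1.0
    sad: float = DEFAULT_SAD_MM
    half_block_u: float | None = None  # recorded block edge (mm), u-coordinate

    def __post_init__(self):
        if self.sad <= 0:
            raise PlanError("SAD must be positive")
        if self.weight < 0:
            raise PlanError("beam weight must be >= 0")
        if self.weight > 0 and self.aperture.is_empty:
            raise PlanError("zero-size aperture with positive weight")

    @property
    def _angle_rad(self) -> float:
        return math.radians(self.gantry_deg)

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from source towards isocenter."""
        a = self._angle_rad
        return np.array([-math.sin(a), -math.cos(a), 0.0])

    @property
    def e_u(self) -> np.ndarray:
        a = self._angle_rad
        return np.array([math.cos(a), -math.sin(a), 0.0])

    @property
    def e_v(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    @property
    def source(self) -> np.ndarray:
        return np.asarray(self.isocenter, dtype=float) - self.sad * self.axis

    def bev_coords(self, points: np.ndarray):
        """Project world points into BEV: (u, v) at the isocenter plane,
        plus distance from the source and depth along the beam axis."""
        r = np.asarray(points, dtype=float) - self.source
        t_axis = r @ self.axis
        u = (r @ self.e_u) * self.sad / t_axis
        v = (r @ self.e_v) * self.sad / t_axis
        dist = np.linalg.norm(r, axis=-1)
        return u, v, dist, t_axis


@dataclass(frozen=True)
class Prescription:
    """50 Gy in 25 fractions with the study's plan objectives attached."""

    total_dose_gy: float = 50.0
    n_fractions: int = 25
    target_d90_gy: float = 50.0
    target_d2_gy: float = 55.0
    lung_constraints: tuple = (("Dmean", 16.0), ("V5Gy", 50.0),
                               ("V20Gy", 25.0), ("V40Gy", 10.0))
    heart_constraints: tuple = (("Dmean", 8.0), ("V5Gy", 50.0),
                                ("V25Gy", 5.0), ("V30Gy", 2.5))

    def __post_init__(self):
        if self.n_fractions < 1:
            raise PlanError("prescription needs >= 1 fraction")
        if self.total_dose_gy <= 0:
            raise PlanError("prescription dose must be positive")


@dataclass(frozen=True)
class Plan:
    technique: str  # tangential | arc | helical
    beams: tuple[Beam, ...]
    prescription: Prescription = field(default_factory=Prescription)
    normalized: bool = False
    meta: tuple = ()  # immutable key/value pairs (arc span, stations, ...)

    def __post_init__(self):
        if self.technique not in ("tangential", "arc", "helical"):
            raise PlanError(f"unknown technique {self.technique!r}")
        if sum(b.weight for b in self.beams) <= 0:
            raise PlanError("total beam weight must be positive")

    @property
    def meta_dict(self) -> dict:
        return dict(self.meta)

    def with_weights_scaled(self, factor: float) -> "Plan":
        beams = tuple(replace(b, weight=b.weight * factor) for b in self.beams)
        return replace(self, beams=beams)


# --------------------------------------------------------------------------
# radiological path (exact Siddon-style voxel traversal)


def radiological_path(grid: DensityGrid, p0, p1) -> float:
    """Exact line integral of density along a segment, in g/cm^2.

    Voxel-traversal (Siddon) integration: the segment is cut at every voxel
    boundary plane it crosses and each piece contributes density times piece
    length. Symmetric in its endpoints and additive over subsegments;
    portions outside the grid contribute zero.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    length = np.linalg.norm(d)
    if length == 0:
        raise ValueError("radiological_path requires p0 != p1")

    lo = grid.origin - grid.spacing / 2          # outer bbox corner
    hi = lo + grid.spacing * np.asarray(grid.shape)

    tmin, tmax = 0.0, 1.0
    for ax in range(3):
        if d[ax] == 0:
            if not (lo[ax] <= p0[ax] <= hi[ax]):
                return 0.0
        else:
            t0 = (lo[ax] - p0[ax]) / d[ax]
            t1 = (hi[ax] - p0[ax]) / d[ax]
            if t0 > t1:
                t0, t1 = t1, t0
            tmin = max(tmin, t0)
            tmax = min(tmax, t1)
    if tmax <= tmin:
        return 0.0

    ts = [np.array([tmin, tmax])]
    for ax in range(3):
        if d[ax] != 0:
            planes = lo[ax] + grid.spacing[ax] * np.arange(grid.shape[ax] + 1)
            t = (planes - p0[ax]) / d[ax]
            ts.append(t[(t > tmin) & (t < tmax)])
    ts = np.unique(np.concatenate(ts))

    mids = p0 + np.outer((ts[:-1] + ts[1:]) / 2, d)
    idx = np.floor((mids - lo) / grid.spacing).astype(int)
    idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
    rho = grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    seg_cm = np.diff(ts) * length / 10.0
    return float(np.sum(rho * seg_cm))


# --------------------------------------------------------------------------
# dose computation


def _depth_lattice(grid: DensityGrid, beam: Beam,
                   uv_cell: float, t_cell: float):
    """Radiological depth sampled on a beam-anchored fan lattice.

    Returns (depth[iu, iv, it] in water-equivalent cm, u0, v0, t0, steps).
    """
    corners = np.array([[x, y, z]
                        for x in (grid.origin[0] - grid.spacing[0] / 2,
                                  grid.origin[0] + grid.spacing[0] * (grid.shape[0] - 0.5))
                        for y in (grid.origin[1] - grid.spacing[1] / 2,
                                  grid.origin[1] + grid.spacing[1] * (grid.shape[1] - 0.5))
                        for z in (grid.origin[2] - grid.spacing[2] / 2,
                                  grid.origin[2] + grid.spacing[2] * (grid.shape[2] - 0.5))])
    cu, cv, cdist, _ = beam.bev_coords(corners)
    u0 = cu.min() - 2 * uv_cell
    u1 = cu.max() + 2 * uv_cell
    v0 = cv.min() - 2 * uv_cell
    v1 = cv.max() + 2 * uv_cell
    t0 = max(cdist.min() - 2 * t_cell, 1e-3)
    t1 = cdist.max() + 2 * t_cell

    us = np.arange(u0, u1 + uv_cell, uv_cell)
    vs = np.arange(v0, v1 + uv_cell, uv_cell)
    ts = np.arange(t0, t1 + t_cell, t_cell)

    # unit directions of the fan rays through each (u, v)
    w = (beam.axis[None, None, :]
         + (us[:, None, None] / beam.sad) * beam.e_u[None, None, :]
         + (vs[None, :, None] / beam.sad) * beam.e_v[None, None, :])
    w /= np.linalg.norm(w, axis=-1, keepdims=True)

    pts = (beam.source[None, None, None, :]
           + ts[None, None, :, None] * w[:, :, None, :])
    idx = (pts - grid.origin) / grid.spacing
    rho = ndimage.map_coordinates(
        grid.values, [idx[..., 0], idx[..., 1], idx[..., 2]],
        order=1, mode="constant", cval=0.0)
    # midpoint-corrected running integral, mm -> cm
    depth = (np.cumsum(rho, axis=2) - rho / 2) * (t_cell / 10.0)
    return depth, u0, v0, t0, uv_cell, t_cell


def compute_beam_dose(grid: DensityGrid, beam: Beam, *,
                      mu_per_cm: float = MU_WATER_PER_CM,
                      scatter_sigma_mm: float = SCATTER_SIGMA_MM,
                      blur: bool = True,
                      uv_cell: float = 5.0,
                      t_cell: float | None = None) -> DoseGrid:
    """Dose of a single beam on the whole grid (deterministic).

    Inverse-square and aperture membership are evaluated exactly per voxel;
    radiological depth is interpolated from the fan lattice.
    """
    if beam.weight > 0 and beam.aperture.is_empty:
        raise PlanError("zero-size aperture with positive weight")
    if beam.weight == 0:
        return DoseGrid(np.zeros(grid.shape), grid.spacing, grid.origin)
    t_cell = t_cell or float(np.min(grid.spacing))
    depth, u0, v0, t0, duv, dt = _depth_lattice(grid, beam, uv_cell, t_cell)

    pts = grid.voxel_centers()
    u, v, dist, _ = beam.bev_coords(pts)

    inside = beam.aperture.contains(u, v)
    dose = np.zeros(grid.shape, dtype=float)
    if inside.any():
        iu = (u[inside] - u0) / duv
        iv = (v[inside] - v0) / duv
        it = (dist[inside] - t0) / dt
        d_rad = ndimage.map_coordinates(depth, [iu, iv, it],
                                        order=1, mode="nearest")
        dose[inside] = (beam.weight
                        * (beam.sad / dist[inside]) ** 2
                        * np.exp(-mu_per_cm * d_rad))
    if blur and scatter_sigma_mm > 0:
        dose = ndimage.gaussian_filter(dose, sigma=scatter_sigma_mm / grid.spacing,
                                       mode="constant")
    return DoseGrid(dose, grid.spacing, grid.origin)


def compute_plan_dose(grid: DensityGrid, plan: Plan, *,
                      mu_per_cm: float = MU_WATER_PER_CM,
                      scatter_sigma_mm: float = SCATTER_SIGMA_MM,
                      blur: bool = True) -> DoseGrid:
    """Superposition of all beam doses; scatter blur applied once to the sum
    (the blur is linear, so this equals blurring per beam)."""
    total = np.zeros(grid.shape, dtype=float)
    for beam in plan.beams:
        total += compute_beam_dose(grid, beam, mu_per_cm=mu_per_cm,
                                   blur=False).values
    if blur and scatter_sigma_mm > 0:
        total = ndimage.gaussian_filter(total, sigma=scatter_sigma_mm / grid.spacing,
                                        mode="constant")
    return DoseGrid(total, grid.spacing, grid.origin)


# --------------------------------------------------------------------------
# plan builders


@dataclass(frozen=True)
class PlanBuildConfig:
    """Geometry defaults for the three technique builders (mm, deg)."""

    laterality: str = "left"
    flash_margin: float = 20.0     # anterior open margin of tangential fields
    aperture_margin: float = 5.0   # conformal margin around the PTV projection
    arc_span: float = 230.0
    n_arc_beams: int = 47
    n_helical_angles: int = 32
    fan_width: float = 25.0        # longitudinal fan aperture (helical)
    sad: float = DEFAULT_SAD_MM
    bev_cell: float = 2.5
    prescription: Prescription = field(default_factory=Prescription)


def _ptv_points(structures: StructureSet) -> np.ndarray:
    if "ptv" not in structures:
        raise PlanError("PTV mask is required")
    idx = np.argwhere(structures["ptv"])
    if idx.size == 0:
        raise PlanError("PTV is empty")
    return structures.origin + idx * structures.spacing


def _bev_mask_aperture(beam_like: Beam, points: np.ndarray, margin: float,
                       cell: float, v_limits: tuple[float, float] | None = None,
                       lateral_only: bool = False) -> Aperture:
    """Conformal aperture: BEV projection of points, dilated by a margin."""
    u, v, _, _ = beam_like.bev_coords(points)
    if v_limits is not None:
        keep = (v >= v_limits[0]) & (v <= v_limits[1])
        u, v = u[keep], v[keep]
    if u.size == 0:
        return Aperture(mask=np.zeros((1, 1), dtype=bool),
                        mask_u0=0.0, mask_v0=0.0, mask_cell=cell)
    pad = margin + 2 * cell
    u0 = u.min() - pad
    v0 = v.min() - pad
    nu = int(np.ceil((u.max() + pad - u0) / cell)) + 1
    nv = int(np.ceil((v.max() + pad - v0) / cell)) + 1
    mask = np.zeros((nu, nv), dtype=bool)
    iu = np.rint((u - u0) / cell).astype(int)
    iv = np.rint((v - v0) / cell).astype(int)
    mask[iu, iv] = True
    r = int(np.ceil(margin / cell))
    if r > 0:
        if lateral_only:
            selem = np.ones((2 * r + 1, 1), dtype=bool)
        else:
            yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
            selem = (yy ** 2 + xx ** 2) * cell ** 2 <= margin ** 2
        mask = ndimage.binary_dilation(mask, structure=selem)
    if v_limits is not None:
        vs = v0 + cell * np.arange(nv)
        mask[:, (vs < v_limits[0]) | (vs > v_limits[1])] = False
    return Aperture(mask=mask, mask_u0=u0, mask_v0=v0, mask_cell=cell)


def make_tangential_plan(structures: StructureSet,
                         config: PlanBuildConfig | None = None) -> Plan:
    """Two half-blocked parallel-opposed tangential fields, open anteriorly.

    The shared posterior block edge is the BEV plane u = 0 through a common
    isocenter placed just posterior of the PTV's tangential extent; the
    anterior side carries a flash margin beyond the PTV (and skin).
    """
    config = config or PlanBuildConfig()
    points = _ptv_points(structures)
    g1, g2 = (300.0, 120.0) if config.laterality == "left" else (60.0, 240.0)

    centroid = points.mean(axis=0)
    probe = Beam(g1, tuple(centroid), Aperture(rect=(-1, 1, -1, 1)), weight=0.0,
                 sad=config.sad)
    u_rel = (points - centroid) @ probe.e_u
    iso = centroid + (u_rel.min() - config.aperture_margin) * probe.e_u

    beams = []
    for g in (g1, g2):
        b0 = Beam(g, tuple(iso), Aperture(rect=(-1, 1, -1, 1)), weight=0.0,
                  sad=config.sad)
        u, v, _, _ = b0.bev_coords(points)
        anterior_positive_u = b0.e_u[1] > 0
        if anterior_positive_u:
            rect = (0.0, float(u.max() + config.flash_margin),
                    float(v.min() - config.aperture_margin),
                    float(v.max() + config.aperture_margin))
        else:
            rect = (float(u.min() - config.flash_margin), 0.0,
                    float(v.min() - config.aperture_margin),
                    float(v.max() + config.aperture_margin))
        beams.append(Beam(g, tuple(iso), Aperture(rect=rect), weight=0.5,
                          sad=config.sad, half_block_u=0.0))
    return Plan("tangential", tuple(beams), config.prescription,
                meta=(("laterality", config.laterality),))


def make_arc_plan(structures: StructureSet,
                  config: PlanBuildConfig | None = None) -> Plan:
    """A single conformal arc spanning ``arc_span`` degrees over the
    ipsilateral hemithorax, uniform weights, isocenter at the PTV centroid."""
    config = config or PlanBuildConfig()
    points = _ptv_points(structures)
    iso = points.mean(axis=0)
    k = np.arange(config.n_arc_beams)
    if config.laterality == "left":
        angles = 300.0 + config.arc_span * k / (config.n_arc_beams - 1)
    else:
        angles = 60.0 - config.arc_span * k / (config.n_arc_beams - 1)
    beams = []
    for g in angles:
        b0 = Beam(float(g), tuple(iso), Aperture(rect=(-1, 1, -1, 1)),
                  weight=0.0, sad=config.sad)
        ap = _bev_mask_aperture(b0, points, config.aperture_margin,
                                config.bev_cell)
        beams.append(Beam(float(g), tuple(iso), ap,
                          weight=1.0 / config.n_arc_beams, sad=config.sad))
    return Plan("arc", tuple(beams), config.prescription,
                meta=(("laterality", config.laterality),
                      ("arc_start", float(angles[0])),
                      ("arc_span", float(config.arc_span))))


def make_helical_plan(structures: StructureSet,
                      config: PlanBuildConfig | None = None) -> Plan:
    """Full-rotation fan beams at successive longitudinal couch positions.

    ``n_helical_angles`` uniformly spaced gantry angles over [0, 360) are
    replicated at abutting longitudinal stations whose fan windows tile the
    PTV's z-extent; apertures are PTV-conformal laterally and hard-limited to
    the fan window longitudinally.
    """
    config = config or PlanBuildConfig()
    points = _ptv_points(structures)
    centroid = points.mean(axis=0)
    zmin, zmax = points[:, 2].min(), points[:, 2].max()
    extent = max(zmax - zmin, 1e-6)
    n_st = max(1, int(np.ceil(extent / config.fan_width)))
    stations = zmin + config.fan_width * (np.arange(n_st) + 0.5)

    angles = 360.0 * np.arange(config.n_helical_angles) / config.n_helical_angles
    half_fan = config.fan_width / 2
    beams = []
    for z_st in stations:
        iso = np.array([centroid[0], centroid[1], z_st])
        for g in angles:
            b0 = Beam(float(g), tuple(iso), Aperture(rect=(-1, 1, -1, 1)),
                      weight=0.0, sad=config.sad)
            ap = _bev_mask_aperture(b0, points, config.aperture_margin,
                                    config.bev_cell,
                                    v_limits=(-half_fan, half_fan),
                                    lateral_only=True)
            if ap.is_empty:
                continue
            beams.append(Beam(float(g), tuple(iso), ap, weight=1.0,
                              sad=config.sad))
    if not beams:
        raise PlanError("helical plan has no beams covering the PTV")
    w = 1.0 / len(beams)
    beams = [replace(b, weight=w) for b in beams]
    return Plan("helical", tuple(beams), config.prescription,
                meta=(("laterality", config.laterality),
                      ("stations", tuple(float(z) for z in stations)),
                      ("fan_width", float(config.fan_width))))


# --------------------------------------------------------------------------
# normalization


def _d_hottest(values: np.ndarray, pct: float) -> float:
    """Minimum dose received by the hottest ``pct`` % of the voxels."""
    v = np.sort(values)[::-1]
    k = max(1, int(np.ceil(pct / 100.0 * v.size)))
    return float(v[k - 1])


def normalize_plan(plan: Plan, grid: DensityGrid, structures: StructureSet,
                   ptv_name: str = "ptv") -> Plan:
    """Scale all beam weights so PTV D90% equals the prescription dose."""
    p, _ = normalize_plan_with_dose(plan, grid, structures, ptv_name)
    return p


def normalize_plan_with_dose(plan: Plan, grid: DensityGrid,
                             structures: StructureSet, ptv_name: str = "ptv"
                             ) -> tuple[Plan, DoseGrid]:
    """As :func:`normalize_plan`, also returning the scaled plan dose."""
    dose = compute_plan_dose(grid, plan)
    ptv_vals = dose.values[structures[ptv_name]]
    if ptv_vals.size == 0:
        raise NormalizationError("PTV is empty")
    d90 = _d_hottest(ptv_vals, 90.0)
    if d90 <= 0:
        raise NormalizationError("plan dose is zero inside the PTV")
    factor = plan.prescription.total_dose_gy / d90
    scaled = replace(plan.with_weights_scaled(factor), normalized=True,
                     meta=plan.meta + (("normalization_factor", factor),))
    return scaled, DoseGrid(dose.values * factor, dose.spacing, dose.origin)
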