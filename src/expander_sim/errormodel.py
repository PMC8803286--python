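"""Inter-fractional port positional errors: sampling, calibration, PRE.

Two error classes are modelled. An **internal port error (IPE)** displaces
the port relative to the patient's anatomy (realised downstream by editing
the density grid); a **patient registration error (PRE)** displaces the
whole patient relative to the beams (realised here by translating every
beam's isocenter by the opposite shift, so accumulated dose lives natively
in the planning anatomy).

The per-fraction error distribution is calibrated to the measured data: the
per-axis supports are lateral [-17, 11] mm, vertical [-10.8, 7.0] mm and
longitudinal [-8.0, 7.0] mm, and 87% of 3-D displacement magnitudes fall
below 5 mm. Only the ranges and that sub-5-mm fraction are known, so the
model is the minimal calibratable form: per axis, a zero-mean two-component
Gaussian mixture (a small-error and a large-error component) truncated to
the support, with the large-component weight solved numerically so the 3-D
sub-5-mm probability equals the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.stats import norm, truncnorm

from .ctmodel import Shift
from .dosecalc import Beam, Plan
from .errors import DistributionError

AXIS_SUPPORTS_MM: tuple[tuple[float, float], ...] = (
    (-17.0, 11.0),    # lateral
    (-10.8, 7.0),     # vertical
    (-8.0, 7.0),      # longitudinal
)
SUB5_TARGET = 0.87
SUB5_RADIUS_MM = 5.0


@dataclass
class ErrorDistribution:
    """Truncated two-component Gaussian mixture of per-fraction port shifts.

    ``p_large`` is the probability (per axis, independently) of drawing from
    the wide component; if None it is solved at first use so that
    P(|shift| < 5 mm) equals ``sub5_target``. ``patient_offset_sigma`` adds
    an optional per-patient systematic offset (default off), emulating cases
    whose port sat persistently displaced through the course.
    """

    supports: tuple[tuple[float, float], ...] = AXIS_SUPPORTS_MM
    sigma_small: float = 1.5
    sigma_large: float = 6.0
    p_large: float | None = None
    sub5_target: float = SUB5_TARGET
    patient_offset_sigma: float = 0.0
    _p_solved: float | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.supports) != 3:
            raise DistributionError("need one (lo, hi) support per axis")
        for lo, hi in self.supports:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise DistributionError(f"invalid support ({lo}, {hi})")
        if self.sigma_small <= 0 or self.sigma_large <= 0:
            raise DistributionError("mixture sigmas must be positive")
        if self.p_large is not None and not (0 <= self.p_large <= 1):
            raise DistributionError("p_large must be in [0, 1]")
        if not (0 < self.sub5_target < 1):
            raise DistributionError("calibration target must be in (0, 1)")

    # -- analytic machinery ------------------------------------------------

    def _component_pdf(self, x: np.ndarray, axis: int, sigma: float) -> np.ndarray:
        lo, hi = self.supports[axis]
        z = norm.cdf(hi / sigma) - norm.cdf(lo / sigma)
        out = norm.pdf(x / sigma) / sigma / z
        out = np.where((x >= lo) & (x <= hi), out, 0.0)
        return out

    def sub5_probability(self, p: float) -> float:
        """P(||shift||_2 < 5 mm) for mixture weight ``p`` (numerical integral).

        The mixture density is linear in ``p`` per axis, so the triple
        integral over the 5-mm ball expands into eight component-product
        integrals, evaluated once on a fixed lattice.
        """
        n = 121
        r = SUB5_RADIUS_MM
        x = np.linspace(-r, r, n)
        w = np.full(n, x[1] - x[0])
        w[0] = w[-1] = (x[1] - x[0]) / 2
        A = [self._component_pdf(x, ax, self.sigma_small) * w for ax in range(3)]
        B = [self._component_pdf(x, ax, self.sigma_large) * w for ax in range(3)]
        gx, gy, gz = np.meshgrid(x, x, x, indexing="ij", sparse=True)
        ball = (gx ** 2 + gy ** 2 + gz ** 2) < r ** 2
        total = 0.0
        for c0 in (0, 1):
            for c1 in (0, 1):
                for c2 in (0, 1):
                    f0 = (B if c0 else A)[0]
                    f1 = (B if c1 else A)[1]
                    f2 = (B if c2 else A)[2]
                    m = np.einsum("ijk,i,j,k->", ball, f0, f1, f2)
                    total += (p if c0 else 1 - p) * (p if c1 else 1 - p) \
                        * (p if c2 else 1 - p) * m
        return float(total)

    @property
    def mixture_weight(self) -> float:
        """The large-component weight, solving the calibration if needed."""
        if self.p_large is not None:
            return self.p_large
        if self._p_solved is None:
            f = lambda p: self.sub5_probability(p) - self.sub5_target
            lo, hi = f(0.0), f(1.0)
            if lo * hi > 0:
                raise DistributionError(
                    "calibration target unreachable with these sigmas: "
                    f"P ranges [{hi + self.sub5_target:.3f}, "
                    f"{lo + self.sub5_target:.3f}]")
            self._p_solved = float(optimize.brentq(f, 0.0, 1.0, xtol=1e-10))
        return self._p_solved

    def axis_moments(self) -> list[tuple[float, float]]:
        """Analytic (mean, variance) per axis of the calibrated mixture."""
        p = self.mixture_weight
        out = []
        for ax in range(3):
            lo, hi = self.supports[ax]
            m = v = 0.0
            for weight, sigma in ((1 - p, self.sigma_small), (p, self.sigma_large)):
                a, b = lo / sigma, hi / sigma
                mean_c = truncnorm.mean(a, b, scale=sigma)
                var_c = truncnorm.var(a, b, scale=sigma)
                m += weight * mean_c
                v += weight * (var_c + mean_c ** 2)
            out.append((m, v - m ** 2))
        return out


@dataclass(frozen=True)
class ErrorSeries:
    """Ordered per-fraction shifts with class and scenario tags."""

    shifts: tuple[Shift, ...]
    error_class: str          # IPE | PRE
    scenario: str             # daily | systematic
    seed: int | None = None

    def __post_init__(self):
        if self.error_class not in ("IPE", "PRE"):
            raise DistributionError(f"error class must be IPE|PRE, got {self.error_class!r}")
        if self.scenario not in ("daily", "systematic"):
            raise DistributionError(f"scenario must be daily|systematic, got {self.scenario!r}")
        if self.scenario == "systematic" and len(set(
                (s.dx, s.dy, s.dz) for s in self.shifts)) > 1:
            raise DistributionError("systematic series must repeat one shift")

    def __len__(self) -> int:
        return len(self.shifts)

    def as_array(self) -> np.ndarray:
        return np.array([[s.dx, s.dy, s.dz] for s in self.shifts])


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the study's run matrix."""

    technique: str            # tangential | arc | helical
    error_class: str | None   # IPE | PRE | None (reference / override)
    scenario: str             # daily | systematic | override | reference

    def __post_init__(self):
        if self.scenario not in ("daily", "systematic", "override", "reference"):
            raise DistributionError(f"unknown scenario {self.scenario!r}")
        if self.scenario in ("daily", "systematic") and self.error_class not in ("IPE", "PRE"):
            raise DistributionError("daily/systematic scenarios need an error class")

    @property
    def label(self) -> str:
        if self.error_class:
            return f"{self.scenario}-{self.error_class.lower()}"
        return self.scenario


def sample_error_series(dist: ErrorDistribution, n_fractions: int, seed: int,
                        error_class: str = "IPE",
                        scenario: str = "daily") -> ErrorSeries:
    """Draw independent per-fraction shifts from the calibrated mixture.

    Sampling is inverse-CDF per truncated component, so every sample lies
    inside its axis support exactly; reproducible for a fixed seed.
    """
    if n_fractions < 1:
        raise DistributionError("need at least one fraction")
    p = dist.mixture_weight
    rng = np.random.default_rng(seed)
    samples = np.zeros((n_fractions, 3))
    for ax in range(3):
        lo, hi = dist.supports[ax]
        wide = rng.random(n_fractions) < p
        u = rng.random(n_fractions)
        for use_wide, sigma in ((False, dist.sigma_small), (True, dist.sigma_large)):
            sel = wide == use_wide
            if sel.any():
                a, b = lo / sigma, hi / sigma
                samples[sel, ax] = truncnorm.ppf(u[sel], a, b, scale=sigma)
    if dist.patient_offset_sigma > 0:
        samples += rng.normal(0.0, dist.patient_offset_sigma, size=3)
        for ax, (lo, hi) in enumerate(dist.supports):
            samples[:, ax] = np.clip(samples[:, ax], lo, hi)
    shifts = tuple(Shift(*row) for row in samples)
    return ErrorSeries(shifts, error_class, scenario, seed)


def systematic_shift(dist: ErrorDistribution,
                     override: tuple[float, float, float] | None = None) -> Shift:
    """The persistent large-error shift for the systematic scenario.

    Default: the largest-magnitude single-axis support bound, applied along
    its axis (lateral -17 mm under the measured supports); an explicit
    ``override`` vector is passed through unchanged.
    """
    if override is not None:
        return Shift(*override)
    best_ax, best_val = 0, 0.0
    for ax, (lo, hi) in enumerate(dist.supports):
        for v in (lo, hi):
            if abs(v) > abs(best_val):
                best_ax, best_val = ax, v
    vec = [0.0, 0.0, 0.0]
    vec[best_ax] = best_val
    return Shift(*vec)


def apply_pre(plan: Plan, shift: Shift) -> Plan:
    """Shift the patient by ``+shift`` relative to the planned fluence.

    Realised by translating every beam's isocenter (and with it the source
    and aperture) by ``-shift``: the patient grid is untouched, so the
    recalculated dose is already registered to the planning anatomy.
    Composes additively: ``apply_pre(apply_pre(p, a), b) == apply_pre(p, a + b)``.
    """
    d = shift.as_array()
    beams = tuple(
        replace(b, isocenter=tuple(np.asarray(b.isocenter) - d))
        for b in plan.beams)
    return replace(plan, beams=beams)
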