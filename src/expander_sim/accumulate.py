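"""Scenario execution: cumulative dose in the planning-anatomy frame.

Four scenario types per technique, mirroring the study design:

* **reference** — the normalized plan on the density-corrected grid;
* **daily** — per-fraction sampled shifts (IPE edits the grid, PRE shifts
  the beams), each fraction contributing 1/n of the plan dose, summed;
* **systematic** — one persistent large shift; a single perturbed full-plan
  calculation already at total-dose scale;
* **override** — the plan recalculated with the port overridden to
  tissue-equivalent density (the "ignore the port" strategy).

Fractions with identical shift vectors share one dose calculation and are
scaled by ``count / n_fractions`` (a single float). Besides being a cache,
this makes two consistency properties exact: a daily series of n identical
shifts equals the systematic scenario voxelwise, and a zero-error series
reproduces the reference dose bitwise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .ctmodel import Shift, override_port_as_tissue, shift_port
from .dosecalc import Plan, compute_plan_dose
from .errormodel import ErrorSeries, ScenarioSpec, apply_pre
from .errors import ScenarioError
from .grids import DensityGrid, DoseGrid, StructureSet
from .synthphantom import TissueModel


@dataclass
class ScenarioResult:
    """Cumulative dose plus per-fraction provenance."""

    spec: ScenarioSpec
    dose: DoseGrid
    provenance: list[dict]

    def __post_init__(self):
        if np.any(self.dose.values < 0):
            raise ScenarioError("cumulative dose must be non-negative")


def _checksum(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def _require_normalized(plan: Plan) -> None:
    if not plan.normalized:
        raise ScenarioError("plan must be normalized before scenario execution")


def run_reference(grid: DensityGrid, structures: StructureSet, plan: Plan
                  ) -> ScenarioResult:
    """Full normalized plan dose on the unperturbed (corrected) grid."""
    _require_normalized(plan)
    dose = compute_plan_dose(grid, plan)
    spec = ScenarioSpec(plan.technique, None, "reference")
    prov = [{"fraction": None, "shift": (0.0, 0.0, 0.0),
             "checksum": _checksum(dose.values)}]
    return ScenarioResult(spec, dose, prov)


def _fraction_dose(grid: DensityGrid, structures: StructureSet, plan: Plan,
                   shift: Shift, error_class: str) -> DoseGrid:
    """Full-plan dose with one shift applied as IPE or PRE."""
    if error_class == "IPE":
        g2, s2 = shift_port(grid, structures, shift)
        return compute_plan_dose(g2, plan)
    if error_class == "PRE":
        return compute_plan_dose(grid, apply_pre(plan, shift))
    raise ScenarioError(f"unknown error class {error_class!r}")


def run_daily(grid: DensityGrid, structures: StructureSet, plan: Plan,
              series: ErrorSeries) -> ScenarioResult:
    """Cumulative dose of the daily-variable scenario.

    Each fraction contributes its perturbed full-plan dose scaled by
    1/n_fractions; the result is registered to the planning anatomy (IPE
    edits densities in place, PRE moves the beams, so no warping is needed).
    """
    _require_normalized(plan)
    n = plan.prescription.n_fractions
    if len(series) != n:
        raise ScenarioError(f"series length {len(series)} != "
                            f"prescription fractions {n}")
    if series.scenario != "daily":
        raise ScenarioError(f"run_daily requires a daily series, "
                            f"got {series.scenario!r}")

    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(series.shifts):
        groups.setdefault((s.dx, s.dy, s.dz), []).append(i)

    cum = np.zeros(grid.shape, dtype=float)
    frac_info: dict[int, dict] = {}
    for key, members in groups.items():
        dose = _fraction_dose(grid, structures, plan, Shift(*key),
                              series.error_class)
        cum += (len(members) / n) * dose.values
        cs = _checksum(dose.values)
        for i in members:
            frac_info[i] = {"fraction": i, "shift": key, "checksum": cs}
    prov = [frac_info[i] for i in range(n)]
    spec = ScenarioSpec(plan.technique, series.error_class, "daily")
    return ScenarioResult(spec, DoseGrid(cum, grid.spacing, grid.origin), prov)


def run_systematic(grid: DensityGrid, structures: StructureSet, plan: Plan,
                   shift: Shift, error_class: str) -> ScenarioResult:
    """Cumulative dose of the systematic scenario (one persistent shift).

    One perturbed full-plan calculation; being a full-course plan dose it is
    already at total-dose scale (the per-fraction dose multiplied by the
    number of fractions).
    """
    _require_normalized(plan)
    dose = _fraction_dose(grid, structures, plan, shift, error_class)
    spec = ScenarioSpec(plan.technique, error_class, "systematic")
    prov = [{"fraction": None, "shift": (shift.dx, shift.dy, shift.dz),
             "checksum": _checksum(dose.values)}]
    return ScenarioResult(spec, dose, prov)


def run_override(grid: DensityGrid, structures: StructureSet, plan: Plan,
                 tissues: TissueModel | None = None) -> ScenarioResult:
    """Full-plan dose with the port overridden to tissue-equivalent density.

    The plan keeps the weights normalized against the metal-inclusive
    reference grid, so the comparison downstream isolates the effect of
    ignoring the metal.
    """
    _require_normalized(plan)
    g2 = override_port_as_tissue(grid, structures, tissues)
    dose = compute_plan_dose(g2, plan)
    spec = ScenarioSpec(plan.technique, None, "override")
    prov = [{"fraction": None, "shift": (0.0, 0.0, 0.0),
             "checksum": _checksum(dose.values)}]
    return ScenarioResult(spec, dose, prov)
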