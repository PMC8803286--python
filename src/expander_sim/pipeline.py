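"""End-to-end orchestration: config, scenario matrix, report, manifest.

``run_pipeline`` executes phantom synthesis -> density correction -> plan
building and normalization (per technique) -> the scenario matrix
{reference, daily-ipe, daily-pre, sys-ipe, sys-pre, override} -> ROI and
robustness report. All randomness flows from the config seed; a manifest
with the config hash and per-scenario seeds makes a run reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accumulate import (ScenarioResult, run_daily, run_override,
                         run_reference, run_systematic)
from .ctmodel import Shift, correct_artefacts, override_port_densities
from .dosecalc import (Plan, PlanBuildConfig, Prescription,
                       normalize_plan_with_dose, make_arc_plan,
                       make_helical_plan, make_tangential_plan)
from .errormodel import ErrorDistribution, sample_error_series, systematic_shift
from .errors import ConfigurationError
from .grids import DensityGrid, StructureSet
from .metrics import ROI, RobustnessReport, build_report, build_roi, port_slice_extent
from .io import save_structures, save_volume
from .synthphantom import (HUCalibration, PhantomConfig, TissueModel,
                           generate_phantom)

log = logging.getLogger("expander_sim")

ALL_TECHNIQUES = ("tangential", "arc", "helical")
ALL_SCENARIOS = ("reference", "daily-ipe", "daily-pre", "sys-ipe", "sys-pre",
                 "override")
_PLAN_BUILDERS = {
    "tangential": make_tangential_plan,
    "arc": make_arc_plan,
    "helical": make_helical_plan,
}


def _build(cls, data: dict | None, what: str):
    data = dict(data or {})
    try:
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigurationError(f"unknown {what} fields: {sorted(unknown)}")
        for key in ("grid_shape", "voxel_size", "body_center", "body_semiaxes",
                    "lung_center", "lung_semiaxes", "heart_center",
                    "heart_semiaxes", "implant_center", "artefact_slices",
                    "supports", "anchors"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(tuple(v) if isinstance(v, list) else v
                                  for v in data[key]) \
                    if isinstance(data[key][0], list) else tuple(data[key])
        return cls(**data)
    except (TypeError, ValueError) as e:
        raise ConfigurationError(f"invalid {what} config: {e}") from e


@dataclass
class RunConfig:
    """Everything a run needs; buildable from a YAML mapping."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    tissues: TissueModel = field(default_factory=TissueModel)
    calibration: HUCalibration = field(default_factory=HUCalibration)
    plan: PlanBuildConfig = field(default_factory=PlanBuildConfig)
    error: ErrorDistribution = field(default_factory=ErrorDistribution)
    techniques: tuple[str, ...] = ALL_TECHNIQUES
    scenarios: tuple[str, ...] = ALL_SCENARIOS
    systematic_override: tuple[float, float, float] | None = None
    systematic_pre_override: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        bad = set(self.techniques) - set(ALL_TECHNIQUES)
        if bad:
            raise ConfigurationError(f"unknown techniques: {sorted(bad)}")
        bad = set(self.scenarios) - set(ALL_SCENARIOS)
        if bad:
            raise ConfigurationError(f"unknown scenarios: {sorted(bad)}")
        if self.plan.laterality != self.phantom.laterality:
            self.plan = dataclasses.replace(self.plan,
                                            laterality=self.phantom.laterality)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {"phantom", "tissues", "calibration", "plan", "error",
                 "techniques", "scenarios", "systematic_override",
                 "systematic_pre_override", "seed"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {
            "phantom": _build(PhantomConfig, data.get("phantom"), "phantom"),
            "tissues": _build(TissueModel, data.get("tissues"), "tissues"),
            "calibration": _build(HUCalibration, data.get("calibration"),
                                  "calibration"),
            "plan": _build(PlanBuildConfig, data.get("plan"), "plan"),
            "error": _build(ErrorDistribution, data.get("error"), "error"),
            "seed": int(data.get("seed", 0)),
        }
        for key in ("techniques", "scenarios"):
            if key in data:
                kwargs[key] = tuple(data[key])
        for key in ("systematic_override", "systematic_pre_override"):
            if data.get(key) is not None:
                kwargs[key] = tuple(float(v) for v in data[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as e:
            raise ConfigurationError(f"cannot read config {path}: {e}") from e
        return cls.from_dict(data)

    def content_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj) if not f.name.startswith("_")}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def corrected_reference_grid(config: RunConfig
                             ) -> tuple[DensityGrid, StructureSet]:
    """Phantom -> artefact correction -> nominal metal overrides."""
    grid, structures = generate_phantom(config.phantom, config.tissues)
    if config.phantom.artefact_slices:
        grid = correct_artefacts(grid, structures,
                                 config.phantom.artefact_slices)
    grid = override_port_densities(grid, structures, config.tissues)
    return grid, structures


def plan_to_dict(plan: Plan) -> dict:
    beams = []
    for b in plan.beams:
        ap = b.aperture
        entry = {"gantry_deg": b.gantry_deg, "isocenter": list(b.isocenter),
                 "weight": b.weight, "sad": b.sad}
        if ap.rect is not None:
            entry["aperture"] = {"rect": list(ap.rect)}
        else:
            entry["aperture"] = {
                "mask_u0": ap.mask_u0, "mask_v0": ap.mask_v0,
                "mask_cell": ap.mask_cell,
                "mask": ["".join("1" if v else "0" for v in row)
                         for row in ap.mask],
            }
        beams.append(entry)
    return {"technique": plan.technique, "normalized": plan.normalized,
            "prescription": _jsonable(plan.prescription),
            "meta": _jsonable(dict(plan.meta)), "beams": beams}


def run_pipeline(config: RunConfig, out_dir=None) -> RobustnessReport:
    """Execute the full scenario matrix and return the combined report."""
    log.info("stage: phantom synthesis + density correction")
    grid, structures = corrected_reference_grid(config)
    rx = config.plan.prescription.total_dose_gy
    n_fr = config.plan.prescription.n_fractions

    base_seed = int(config.seed) % (2 ** 31 - 3)
    series = {}
    if "daily-ipe" in config.scenarios:
        series["IPE"] = sample_error_series(config.error, n_fr, base_seed,
                                            "IPE", "daily")
    if "daily-pre" in config.scenarios:
        series["PRE"] = sample_error_series(config.error, n_fr, base_seed + 1,
                                            "PRE", "daily")
    sys_ipe = systematic_shift(config.error, config.systematic_override)
    sys_pre = (Shift(*config.systematic_pre_override)
               if config.systematic_pre_override is not None else sys_ipe)

    # ROI slices: where the port sits, including simulated IPE extremes
    ipe_shifts: list[Shift] = []
    if "IPE" in series:
        ipe_shifts += list(series["IPE"].shifts)
    if "sys-ipe" in config.scenarios:
        ipe_shifts.append(sys_ipe)
    roi = build_roi(structures, port_slice_extent(structures, ipe_shifts),
                    expansion_mm=config.phantom.ptv_margin)

    all_rows: list[dict] = []
    reference_values: dict[str, dict] = {}
    plans: dict[str, dict] = {}
    for technique in config.techniques:
        log.info("stage: %s plan build + normalization", technique)
        plan = _PLAN_BUILDERS[technique](structures, config.plan)
        plan, _ = normalize_plan_with_dose(plan, grid, structures)
        plans[technique] = plan_to_dict(plan)

        log.info("stage: %s scenarios %s", technique, list(config.scenarios))
        reference = run_reference(grid, structures, plan)
        results: list[ScenarioResult] = []
        if "daily-ipe" in config.scenarios:
            results.append(run_daily(grid, structures, plan, series["IPE"]))
        if "daily-pre" in config.scenarios:
            results.append(run_daily(grid, structures, plan, series["PRE"]))
        if "sys-ipe" in config.scenarios:
            results.append(run_systematic(grid, structures, plan, sys_ipe, "IPE"))
        if "sys-pre" in config.scenarios:
            results.append(run_systematic(grid, structures, plan, sys_pre, "PRE"))
        if "override" in config.scenarios:
            results.append(run_override(grid, structures, plan, config.tissues))
        if "reference" in config.scenarios:
            results.append(run_reference(grid, structures, plan))

        rep = build_report(reference, results, structures, roi, rx)
        all_rows.extend(rep.rows)
        reference_values[technique] = rep.reference_values

    manifest = {
        "software": f"expander-sim {__version__}",
        "config_hash": config.content_hash(),
        "seed": base_seed,
        "series_seeds": {k: s.seed for k, s in series.items()},
        "systematic_ipe_mm": [sys_ipe.dx, sys_ipe.dy, sys_ipe.dz],
        "systematic_pre_mm": [sys_pre.dx, sys_pre.dy, sys_pre.dz],
        "techniques": list(config.techniques),
        "scenarios": list(config.scenarios),
    }
    report = RobustnessReport(all_rows, reference_values, manifest)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_volume(out / "phantom_density", grid)
        save_structures(out / "structures", structures)
        for technique, pdict in plans.items():
            (out / f"plan_{technique}.json").write_text(
                json.dumps(pdict, indent=1))
        if series:
            frames = []
            for s in series.values():
                arr = s.as_array()
                frames.append(pd.DataFrame({
                    "fraction": np.arange(len(s)),
                    "dx_mm": arr[:, 0], "dy_mm": arr[:, 1], "dz_mm": arr[:, 2],
                    "class": s.error_class, "scenario": s.scenario,
                }))
            pd.concat(frames).to_csv(out / "error_series.csv", index=False)
        report.to_csv(out / "report.csv")
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=1, sort_keys=True))
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        log.info("outputs written to %s", out)
    return report
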