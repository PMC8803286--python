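# expander-sim

Robustness analysis of external-beam breast radiotherapy against
inter-fractional positional variations of the metal port embedded in a
temporary tissue expander.

Patients irradiated after mastectomy with a tissue expander in place carry a
small high-density injection port (a rare-earth magnet inside a titanium
shell) inside the radiation field, and that port does not sit in the same
place every day. This package is a desk-scale, fully synthetic pipeline for
asking: *how much does that daily motion perturb the cumulative dose, and
which delivery technique tolerates it best?* It is written for medical
physicists and methods researchers who want a transparent, reproducible
model of the whole chain — phantom, density overrides, dose engine, error
simulation, accumulation, DVH analysis — rather than a commercial black box.

## What it models

* **Phantom** — a voxelized thorax with body, ipsilateral lung, heart, a
  spherical saline implant on the anterior chest wall, and the metal port
  (magnet core, density 8.0 g/cm³, in a titanium shell, 4.0 g/cm³) at the
  implant centre. HU↔density conversion is piecewise linear through the
  anchors (−1000, 0.001), (0, 1.0), (3926, 4.0), (10248, 8.0).
* **Three techniques** — tangential parallel-opposed half-blocked fields
  open anteriorly (3DCRT-like); a single 230° conformal arc (VMAT-like);
  full-rotation fan beams at successive couch positions (helical
  tomotherapy-like). Prescription 50 Gy in 25 fractions, normalized so PTV
  D90% = 50 Gy.
* **Dose engine** — divergent beams with inverse-square falloff,
  exponential attenuation along the density line integral
  (μ = 0.049 cm⁻¹ · ρ), and a 5-mm Gaussian scatter blur. Simple enough to
  verify analytically, rich enough that the port casts a dose shadow.
* **Two error classes × two scenarios** — internal port errors (IPE: the
  port moves inside the anatomy) and patient registration errors (PRE: the
  whole patient moves relative to the beams), each as daily-variable
  per-fraction samples or as one persistent systematic shift. The sampler
  is calibrated to the measured statistics: per-axis ranges of
  [−17, 11] / [−10.8, 7.0] / [−8.0, 7.0] mm and 87 % of 3-D deviations
  below 5 mm.
* **Metrics** — V_100%Rx of a 5-mm shell of tissue abutting the implant
  (the plausible recurrence site), V_20Gy of the ipsilateral lung and
  V_5Gy of the heart on the shell's slices, and point-dose-difference
  statistics (mean, IQR, P1–P99), all relative to the unperturbed plan.

## Worked example

```python
import expander_sim as es

grid, st = es.generate_phantom(es.PhantomConfig())
grid = es.override_port_densities(grid, st)

plan = es.normalize_plan(es.make_tangential_plan(st), grid, st)
ref = es.run_reference(grid, st, plan)

sys_ipe = es.Shift(-17.0, 0.0, 0.0)     # largest measured port error
ipe = es.run_systematic(grid, st, plan, sys_ipe, "IPE")

roi = es.build_roi(st, es.port_slice_extent(st, [sys_ipe]))
stats = es.point_dose_stats(
    es.dose_difference_map(ipe.dose, ref.dose, 50.0), roi)
print(f"ROI point-dose differences: P1 {stats.p1:+.2f}%  P99 {stats.p99:+.2f}%")
```

prints, on the default phantom:

```
ROI point-dose differences: P1 -5.19%  P99 +5.02%
```

i.e. a persistent 17-mm lateral port displacement moves the port's dose
shadow across the target shell, perturbing individual points by about ±5 %
of the prescription in the tangential technique — while running the same
scenario through `es.make_arc_plan` / `es.make_helical_plan` yields P1–P99
spreads of roughly 3.5 % and 2 %: rotational deliveries smear the shadow
over many directions. The full matrix (three techniques × six scenarios)
runs from the shell:

```bash
expander-sim run --seed 1 --out results/run
```

and writes `report.csv` / `report.json` with one row per technique ×
scenario plus a reproducibility manifest.

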