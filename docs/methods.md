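# Methods

This note documents the models inside `expander-sim`: what each stage
assumes, which parameters matter, and what the synthetic setting can and
cannot say about real patients.

## The question being modelled

A temporary breast tissue expander contains a metal injection port (a
rare-earth magnet core inside a titanium shell). During a 25-fraction,
50 Gy course the port's position varies from day to day. Two distinct
mechanisms produce the apparent motion:

* **internal port error (IPE)** — the port (or the whole expander) moves
  relative to the patient's anatomy;
* **patient registration error (PRE)** — the whole patient is set up
  slightly displaced relative to the planned beam geometry.

The pipeline quantifies how each mechanism, applied either as daily
per-fraction samples or as one persistent ("systematic") shift, perturbs the
cumulative dose in three delivery geometries, and how much planning with the
port overridden to tissue density overestimates coverage.

## Phantom

The computational patient is a regular voxel lattice (default 128×128×64 at
2.5 mm isotropic — large enough for 5-mm expansion shells and 17-mm shifts,
small enough for minute-scale runs) with axes lateral (x, +left), vertical
(y, +anterior) and longitudinal (z, +superior); world coordinates are mm at
voxel centres. Structures are schematic: ellipsoidal body, ipsilateral lung
and heart; a spherical saline implant (default radius 35 mm) on the anterior
chest; the port as coaxial cylinders (core radius 6 mm × 10 mm length,
shell 2 mm) with axis anterior–posterior at the implant centre. The port's
physical dimensions are not fixed by any measurement we model; they are
configurable assumptions. Geometry parameters are explicit world
coordinates for a left-sided case; `PhantomConfig.mirrored()` produces the
right-sided phantom (everything mirrors, including the heart — the phantom
is schematic, not anatomical).

Tissue densities (g/cm³): air 0.001, lung 0.26, breast 0.95, saline 1.00,
titanium shell 4.0, magnet core 8.0. Overlapping geometric masks are
resolved by priority (core > shell > implant > lung > heart > body), so
every voxel carries exactly one density. The HU→density calibration is a
piecewise-linear table through (−1000, 0.001), (0, 1.0), (3926, 4.0),
(10248, 8.0), clamped outside; the two metal anchors are not collinear with
the water point, so a single slope cannot represent it.

The PTV is the `ptv_margin` (5 mm) Euclidean expansion of the
implant-bearing chest wall, kept inside the skin (body eroded by
`skin_thickness`). Optional multiplicative streak noise on listed slices
emulates metal artefacts, solely to exercise the correction operation.

## CT editing

* **Artefact correction** replaces breast-tissue voxels on artefacted
  slices with the mean breast density of artefact-free slices; nothing else
  changes.
* **Metal override** assigns the nominal densities (4.0 / 8.0) inside the
  contoured shell and core; idempotent.
* **Port shift (IPE)** translates the port masks by the nearest-voxel
  rounding of the measured displacement (masks are boolean; interpolation
  would destroy them; the rounding error is at most half a voxel, 1.25 mm
  at default spacing). Vacated voxels are backfilled with the local
  background — implant density inside the implant, mean breast density
  elsewhere — a choice the clinical workflow leaves unstated; it avoids
  creating spurious air cavities. Where the shifted port overlaps anything,
  metal wins. Port voxel counts are conserved, and a shift that would push
  the port out of the body raises an error naming the offending axis.
* **Tissue override** sets the whole port to breast density (the
  "ignore the port" planning strategy).

## Dose engine

A deliberately transparent stand-in for clinical convolution/Monte-Carlo
engines. Per beam, the pre-scatter dose at voxel v is

    dose(v) = w · in_aperture(v) · (SAD / r(v))² · exp(−μ_w · d_rad(v))

with SAD = 1000 mm, μ_w = 0.049 cm⁻¹ (a 6 MV-like effective attenuation
coefficient for water), r the source–voxel distance and d_rad the
radiological depth (line integral of density from the source,
water-equivalent cm). A single isotropic Gaussian blur (σ = 5 mm) stands in
for scatter and electron transport; there is no buildup region. The
engine's central approximation is that attenuation scales with mass density
alone — crude for high-Z metal, but it reproduces the inverse-square and
depth behaviour exactly (verified analytically in the tests to ~10⁻⁶
relative) and makes the port cast a dose shadow, which is the effect under
study. All endpoints are *differences* between perturbed and reference runs
of the same engine, so absolute-dose fidelity is not required.

Numerically, `radiological_path` is the exact Siddon voxel-traversal
integral and serves as the oracle; `compute_beam_dose` evaluates depth on a
beam-anchored fan lattice (5 mm transverse, one-voxel steps along each fan
ray, midpoint-corrected cumulative sum) and interpolates trilinearly to the
voxels, while aperture membership and inverse-square are evaluated exactly
per voxel. Dose is exactly linear in beam weight; plan dose is the beam
superposition with the blur applied once to the sum (the blur is linear).

## Plans

* **Tangential** — two parallel-opposed beams (gantry 300°/120° for a
  left-sided case, mirrored for right), sharing one isocenter placed just
  posterior of the PTV's tangential extent so the posterior field border is
  the common half-block plane u = 0; the block sits `aperture_margin`
  (5 mm) behind the PTV so the whole target lies in the open field. The
  anterior side carries a 20-mm flash margin beyond the PTV and skin — the
  feature that makes this technique forgiving of anterior setup error. No
  wedges, no bolus.
* **Arc** — 47 beams uniformly spanning exactly 230° over the ipsilateral
  hemithorax, isocenter at the PTV centroid, each aperture the beam's-eye
  projection of the PTV dilated by 5 mm (rasterized at 2.5 mm).
* **Helical-like** — 32 gantry angles over [0°, 360°) replicated at
  abutting longitudinal stations (25-mm fan width) tiling the PTV z-extent;
  apertures PTV-conformal laterally, hard-limited to the fan window
  longitudinally.

Arc and helical weights are uniform — no inverse optimization; conformality
comes entirely from the per-angle apertures, and plan quality is then set
by normalization. This is sufficient for robustness *ordering*, which is
the endpoint; absolute plan quality (e.g. homogeneity) is below clinical
standards by construction. Every plan is normalized by one global weight
factor so PTV D90% equals 50 Gy (D_x convention: minimum dose of the
hottest x% of voxels).

## Error model

Only two facts about the measured per-fraction port displacements are
carried as constraints: the per-axis ranges — lateral [−17, 11] mm,
vertical [−10.8, 7.0] mm, longitudinal [−8.0, 7.0] mm — and that 87 % of
3-D displacement magnitudes are below 5 mm. The sampler is the minimal
calibratable distribution consistent with both: per axis, a zero-mean
two-component Gaussian mixture (σ_small = 1.5 mm for routine daily
variation, σ_large = 6 mm for occasional large excursions), truncated to
the measured support, components and axes independent. The large-component
weight p is solved once by root-finding so that P(‖shift‖ < 5 mm) = 0.87,
with the ball probability evaluated by deterministic numerical integration
(the mixture density is linear in p per axis, so the triple integral
expands into eight fixed component-product integrals); the solved default
is p ≈ 0.115. Sampling is inverse-CDF per truncated component, so supports
are respected exactly and runs are reproducible by seed. An optional
per-patient systematic offset (default off) can emulate cases whose port
sat persistently displaced.

The systematic scenario uses the largest measured single-axis error,
−17 mm lateral, applied along its axis; the measurement reports only the
magnitude ranges, so axis and sign are configurable choices. For the
systematic *registration* scenario used in the technique-ordering analysis
we use a 10-mm anterior patient shift: anterior is the direction the
tangential technique is explicitly designed to forgive (flash), so it is
the cleanest probe of the conformal-vs-open robustness contrast.

PRE is realized by translating every beam (isocenter, hence source and
aperture) by the opposite of the patient shift — exactly equivalent to
rigidly moving the patient, but it keeps the accumulated dose natively in
the planning anatomy with no resampling. The equivalence is tested against
an actual patient-grid translation, not assumed; agreement is bounded by
one voxel of motion at the local dose gradient.

## Accumulation

Daily scenarios sum 25 per-fraction doses, each a full-plan calculation on
the per-fraction anatomy (IPE) or beam geometry (PRE) scaled by 1/25 —
uniform fractionation, the clinical norm; under a linear engine this is
equivalent to true 2-Gy fraction calculations. Fractions with identical
shift vectors share one dose calculation, scaled by count/fractions
computed as a single float; besides caching, this makes two consistency
properties hold exactly: a daily series of 25 identical shifts equals the
systematic scenario voxelwise, and a zero-error series reproduces the
reference bitwise. The systematic scenario is one perturbed full-plan dose
(already at course scale). IPE doses are reported on planning anatomy
without warping — voxel correspondence is exact because IPE edits densities
in place.

## Metrics

The analysis ROI is the 5-mm shell of tissue abutting the implant: the
Euclidean expansion of the implant intersected with the PTV, minus the
implant, restricted to the z-slices where the port sits or migrates during
simulation. The expansion uses the full implant mask (port included), and
excludes the implant interior, reading the ROI as the tissue ring around
the implant. Distance is measured to the implant's sub-voxel surface,
estimated as the 0.5 level set of the linearly interpolated indicator on a
3× supersampled lattice — plain voxel dilation is biased at 2.5-mm spacing
(centre distances undershoot the contour, cube unions overshoot it); the
level-set construction lands within a few percent of the analytic shell
volume and converges with supersampling.

DVH conventions: V_x counts voxels with dose ≥ x (">=" at the threshold);
D_x is the minimum dose of the hottest x% of voxels; percentile statistics
(IQR, P1–P99) use linear interpolation between order statistics. OAR
metrics (lung V_20Gy, heart V_5Gy) are evaluated only on slices where the
ROI is present. All point-dose differences are percentages of the 50-Gy
prescription.

## What the synthetic setting shows — and what it does not

The phantom reproduces the *mechanisms*: the port's shadow and its motion
(IPE), the interplay of setup error with field conformality (PRE), and the
attenuation removed by a tissue override. On the default phantom the
pipeline reproduces the expected qualitative orderings: tissue override
never lowers ROI coverage in any technique; a 10-mm systematic registration
error costs the conformal arc and helical deliveries more ROI coverage than
the tangential fields; and the systematic internal port error produces the
widest ROI point-dose spread in the tangential technique, where a single
shadowed ray direction dominates.

It does not reproduce patient-specific percentages: those depend on real
anatomies, clinical fluence optimization, and commercial dose engines, none
of which are modelled. Deformable anatomy, breathing, rotational port
motion, Monte-Carlo noise and NTCP/TCP modelling are out of scope. Passing
tests therefore validate the method's internal consistency and the
direction and rough ordering of its effects, not clinical dose accuracy.

## Numerical choices and degenerate inputs

* Nearest-voxel mask translation; exact voxel multiples round-trip exactly.
* Beam-space depth lattice: 5-mm transverse cells, one-voxel ray steps,
  trilinear interpolation everywhere; segments outside the grid contribute
  zero density.
* Gaussian blur uses zero-padding boundaries (outside the body is air).
* Normalization demands nonzero PTV dose; empty PTVs, empty masks, zero
  apertures with positive weight, out-of-body shifts and malformed volume
  files raise typed errors rather than propagating silently.
* An empty ROI is returned with a warning (not an error) so callers can
  report it; statistics over an empty mask raise.
* All randomness flows from explicit seeds; reports and manifests are
  byte-reproducible for a fixed config and seed.

## Problem sizes

Default runs use the 128×128×64 phantom; unit tests use a half-scale
(48×48×32) phantom with identical containment relations. The full
three-technique scenario block on the default phantom (reference, override,
systematic IPE and PRE per technique) computes in a few minutes on one
core; daily 25-fraction scenarios add one full-plan dose per unique shift.
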