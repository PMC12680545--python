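# Methods

This note documents the models implemented in `femrisk`, the choices
made where the underlying procedure was open, and what the synthetic
data do and do not establish about real images.

## Impact-force models

Peak sideways-fall impact force is modelled per metric as
`F [kN] = a·x + b`. Two coefficient sets are built in.

`as_printed` carries the published equations verbatim. Their coefficient
strings are typographically corrupted in the source (slope and intercept
run together, e.g. `−0.10310.2∗age+`); we parse each as
"slope · variable + intercept" with the trailing sign attached to the
intercept, giving age `−0.103·age + 10.2`, weight
`0.00756·W[N] + 0.00555`, height `4.55·h − 2.72`, STT
`−0.0723·t + 7.10`. This set does **not** reproduce the published
group-level force summaries, so both parse candidates are preserved
rather than guessing a single truth.

`table_reconciled` (the default for BSI computation) instead recovers
each line from the published cohort summaries, exploiting that a linear
map commutes with order statistics and standard deviations:

* age from the control quartile pairs (54.0 y, 4.12 kN) and
  (68.8 y, 3.15 kN) → `F = −0.06554·age + 7.659`;
* weight from (47.0 kg, 3.87 kN) and (60.1 kg, 4.14 kN) →
  `F = 0.02061·w + 2.901` (kilograms; the printed weight tables use kg,
  whereas the printed equation uses newtons — `g = 9.81` converts);
* height from (1.54 m, 4.21 kN) and (1.65 m, 4.89 kN) →
  `F = 6.182·h − 5.310`;
* STT from the control means/SDs (34.3 ± 8.78 mm, 4.42 ± 0.692 kN):
  `|a| = 0.692/8.78`, sign negative (thicker trochanteric soft tissue
  attenuates impact), intercept from the means →
  `F = −0.07882·t + 7.123`.

The reconciled set reproduces all published per-metric force summaries
to within 0.01–0.04 kN. The per-subject maximum over available metrics
is the BSI denominator; exact ties break to the fixed order
age < weight < height < stt (the source is silent on ties). Aggregation
of literature lines is the unweighted mean of slopes and intercepts by
default, with sample-size weighting opt-in.

## BVF mapping

On the FLASH hip acquisition bone is hypointense and marrow
hyperintense. Within the periosteal segmentation, reference intensities
for pure bone (1st percentile) and pure marrow (99th percentile) are
estimated in cubic windows (default radius 10 in-plane voxels, scaled
per axis for anisotropy) centred on a coarse lattice, each voxel using
its nearest lattice references; windows with fewer than 50 bone-region
voxels or no contrast fall back to global references. BVF is the linear
partial-volume inversion `(I_marrow − I)/(I_marrow − I_bone)` clamped to
[0, 1], kept internally on the [0, 1] scale (0–100 is a display
convention). The exact local-threshold estimator of the original
processing chain is unpublished; this windowed-percentile scheme is a
stated stand-in with the same contract. A polarity switch supports
bone-bright contrasts.

Limitation: reference-based thresholding needs near-pure voxels of both
phases in the image. If a volume contains only mid-range mixtures, the
percentile references stretch the observed intensity range and the map
overstates contrast. The default phantom's clipped trabecular field
provides both phases deliberately; very coarse or very uniform inputs do
not, and results there say little about real data.

## Finite-element strength

Every voxel with BVF ≥ 0.01 becomes an 8-node trilinear hexahedron
(isotropic elasticity, 2×2×2 Gauss integration; engineering-shear Voigt
convention). Only the largest 6-connected component is meshed. Units are
SI internally; forces are reported in kN.

Material: `E = E0 · BVF · sech(k · ε_eq)` with `E0 = 15 GPa`, `ν = 0.3`.
The softening argument and rate are this package's decisions: `ε_eq` is
the von Mises (deviatoric) equivalent strain at the element centroid,
normalised by `3/(2(1+ν))` so that a uniaxial stress state gives exactly
the axial strain — this makes the homogeneous-bar response
`σ(ε) = E0·ε·sech(kε)` independent of ν, with peak at `ε* = x*/k`,
`x* tanh x* = 1 ≈ 1.19968`. The default `k = 120` puts the uniaxial peak
near 1% tissue strain, physiologic for bone; both are configurable. The
secant factor is floored at 0.01 (crushed tissue retains ~1% residual
stiffness), which also bounds the stiffness contrast seen by the
iterative solver.

Boundary conditions: the load axis is the ground normal rotated by the
diaphysis tilt (10°, about the anterior–posterior axis) then the
internal rotation (15°, about the inferior–superior axis). Head-patch
nodes are driven along this axis with lateral components free;
trochanter-patch nodes are fixed along it; the distal shaft cut is fully
fixed (the source does not state its distal condition; full fixation is
a stability decision). Oblique single-direction constraints are imposed
exactly by rotating the affected nodes into an orthonormal basis whose
first axis is the load axis — no penalties, and the system stays
symmetric positive definite. "3% strain" is interpreted as *apparent*
strain: prescribed head displacement over the initial
head-to-trochanter gauge length along the load axis, reached in
`n_steps` (default 30) equal increments.

Per increment the softened moduli are resolved by secant (Picard)
iteration with **irreversible damage**: an element's secant factor may
only decrease along the loading path. Without irreversibility, elements
that unload when a crushed neighbourhood sheds load would regain
stiffness and the iteration cycles; with it the modulus sequence is
non-increasing and bounded below, so the iteration settles. An increment
is accepted when the largest relative modulus decrease is below 1% or
the head reaction force is stable to 0.5% (cap 25 iterations;
post-peak increments may hit the cap, which slightly smooths the
descending branch but leaves the recorded peak intact to the stated
oracle tolerances). Linear solves use conjugate gradients (relative
residual 1e-6) preconditioned by an exact sparse LU of a reference
stiffness, refreshed when CG slows; systems under ~6000 unknowns are
solved directly. Strength is the maximum of the recorded
force–displacement curve, with the apparent strain at the peak.

## Soft-tissue thickness

STT is the minimum Euclidean distance (mm, voxel-anisotropy aware)
between trochanter-surface pixels and the skin outline, per coronal
slice, minimised over slices; straight-line distance is used (the
source does not say whether its distance was straight-line or purely
lateral). Without an explicit trochanter label, the trochanter is the
bone surface in the superior third of the bone's extent on the lateral
side of the bone centroid; an explicit label overrides this.

## Synthetic data

**Phantom.** A stylized femur — shaft cylinder, neck capsule at a 130°
neck-shaft angle, spherical head, lateral trochanteric bulge — on a
1.5 mm isotropic grid (~60×26×58 voxels) so the full nonlinear FE chain
runs in minutes on one CPU. Ground-truth BVF: cortical shell at 1.0
(1.8 mm), trabecular interior a clipped correlated Gaussian field
(mean 0.45, SD 0.30, correlation length 3 mm — the clipping leaves
pure-marrow and pure-bone voxels so the mapper's references are
identifiable), low-density medullary canal. Grayscale is the inverse of
the mapper's mixing model plus Gaussian noise; the soft-tissue slab
places the lateral skin a configured pad (default 34.3 mm, the control
mean) from the trochanter. All randomness flows from one seed; equal
specs give bit-identical outputs. These defaults put the intact
phantom's strength near 5 kN — a healthy-range femur — so that halving
the trabecular BVF moves its BSI across the fracture threshold under a
median-control impact force, which is the designed end-to-end contrast.
The phantom exercises meshing, boundary conditions, mapping and
measurement; it does not emulate trabecular microarchitecture, MRI
physics (bias fields, coil shading) or anatomical shape variation, so
passing round trips validate the inverse operations, not robustness to
those real-data effects.

**Cohort.** Matched 10+10 fracture/control tables. Control age, weight
and height are drawn from two-piece normal distributions
quantile-matched to the published median/quartiles (the printed IQRs
are asymmetric), via stratified inverse-CDF sampling by default so a
cohort of ten actually resembles the summaries it emulates; fracture
subjects are their controls plus per-pair offsets bounded by the
published matching tolerances (±0.3 y, ±0.04 m, ±6 kg). (The published
group medians for age differ by 0.5 y despite the ±0.3 y pair
tolerance, which a pairwise-matched design cannot produce; the
generator keeps pairs within tolerance.) STT is group-specific
(34.3 ± 8.78 vs 22.6 ± 7.10 mm, floored at 2 mm). Strength is a
per-subject bone-quality proxy times that subject's maximum impact
force, the proxy drawn around 0.862 (control) with group effect −0.326
and SD 0.336, i.e. Cohen's d ≈ −0.97 — the published effect sizes are
the calibration targets. Which metric attains the per-subject maximum
force depends on the joint metric distribution, which the source does
not publish; the generator's attribution mix (STT-heavy because the
fracture group's thin soft tissue inflates its STT force) therefore
differs from the published height-heavy split and is not a calibration
target.

## Statistics

Per group, an Anderson–Darling normality gate at α = 0.05 (scipy's
interpolated p-value; fixed 5% critical value on older scipy). Both
groups normal → two-sample pooled-variance t test, else Wilcoxon
rank-sum. "One-way two-sample t test" in the source is ambiguous; the
default here is two-sided with an opt-in one-sided
(fracture < control) alternative. Summaries are mean ± SD when normal,
median [IQR] otherwise. The mean difference (fracture − control)
carries a pooled-SD t-based 95% CI and pooled-SD Cohen's d (the source
states neither formula). No multiple-testing correction, matching the
exploratory design. BSI = 1.0 exactly is classified non-fracture (the
rule is strictly "less than unity").

## Problem sizes and tolerances

Unit tests run bars of 10–250 elements (direct solves, machine-precision
patch test, 0.5% Hooke-bar and 2% sech-peak tolerances at 60 steps).
The end-to-end check runs the default phantom (~10 000 elements,
~37 000 unknowns) twice — intact and trabecular-halved — at 10
increments with a 10-iteration secant cap and CG tolerance 1e-5, which
resolves the pre-peak curve at 0.3% apparent-strain spacing; that is
sufficient for classification and monotonicity, while production runs
default to 30 increments. The cohort acceptance layer uses 100 seeds
for the effect direction and 200 label shuffles for the null.

## Known limitations

* The strength solver is quasi-static displacement control; no contact,
  soft-tissue padding, or impact dynamics.
* The sech constants are not published in the source chain; `k` is an
  exposed parameter, and absolute strengths shift with it (the BSI
  pipeline is linear in strength, so cohort *contrasts* are insensitive
  to moderate `k` changes).
* The BVF mapper assumes both pure phases are present locally or
  globally (see above).
* Segmentation is an input everywhere; no automatic femur segmentation
  is provided.
* DXA/FRAX metadata are pass-through only.
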