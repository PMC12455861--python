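# Methods

## Inputs and geometry

All computations operate on *soft masks*: 3D scalar volumes on a shared
template grid whose voxel values in [0, 1] give the fraction of the voxel
occupied by the structure (lesion, cord, or tract probability). Inputs are
assumed co-registered; the package validates grid compatibility (shape,
spacing to 1e-4 mm, axis roles) but never resamples, and rejects oblique
affines (off-axis direction cosines > 1e-3) with a request to resample
first.

On read, every volume is reoriented to one fixed convention: array axis 0
runs right → left, axis 1 posterior → anterior, axis 2 inferior → superior.
This pins down the plane/axis correspondence used everywhere downstream —
axial maps collapse the S-I axis, coronal the A-P axis, sagittal the R-L
axis — following standard radiological usage. A voxel is treated as a cell
of volume ∏(spacing) centred on its index, which makes volume sums exact.
Soft values within 1e-6 outside [0, 1] are clamped as float noise; larger
excursions are reported as errors rather than silently clipped.

## Projection maps

For each plane, the pixel value is Σ(soft value × through-plane spacing)
along the collapsed axis — the lesion's through-plane extent in mm rather
than a voxel count, so maps are comparable across grids with different
slice thicknesses (clinical sagittal acquisitions vary roughly 2–4 mm).
Since each plane integrates the same 3D mass, all three maps integrate to
the identical lesion volume; this conservation is asserted at construction
to 1e-9 relative and exercised on random soft lesions in the tests.

## Tract damage

Damage of a tract (or merged tract group) is

    100 · Σ(min(lesion, 1) · tract) / Σ(tract)

with both masks kept fuzzy: the numerator is the expected overlap volume
between a partial-volume lesion and a probabilistic tract. Binarizing the
lesion first is available as an option but off by default, since the soft
values are the point of partial-volume segmentation. Voxels are pooled over
the evaluation region (no per-slice averaging).

By default both sums run only over the lesion's superior–inferior span
(slices with any soft value > 0.01, a threshold chosen to ignore
interpolation ringing after template warping; configurable). This bounded
denominator measures "what fraction of the tract *at the injury level* is
damaged" and matches the bounded 3D lesion representation the projection
maps describe; an unrestricted whole-grid denominator is exposed via a
flag. With the bounded denominator, typical phantom and clinical-scale
lesions yield damage in the tens of percent rather than the vanishing
fractions a whole-cord denominator would give.

The atlas is manifest-driven: a CSV maps each NIfTI tract mask to a name, a
functional group (motor / sensory) and a side (left / right). The
conventional grouping — ascending dorsal-column, spinocerebellar,
spinothalamic, spinoreticular and spino-olivary tracts as *sensory*;
corticospinal, rubrospinal, reticulospinal, vestibulospinal and tectospinal
tracts as *motor* — is shipped as name lists and drives the phantom atlas,
but the tract count is whatever the manifest declares (atlases differ in
whether lateral/ventral subdivisions are separate entries). Merged group
masks sum member probabilities and cap at 1, since a voxel cannot exceed
100% white matter. When a mask is split about a sagittal midline, a voxel
exactly on an integral midline contributes half to each side so the split
conserves mass exactly; the default midline is the mean over S-I slices of
the per-slice cord centroid, robust for nearly straight template-space
cords.

## Tissue bridges and lesion type

Bridges are measured on the single sagittal slice through the cord's mass
centroid (rounded to the nearest slice index). Both masks are binarized at
0.5 — bridges are conventionally measured on hard boundaries. For every S-I
row of that slice where the lesion intersects the cord, the ventral gap is
the count of spared cord voxels anterior to the lesion times the A-P
spacing, the dorsal gap likewise posterior; the reported widths are the
minima over lesion rows (the narrowest spared corridor). A row where the
lesion reaches the cord boundary gives width 0. The minimum-gap rule is a
reasoned reconstruction of the established midsagittal bridge protocol,
which is defined operationally on manual tracings; it is the natural
"narrowest corridor" reading and is what the monotonicity guarantees
(growing a lesion can only narrow a bridge) rely on.

Lesion type follows from bridge presence: both intact → central; only
dorsal intact → ventral; only ventral intact → dorsal; none → complete.
"Intact" means width > 0 mm after binarization (threshold configurable).
A lesion with no voxels on the midsagittal slice leaves the 2D metric
genuinely undefined; the result carries an explicit flag instead of
fabricated widths, and downstream tabulation emits nulls. An empty lesion
is reported as type central (both bridges trivially intact) with zero
damage and volume.

## Clinical scores

ISNCSCI motor scores run 0–5 over 10 key muscles per side (max 50/side);
light touch and pinprick run 0–2 over 28 dermatomes per side (max 56/side).
Normalization divides a score by the maximum attainable over segments
*strictly below* the neurological level of injury, computed from a bundled
segment table; strict exclusion of the NLI segment is the conservative
reading and is configurable in spirit by passing a different level.
Recovery is expressed as raw month-6 minus month-1 differences per modality
and side — deltas need no normalization because the injury level cancels.
AIS grades are carried as data, never recomputed, since grade determination
has edge rules beyond this package's scope.

## Statistical models

*Longitudinal*: outcome ~ months post-injury with a random intercept per
patient and age, sex and center as fixed covariates of no interest. Random
slopes are deliberately omitted — cohorts of a few dozen patients with
three timepoints cannot support them. *Lateralized prediction*: one row per
patient × side; per-side tract damage at the early timepoint predicts the
per-side score delta, the patient random intercept absorbing the
within-patient correlation of the two sides (side itself enters through the
lateralized predictor, not as a fixed effect). *Cross-sectional*: ordinary
least squares at one timepoint with the same covariates.

Standardized coefficients z-score the predictor and outcome only,
covariates staying on their native scales; because that is an affine
rescaling, they are derived from the raw fit without refitting, and the
reported CI scales the raw Wald CI by sd(x)/sd(y). Mixed-model fit quality
is the Nakagawa–Schielzeth variance partition: marginal R² =
var(fixed)/(var(fixed)+var(random)+var(residual)), conditional R² adds the
random-intercept variance to the numerator. Center enters as an unordered
categorical fixed effect. Covariates constant in a given sample (a single
center, an all-male cohort) are dropped with a warning instead of producing
a singular design. When the random-intercept variance estimate collapses to
the boundary, the mixed fit's Hessian is singular and its fixed-effect
standard errors are undefined; inference then falls back to the OLS fit of
the same mean model, which the boundary solution equals. Group contrasts
use Welch's unequal-variance two-tailed t-test. No multiple-testing
correction is applied by default, matching common single-table reporting at
α = 0.05.

## Phantom generator

The generator emulates the study conditions this package targets — acute
cervical SCI with template-space segmentations and ISNCSCI exams at
baseline (~0.65 months post-injury), 1 month (~1.78) and 6 months (~6.32) —
while remaining fully analytic:

- **Cord/atlas**: a straight cylindrical cord (radius 4 mm, gray-matter
  core 1.6 mm) on a 0.5 × 0.5 × 2 mm grid; the white-matter annulus is
  partitioned into one angular sector per tract (sensory posterior, motor
  anterior), mirrored left/right. Sectors are disjoint by construction, so
  tract masses sum exactly to the annulus mass and left/right masks are
  exact mirror images. Even grid dimensions keep voxel centres off the
  midline, making side assignment unambiguous.
- **Lesions**: ellipsoids with a linear soft-edge ramp (not Gaussian) so
  that fuzzy overlap truths are exactly computable by enumeration;
  presets place the ellipsoid to realize each of the four lesion types.
  Ground truth (per-tract fuzzy overlap, volume, bridge widths from an
  independent row-scan, intended type) is enumerated at generation time.
- **Cohorts**: 35 patients by default, lesion volume starting near 382 mm³
  and shrinking 14.04 mm³/month, sensory/motor damage near 70%/63% with
  slopes −0.69 and +0.02 %-points/month, motor recovery ≈ 4.95 total
  points/month, with per-timepoint availability (1.0 / 0.90 / 0.94)
  mimicking variable follow-up. The month-1→month-6 per-side delta is
  generated as mean + sd·(β·z(damage) + u + ε) with var(u)+var(ε) = 1−β²,
  so the configured β (−0.3 by default) *is* the population standardized
  coefficient — what the lateralized model should recover. Ages draw from
  N(47.5, 15) clipped to 18–70, sex is ~6% female, and three centers are
  used rather than the many sites of a real multicenter trial so that
  center cells stay populated at n = 35.

What the phantoms do *not* emulate: MR intensities, artifacts,
segmentation-rater variability, curved cords, realistic tract shapes, or
registration error. Passing tests therefore demonstrate the correctness of
the computations given segmentations, not robustness to acquisition or
segmentation noise.

## Numerical choices and degenerate inputs

- Spacing comparison tolerance 1e-4 mm; value clamp tolerance 1e-6;
  projection conservation asserted at 1e-9 relative.
- Damage is clipped into [0, 100] after division to absorb float residue.
- A tract with zero mass in the evaluation region is an error ("tract
  absent in lesion span"), not a 0 or NaN.
- Empty lesions short-circuit to zero damage rather than erroring inside
  the span computation.
- Determinism: all generation flows through one seeded
  `numpy.random.default_rng`; iteration orders are fixed, and NIfTI
  writing is byte-stable, so a fixed seed reproduces the full
  phantom → quantify → fit pipeline byte-for-byte.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 500 random binary
phantoms (≤ 16³) against a plain-Python enumeration oracle; 100 random soft
lesions for projection conservation; one hard ellipsoid on a 0.25 mm grid
against (4/3)πabc (agreement ≈ 0.1%, asserted < 2% to allow for
discretization at other radii); 200 synthetic cohorts for CI coverage of
the volume slope; 200 replicates for sign recovery and bias of β; 500
null-coupling replicates for type-I error; 200 nested lesion pairs for
monotonicity; and a 4-patient end-to-end determinism run. These sizes give
stable Monte-Carlo estimates (binomial SE ≈ 1–2 points at 200–500
replicates) while keeping the whole validation run at a couple of minutes
on one CPU.

## Known limitations

- The bridge-width rule reconstructs a manual protocol; absolute widths on
  real tracings may differ from automated minimum-gap scans even when the
  presence/absence classification agrees.
- The damage denominator choice (lesion-span vs whole cord) changes the
  scale of the percentages; comparisons across studies must match
  conventions.
- The lateralized model assumes a patient random intercept is enough to
  capture left/right dependence; a side fixed effect or correlated residual
  structure is not fitted.
- Normalized scores and raw deltas are both emitted, but mapping between
  them requires the NLI-dependent maximum, so pooled-side aggregates are
  provided alongside per-side values rather than chosen for the user.
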