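# Methods

## Phantom model

A scene is a 64 × 64 × 48 voxel grid at 2 × 2 × 3 mm spacing (a typical
clinical PET reconstruction grid; 128 × 128 × 144 mm field of view). Into a
uniform background of SUV 0.5 we place:

* **one ellipsoidal lesion** (one per scene by default; multi-lesion scenes
  are supported). The analytic volume V = (4/3)π·a·b·c is drawn log-uniform
  on 1.1–6.1 mL — the observed clinical cohort range, with every lesion
  ≥ 1 mL per the cohort's inclusion rule; the log-uniform choice keeps the
  median near 2 mL, matching the reported median of 2.2 mL. Semi-axes get a
  mild volume-preserving random anisotropy (axis ratios 0.8–1.25,
  renormalized). Lesion uptake is a uniform plateau drawn from SUV 6–20:
  no cohort SUVmax distribution is published, so the plateau range is an
  assumption chosen so that clinically debated thresholds (SUV ≈ 2.5–5)
  fall between background and plateau for every lesion; it is a config
  field, not an estimate.
* **three 10 mm reference cubes** (bone marrow, parotid, pituitary) at
  fixed positions far from the lesion, with SUVmean drawn *independently*
  and uniformly from the published ranges (0.67–1.89, 0.63–2.09,
  5.86–15.23). Only median and range are published, so the bounded uniform
  is the least-assumptive distribution; independence mirrors the reported
  absence of cross-tissue correlation.

The scene is then convolved with an isotropic-in-physical-space Gaussian
point-spread function, σ_axis = FWHM/(2√(2 ln 2))/spacing_axis. The default
FWHM is 5 mm: clinical post-reconstruction smoothing alone is ~2 mm, but
the effective resolution of a reconstructed clinical PET image is larger,
and 5 mm produces partial-volume behaviour (edge underestimation of small
lesions, blur halos at low thresholds) of realistic magnitude. Optional
additive Gaussian noise (default off) is truncated at zero. Lesion
placement keeps all structures ≥ 4σ + 2 mm from the grid border so the blur
conserves total image mass; placement is rejection-sampled against overlap
with the reference cubes (and other lesions) up to 100 retries.

The label map marks the *pre-blur* shapes and plays the role of the
morphological ground truth a CT contour provides clinically. The manifest
records both the analytic ellipsoid volume and the voxelized label-map
volume. The analytic value is the default "CT reference" handed downstream
(an optional multiplicative noise term emulates manual-contouring
variability); the voxel value is the only volume exactly attainable on the
grid and is the target used when a test asserts exact recovery.

### What the phantom does not emulate

Anatomy, attenuation/scatter, reconstruction artefacts, tracer kinetics and
uptake-time variability, heterogeneous lesion texture, and lesions abutting
physiologically avid structures. Passing tests therefore demonstrate the
correctness and the qualitative behaviour of the delineation and statistics
machinery under controlled partial-volume conditions — not clinical
performance on patient images.

## Geometry and delineation

Voxel membership is by voxel-center inclusion (boundary inclusive): a voxel
belongs to a shape iff its center satisfies Σ((xᵢ−cᵢ)/aᵢ)² ≤ 1 (ellipsoid)
or |xᵢ−cᵢ| ≤ side/2 per axis (cube). This matches how clinical workstation
masks rasterize and makes an exhaustive per-voxel oracle exact. Volumes are
voxel count × voxel volume (mL ≡ cm³); whether clinical workstations count
voxels or interpolate isocontours is unreported, so voxel counting is a
possible systematic difference from workstation volumes. VOI exclusion
shapes are removed after inclusion; an empty VOI is an error, an empty
suprathreshold set is a valid 0 mL result.

Thresholding is inclusive (≥): deterministic, and ties have measure zero
after blur or noise. "SUV_ref minus X%" resolves to (1 − X/100)·SUVmean_ref;
percentage rows below 125% in the reference families are read as these
subtractive variants, the only reading under which the resolved threshold
(hence the overestimation) ordering is monotone in the label. No
connected-component filtering is applied by default; a largest-26-connected-
component mode exists because visual verification in clinical workflows
implicitly removes disconnected off-target uptake.

The default battery contains the 47 tabulated rules: fixed SUV
{2.5, 3, 3.5, 3.75, 4, 4.5, 5, 10, 15}; isocontour 10–50% in 5% steps;
bone marrow ×{400, 375, 350, 200, 150}% and minus {10, 30, 40, 50, 60}%;
parotid ×{400, 375, 350, 300, 250, 200, 150}% and minus {40, 60, 70, 80}%;
pituitary ×125% and minus {30, 35, 40, 50, 60, 70, 80}%.

## Backwards thresholding

V(t) over a VOI is a right-continuous non-increasing step function whose
only jump points are the observed SUVs, so "the threshold giving the
identical volume" is generally unattainable; the implementation evaluates V
at every unique VOI value and returns the candidate minimizing
|V(t) − target|, ties toward the larger threshold. This discrete search is
exact and reproducible, unlike continuous bisection on a discontinuous
function. A target exceeding the whole-VOI volume returns the minimum
candidate with an `unattainable` flag. Cohort summary: mean, sample SD
(n−1), CoV = 100·SD/mean; the arithmetic cohort-mean threshold is then
reapplied to every lesion and scored like any fixed rule.

## Agreement statistics

* Correlation method gate: Pearson iff *both* paired samples pass
  Shapiro–Wilk at α = 0.05, else Spearman (Pearson on mid-ranks; two-sided
  t-approximate p). The exact clinical gating rule is unreported; requiring
  both samples normal is the conservative symmetric choice, and α is
  configurable.
* Bland–Altman differences are PET − reference, so positive bias =
  overestimation; limits are bias ± 1.96·SD (n−1 sample SD; multiplier
  configurable). The slope of differences regressed on pair means is
  reported as a proportional-bias diagnostic.
* CoV = 100·sample SD/mean, undefined for non-positive means.
* A battery rule whose volumes are degenerate (e.g. zero variance because
  no lesion reaches SUV 15) is reported with NaN correlation and a manifest
  warning rather than aborting the run.

## Problem sizes and determinism

The default cohort is 19 single-lesion scenes of 64 × 64 × 48 voxels; a
full pipeline run (47 rules + backwards + statistics) takes a few seconds,
and the test suite uses the same scale with smaller cohorts where a
property does not need all 19 lesions. All randomness flows from one
`numpy.random.default_rng(seed)`; identical config + seed gives
byte-identical CSV output.

## Known limitations

* Uniform plateau lesions make isocontour rules unrealistically stable:
  SUVmax ≈ plateau is well-defined, whereas clinical SUVmax depends on a
  single hottest voxel and is scanner/reconstruction sensitive.
* The voxelized truth differs from the analytic ellipsoid volume by up to a
  few percent at 2 × 2 × 3 mm spacing; comparisons against the analytic
  reference inherit that discretization error.
* The reference-cube SUVmean measured after blur is attenuated toward the
  background relative to the sampled value (the same partial-volume effect
  that affects lesions); resolved reference thresholds therefore sit
  slightly below their nominal multiples of the sampled tissue uptake.
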