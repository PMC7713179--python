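# Methods

## The measurement model

The quantity of interest is the fraction of a volume of interest (VOI)
around a metal implant whose CT numbers are incompatible with the normal
appearance of the local tissue. "Normal" is defined empirically, not
physically: an artifact-free reference region of the same material, in the
same scan geometry, gives a mean μ and standard deviation σ, and the closed
interval μ ± k·σ (k = 3) is taken as the normal range. The approach assumes

- CT numbers of artifact-free tissue are approximately Gaussian within a
  material compartment, so k = 3 covers 99.7% of normal voxels;
- the reference region is genuinely artifact-free (placed ≥ 10 cm from the
  implant) and representative of the VOI's material;
- all series of one study are acquired in the same position on the same
  grid, so a VOI drawn once can be copied to every series without
  resampling.

Voxels exactly on a bound count as normal ("beyond the thresholds" is read
strictly); ties are measure-zero for continuous data, so the convention
only matters for synthetic integer-valued inputs.

Thresholds for photon-counting (PCD) series are derived from the same-kVp
conventional (EID) series by default, because tube potential shifts CT
numbers and the conventional acquisition is the common reference. This is
deliberate and has a visible cost: energy thresholding also shifts material
means and raises noise, so EID-derived thresholds misclassify a substantial
fraction of perfectly normal PCD voxels. That is what the correction factor
is for: it is computed per series *and* per material by applying the
applied thresholds to that series' own artifact-free reference and
measuring the out-of-range percentage, then subtracting it from the raw
artifact percentage (floored at zero — negative artifact volume is
meaningless). On self-referenced series the correction reduces to the
Gaussian floor 2·Φ(−k) ≈ 0.27% at k = 3. A configuration switch
(`threshold_source: self`) derives thresholds from each series' own
reference instead; the ground-truth recovery experiment uses it so that
the detection boundary and the truth definition coincide.

Noise is the sample SD (n−1) of the water bath scanned without the phantom,
with a 3 cm margin to the surface and container. CNR between a tissue and
the with-phantom water bath is |Δμ| divided by the quadratic mean of the
two SDs, √((σ_t² + σ_w²)/2); this is the form that reproduces the published
per-protocol CNR values from the published material statistics (verified
for all 24 protocol×tissue cells), whereas normalising by the water SD
alone does not reproduce any of them. The literal form remains available
as `method="water_sd"`.

## The synthetic phantom

Geometry (defaults, all configurable): a 22 cm wide × 13 cm high water
bath; a femur model running the full z-extent with an elliptical cortical
shell (outer semi-axes 36 × 30 mm, 5 mm thick) around a marrow core; a
metal stem (3000 HU, titanium-like plumbing value chosen only to exceed
every threshold) tapering linearly from a 50 × 40 mm proximal to a
32 × 36 mm distal cross-section over 85 mm. The VOI window is the proximal
90 mm of the volume; the 72 mm reference window sits at the distal end,
separated by a 100 mm guard gap. Default grid 0.5 × 0.5 mm in-plane with
2 mm slices; experiments and tests use a geometrically identical phantom
at 1.5 × 1.5 × 4 mm (≈ 1M voxels) so the full suite runs in seconds.

Materials are painted at the published per-protocol mean CT numbers (twelve
protocols: EID at 100/120/140 kVp; Macro- and Chess-mode high-energy
threshold images at 140/75, 120/70, 100/65, plus Chess 140/65, 120/60,
100/55 keV). Noise is additive Gaussian in HU with one sigma per series —
the published water-bath SD — because the method itself only ever measures
noise as an SD in water; this is the main idealisation. Consequences: in
simulated series every material has the same SD (the published *tissue*
SDs are larger than the water SD), so CNR measured on simulated volumes is
higher than the published CNR. The CNR reproduction therefore feeds the
published statistics directly through the CNR operation; the simulator is
not a CT-physics engine and is not used for that check. A Chess protocol
with no configured sigma defaults to √2 × its Macro partner's sigma,
encoding that each Chess threshold setting uses half the detector
subpixels. The subpixel argument itself is simulated separately
(`simulate_detector_noise`): the SD of the mean of n unit-variance
subpixel samples is 1/√n, so 8 vs 16 subpixels gives a ratio of √2.

Streak artifacts are analytic, not reconstructed: an even number of angular
rays (default 24) alternating hyper-/hypo-dense, emanating from the stem
axis, with a steep generalised-Gaussian angular profile (exponent 6) and
amplitude decaying as 1/(1 + d/d₀) with d the distance to the stem axis
segment (in-plane within the stem's z-range, 3-D beyond the tip, so
artifacts fade both radially and past the tip). Ground truth is the set of
voxels whose injected perturbation exceeds a cutoff in magnitude; the
default cutoff is 3× the series noise so truth and detection share one
boundary and recovery is well posed. Design choices that keep the
ground-truth bookkeeping honest:

- the perturbation is truncated beyond a support radius (default 4·d₀,
  capped at 90% of the guard gap) so the reference region stays exactly
  artifact-free;
- the perturbation never touches air, the prosthesis, or the prosthesis'
  axial footprint (the in-plane union of stem cross-sections extended
  along z), so per-slice truth statistics vary smoothly along z instead of
  tracking the tapering metal cross-section; with the default untwisted
  ray pattern the slice-wise truth fraction is exactly non-increasing with
  distance from the stem tip;
- for calibrated experiments a slow azimuthal twist (0.003 rad/mm)
  decorrelates voxelised ray positions between slices, making the truth
  fraction a near-continuous function of the ray width; a bisection on the
  noiseless field then pins the width that puts an exact target fraction
  (5/10/20/40%) of truth into a VOI.

What passing the simulator-based tests does *not* show: the generator has
no beam hardening, photon starvation, scatter, partial-volume blur or
reconstruction-kernel correlation, so the tests validate the measurement
chain (statistics → thresholds → segmentation → correction → metrics), not
the physics fidelity of any scanner. Real streaks are spatially correlated
with tissue structure; ours are independent of the noise field.

## Numerical choices

- Sample SD (n−1 denominator) everywhere; negligible at volume scale,
  unbiased for the small fixtures used in tests.
- Metric erosion for margins: Euclidean distance transform with
  anisotropic voxel spacing in mm; a voxel survives if its distance to the
  mask complement strictly exceeds the margin. Margins: 2 mm for cortical
  bone and marrow, 30 mm for water.
- Strict grid identity (shape and spacing) for every cross-series
  operation; no resampling exists in the package by design.
- Reference/VOI masks are derived by eroding the full-length material mask
  first and windowing in z second, so margins act toward neighbouring
  materials rather than toward the z-crop planes.
- Percentages are reported to one decimal, CNR to two, HU to two, matching
  the conventional table precision; result objects keep full precision.
- One study seed is fanned out to per-stage seeds by CRC-32 hashing of
  "seed:tag" strings (kept below 2³¹), so adding a series never reshuffles
  the noise of the others.
- Degenerate inputs fail loudly: empty masks, single-voxel regions,
  zero pooled SD with non-zero contrast, single-slice VOIs in a distance
  profile, geometry that does not fit (stem vs marrow cavity, femur vs
  bath) are all errors, not warnings.

## Problem sizes

Tests and the recovery/distance/Chess-vs-Macro experiments run the
physical phantom at 1.5 × 1.5 × 4 mm (≈ 1.1M voxels per series); the
misclassification calibration uses 1.2–2M Gaussian voxels; the detector
simulation 150 000–300 000 pixel samples. At these sizes the recovery
experiment reads back injected truth fractions of 5–40% with worst-case
errors around 0.5 percentage points, comfortably inside the ±1.5 point
acceptance band, and the full test suite completes in well under a minute.

## Known limitations

- The single-sigma-per-series noise model cannot reproduce published
  *tissue* SDs, only water SDs (see above).
- EID-derived thresholds plus correction recover truth only up to a
  truth-dependent term (≈ truth × FPR); with the published cross-detector
  mean offsets that term reaches a few percentage points at high artifact
  loads, which is why the recovery experiment uses self-derived
  thresholds. This mirrors a genuine property of the method, not a bug in
  the implementation.
- The streak model's amplitude/decay/count have no measured counterparts
  (published scans report artifact percentages, not streak parameters);
  they are plumbing defaults chosen to exercise the pipeline.
- DICOM series ingestion is not implemented; volumes enter as NIfTI.
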