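# Methods

This note records the models, estimators, parameter choices and known
limitations behind `rcpvc`. It states no empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Digital phantom simulator

The simulator stands in for physical phantom sessions: perspex hot spheres
(10–37 mm) in a warm elliptical cylinder for calibration, and
sphere/zeolite-like inserts for validation.

**Activity map.** A declarative `PhantomSpec` (elliptical-cylinder
background, list of lesions) is rasterized on the clinical reconstruction
grid — voxels of (dz, dy, dx) = (3.27, 4.7, 4.7) mm, axis order
(slice, row, col), background cylinder 24 × 30 cm section and 21 cm height,
background concentration 0.01258 MBq/mL by default. Lesion boundary voxels
are weighted by sub-voxel occupancy (5×5×5 midpoint supersampling; the 3×3×3
rule biased 10 mm-sphere volumes ~6% low, 5×5×5 keeps the error near 1%, as
the total-activity test checks). Blobs are unions of sub-spheres at relative
control points, uniformly rescaled so the union volume matches the requested
sphere-equivalent diameter; `uniformity="gradient"` shapes the uptake by the
interior Euclidean distance transform with a stated peak-to-edge ratio
(default 3), normalized so the lesion mean equals the specified
concentration.

**Acquisition.** The activity map is convolved with an isotropic Gaussian
PSF (default FWHM 7.0 mm: intrinsic 4–5 mm scanner class plus
reconstruction smoothing), then zero-mean Gaussian noise with
std = `noise_scale`·√(signal)/√(t) is added and the result clipped at zero.
`noise_scale = 0.02 MBq^1/2 mL^-1/2 min^1/2` gives ≈10% per-voxel background
noise at the clinical 2.5 min/bed scan and ≈3% at a 30 min calibration scan
— a realistic reconstructed-image noise level, fixed once. Poisson noise on
raw counts, attenuation, scatter and OSEM reconstruction are deliberately
out of scope (see §7).

**Geometry conventions.** Physical mm coordinates sit at voxel centers with
voxel (0,0,0) at the origin. The six calibration spheres sit on a ring
(radius 80 mm) on a common axial plane through a slice center, as when a
sphere holder is aligned with the slice grid. In the calibration and
validation workflows every lesion/sphere additionally receives a seeded
sub-voxel position jitter: real lesions fall anywhere relative to the grid,
and on a 4.7 mm grid under a 7 mm PSF the sampled field is genuinely
undersampled, so measurements depend on that phase; randomizing it makes the
calibration curves phase-averaged rather than phase-biased.

## 2. Operator-independent isocontour measurement

The measurement chain is deterministic (fixed tie-breaks) and invariant
under positive rescaling of the volume.

- **Peak finding.** Within a search ball around the user seed, the axial
  slice with the highest in-ball activity sum is chosen (for any axially
  symmetric lesion this is the central slice, and single-voxel noise cannot
  move it — unlike the global max voxel, which wanders across the flat
  axial plateau of large spheres), then the hottest voxel on that slice.
  Ties break to the lowest index.
- **Axial refinement.** The measurement plane is cubic-interpolated between
  slices at the sub-slice axial peak position (parabolic fit to local slice
  sums). Without this, the measured cross-section of a lesion depends on
  where its center falls between slice centers (±1.6 mm).
- **In-plane refinement.** The plane is refined 4× per axis by cubic
  B-spline interpolation; blurred PET fields are smooth, so the spline
  tracks the underlying profile largely independently of sampling phase,
  and the isocontour area varies continuously with lesion size instead of
  jumping by whole-voxel (22 mm²) increments.
- **Threshold level.** 60% (the calibrated optimum) of a peak estimate
  taken as the mean of a small disk (radius 2.35 mm, half an in-plane
  voxel) around the refined local maximum — an SUVpeak-style average that
  is robust to single-voxel noise and sampling phase. A plain noisy maximum
  makes the threshold, and hence the contour, noise-dependent.
- **ROI.** The 4-connected component above the level containing the peak;
  contours touching the slice border are flagged `truncated`. A 3-D
  6-connected variant (`isocontour_roi_3d`) exists behind its own function
  but is not the default: the metabolic volume of the method is by
  construction the sphere built on the 2-D circle-equivalent diameter
  d = 2√(area/π).
- **Uptake.** C_thr is the mean inside the contour (a max-based uptake
  would be insensitive to the contour and make the recovery surface
  degenerate in diameter).
- **Background.** Four circular 2-D ROIs (diameter 15 mm) at 90° spacing
  around the lesion centroid on the measurement plane. The ring radius
  defaults to d_thr/2 + 8 mm + ROI radius so the ROI *inner edge* clears
  the lesion radius by about two PSF widths: a ring at 1.5·d_thr from the
  centroid (an earlier design) places the 15 mm ROIs on the blurred
  spill-out flank of sub-15 mm lesions, inflating B_m with contrast and
  distorting the recovery curves. If every rotation of the ring overlaps
  the lesion or leaves the slice, the measurement errors out and asks for a
  manual offset (the clinical analogue: exclude adjacent high-uptake
  organs).
- **Threshold optimization.** Across thresholds {50, 60, 70, 80}%, among
  those whose per-sphere mean percentage diameter differences
  100·(d − d_thr)/d are all non-negative (contours never larger than the
  sphere, so no background is swept into the ROI), the one with the
  smallest mean |difference| wins; with no qualifying threshold the
  smallest-|difference| one is returned with a warning.

## 3. RC calibration

**Design.** One simulation per gold-standard contrast level, all six
spheres sharing the level; 13 levels span L/B_GS 2.5–35, denser at the low
end because the hyperbola's curvature lives at low L/B_m and because the
spheres map a given L/B_GS to very different measured L/B_m (a 10 mm sphere
at L/B_GS 6 measures L/B_m ≈ 2–3). Calibration scans use 30 min acquisition
(noise-minimized), the clinical protocol's 2.5 min is used for validation.
Samples whose measured L/B_m falls outside the surface validity box [2, 30]
are discarded: below 2 the 60% level approaches the background and the
contour balloons into it, carrying no usable recovery information.

**Curves.** RC samples are grouped per physical sphere (six curves) and
fitted with RC(x) = a − b/(x + c) by bounded nonlinear least squares
(deterministic initialization: a₀ = RC at the largest sampled L/B_m
clipped to (0, 2], c₀ chosen above the pole bound, b₀ from the extreme
samples; the pole x = −c is constrained below the smallest sampled L/B_m).
The sign of b is free so the curve follows whichever monotone trend the
data shows — in this simulator small-sphere recovery *decreases* mildly
with L/B_m (see §7). Exactly constant samples short-circuit to a flagged
constant curve. r² = 1 − SS_res/SS_tot on the RC values; sample
uncertainties, when present, weight the fit (propagated in quadrature for
ratios).

**Surface.** Curves are indexed by measured isocontour diameter, but a
single label per curve is not enough: the 60% contour of one and the same
object measures larger at low contrast, so each curve carries its measured
diameter as a function of L/B_m (interpolated sample knots, `d_at`). A
query (L/B_m, d_thr) is placed among the curves by comparing d_thr with
each curve's diameter *at the query's L/B_m*, and RC is interpolated
across curves with a shape-preserving monotone cubic (PCHIP): RC versus
diameter is strongly convex between the 10 and 17 mm spheres, where a
linear chord systematically under-estimates RC and over-corrects mid-size
lesions. Queries outside the box are clamped to its edge and loudly
flagged, never extrapolated. Surfaces round-trip losslessly through a
versioned YAML file.

## 4. PVE correction and validation studies

`apply_correction` computes RC at the lesion's measured coordinates,
F = 1/RC, C_corr = F·C_thr, and carries clamping flags and provenance. Two
guards are hard errors: a threshold mismatch between measurement and
surface (calibration/correction consistency is the method's core claim)
and re-correcting an already-corrected record.

- `sphere_accuracy_study`: uniform spheres of 12.3–16 mm at L/B_GS 8–30
  (the contrast envelope in which the physical validation operated:
  measured L/B_m ≈ 5–18), each at a random sub-voxel position, measured
  and corrected three times with independent noise; the residual
  100·(C_GS − C_corr)/C_GS uses the replicate-mean corrected value, as the
  physical validation rows likewise carry replicate uncertainties.
- `subcentimeter_recovery_study`: the 9.8 mm insert at L/B_GS 8–18;
  recovery = 100·C_corr/C_GS, averaged over contrasts.
- `noise_sensitivity_study`: a 13 mm sphere at L/B_GS 8.5, acquisition
  times {2.5, 5, 10, 15, 30} min, 10 noise replicates each; reports the
  percentage difference of mean RC per time against the 30 min reference.
- `validation_study`: the clinical-like insert set (9.8–15.6 mm spheres,
  one uniform and two gradient blobs), per-lesion residuals partitioned by
  shape/uniformity class, with |residual| > 30% flagged unreliable —
  non-uniform lesions violate the uniform-sphere calibration assumption
  and are expected to land there.

Problem sizes were chosen to keep a full calibration-plus-validation cycle
around a few seconds on one CPU: calibration grids of 66×56×70 voxels per
level and compact 31×26×26 single-lesion cylinders for validation.

## 5. SUV and response classification

Body-weight SUV = C_tissue/(dose/(weight·1000 g)), with the net dose
(injected − residual) decay-corrected from injection to scan start using
the ¹⁸F half-life 109.77 min; decay correction is on by default (the 60 min
uptake protocol implies it) and can be disabled to reproduce idealized
examples. The PVE-corrected SUV uses the same measured concentration, so
the percentage difference is exactly 100·(F − 1). EORTC-style classes use
configurable cutoffs, default ±25% on the SUV percentage change; boundary
values map to stable disease (SMD); "complete metabolic response" is
operationalized as SUV_post at or below a configurable
background-equivalence level (default 1.0 g/mL), since the criteria's
"complete resolution" has no universal numeric form.

## 6. What the simulator does and does not emulate

It emulates: partial-volume spill-in/spill-out from finite resolution,
count-limited reconstructed-image noise and its 1/√t scaling, coarse
anisotropic sampling and the resulting sub-voxel phase effects, lesion
shape and uptake non-uniformity, and gold-standard bookkeeping.

It does not emulate: sinogram formation and OSEM reconstruction (and hence
the contrast- and object-size-dependent convergence bias of iterative
algorithms), attenuation/scatter/randoms and their corrections, patient
anatomy or physiological background heterogeneity, respiratory motion, or
scanner calibration drift. Tests passing on this simulator therefore
validate the *method's internal consistency* — that the measured-coordinate
lookup inverts the measurement process — not its absolute accuracy on any
particular scanner.

## 7. Known limitations

- **Flat recovery curves for large spheres.** Under a linear, stationary
  Gaussian PSF, the recovery of spheres larger than ~2.5× FWHM is nearly
  independent of contrast: their RC-vs-L/B_m samples are constant to
  within measurement noise (dominated by the finite background-ROI area),
  and the r² of any fit through them is a noise statistic rather than a
  fit-quality one — the acceptance suite reports this honestly, with the
  minimum per-curve r² driven to ≈0 by the 23–37 mm curves while the 10–13
  mm curves, where partial volume makes recovery genuinely
  contrast-dependent, fit well. Physical measurements on clinical scanners
  show strong contrast dependence at *all* sphere sizes (large-sphere
  underestimation varying tens of percent across contrast), which
  implicates reconstruction nonlinearity — explicitly outside this
  simulator's scope. Consequence: on simulated data the surface is flat in
  the L/B_m direction for d ≳ 20 mm, which is also why the correction
  there is insensitive to the exact curve shape.
- **Small-diameter steepness.** RC changes by ~0.2 between the 10 and
  13 mm curves while their measured diameters differ by barely 1 mm; in
  that regime the lookup is ill-conditioned and the residual error of
  corrected 12–13 mm lesions is dominated by sub-voxel sampling phase
  (several percent even noiselessly). This matches the method's intrinsic
  behavior: sub-centimeter lesions are corrected to a recovered *fraction*
  of activity, not to high accuracy.
- **2-D measurement.** The max-slice circle-equivalent construction uses a
  single plane; axially elongated lesions are summarized by one
  cross-section.
- **Background uniformity.** The background model is uniform; adjacent hot
  organs are handled only by the ROI-placement error path, not modeled.
- **EORTC CMR rule.** The background-equivalence SUV for complete response
  is a pragmatic configurable default, not a standardized value.
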