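# Methods

`hippoprof` quantifies hippocampal sclerosis imaging markers — atrophy and
T2 prolongation — *locally* along the hippocampal long axis, instead of as
one volume and one qT2 number per hippocampus. This note records the model,
the defaults, and the design decisions, in enough detail to reimplement or
audit the package.

## Measurement model

**Inputs per subject.** A 3-D T1-weighted volume (1 mm isotropic), binary
or probabilistic hippocampal segmentations (one per side), a coronal
dual-echo PD/T2 pair (0.43 × 0.43 mm in-plane, 4-mm slices, TE = 30/119 ms),
and the total intracranial volume (TIV). All volumes are handled in a RAS+
world frame in mm; the anterior-posterior (AP) profiling axis is world +y.
Files in other on-disk orientations are reoriented to the closest RAS+
canonical form on load.

**qT2.** The dual-echo sequence samples S(TE) = S0·exp(−TE/T2) twice, so

    qT2 = (TE2 − TE1) / ln(S(TE1) / S(TE2))   [ms].

Voxels with non-positive or non-decaying signal, or qT2 above a 1000-ms
ceiling (CSF-dominated), are marked invalid with an explicit reason and
never clamped. Hippocampal summaries exclude partial-volume voxels: the
segmentation is linearly resampled onto the dual-echo grid and only voxels
with mask fraction ≥ 0.99 are kept (one-voxel interior erosion as fallback
when fewer than 10 voxels survive). The 0.99 rule is this package's
deterministic reading of "exclude partial-volume voxels"; the ceiling and
the two-point (not multi-echo) estimator are deliberate scope choices.

**Alignment.** A profiling frame is defined by a group template whose
hippocampi lie along +y:

1. each subject is reoriented by the minimal rotation taking the mean of
   the two per-side principal axes (PCA of in-mask world coordinates) onto
   +y, pivoted at the joint mask centroid;
2. a template is built by iterated registration of all control T1s to the
   evolving mean image (default 10 affine iterations, matching the
   method's published iteration count; test-scale runs use fewer);
3. every subject is registered to the template — rigid, then full affine —
   with the similarity (normalized cross-correlation) evaluated only
   outside the template hippocampi plus inside a dilated brain mask
   (cost-function masking), so hippocampal pathology cannot bias the
   alignment. A nonlinear refinement is a pluggable callable
   (two volumes + cost mask → transform); the default pipeline is
   affine-only, which suffices at phantom scale. Rigid/affine optimisation
   is delegated to SimpleITK with full (non-sampled) metric evaluation and
   a fixed multi-resolution schedule, so registration is deterministic.

The template carries an AP **distance map**: coronal slice k (1-based from
the most posterior slice) holds k × slice-spacing mm; a 218-slice 1-mm
template reads 1…218 mm. The inverse subject transform propagates this map
into subject space; averaging it over each coronal slice of the
segmentation maps every subject slice to a template AP position.

**CSA profiles.** Per-slice cross-sectional area = (fractional in-mask
sum) × in-plane voxel area. Masks are resampled for this through the
*rigid part* (polar decomposition) of the subject→template transform, so
slices cut the hippocampus perpendicular to its long axis and areas are
never scaled by the affine; AP positions come from the distance map through
the residual affine. CSA is TIV-corrected by ratio scaling,
value × (TIV_ref / TIV) with TIV_ref the control-cohort mean, applied
identically to slice areas and volumes so profiles integrate exactly to
corrected volumes (an alternative residual-regression correction was
considered and rejected for opacity; the ratio rule is the simplest
reading of "corrected for TIV"). Profiles are linearly interpolated to a
uniform 1-mm grid. qT2 profiles stay discrete: one point per 4-mm slice
with ≥ 5 valid voxels (fewer → the point is missing, never zero).

**Normative model.** At 1-mm steps the control cohort's local mean μ(x)
and SD σ(x) are estimated with a Gaussian kernel (bandwidth 2 mm,
peak-1 weights; n_eff = summed weights, minimum support 10 before a grid
point enters the model). Two refinements matter:

* dispersion is estimated from *cross-subject* residuals (per-position
  sample moments for lattice-aligned continuous profiles; residuals about
  the local fit for scattered discrete qT2 points), so the mean's AP trend
  is never mixed into σ — identical subjects give σ ≡ 0 exactly, and as
  bandwidth → 0 the estimator degenerates to per-position sample mean/SD;
* the smoothed mean uses **local-linear** (not Nadaraya–Watson) weights.
  The plain kernel mean is biased at the profile tips, where a one-sided
  window drags μ up the taper slope; that bias systematically flagged a
  perfectly average subject at the tips. The first-order fit removes it.

The normal range is μ ± 1.96σ. Individual comparison is one-sided per the
clinical signs: a point is atrophic when CSA < μ − 1.96σ and T2-elevated
when qT2 > μ + 1.96σ (qT2 compared at its own slice positions against the
interpolated model). Whole-hippocampus flags compare the scalar against
the control mean ± 1.96 SD in the same one-sided way.

**Regions.** The hippocampal body is the maximal contiguous run of grid
points where |dμ/dx| < 2 mm²/mm (central differences; one-sided at the
ends); tail is posterior of it, head anterior; equal-length runs tie-break
to the more posterior one. A run spanning the whole extent is flagged
degenerate (flat profile; zero-length tail/head allowed only there).
Region volumes sum CSA over the region; regional qT2 averages slice values
weighted by the segmentation volume per slice, each slice assigned to the
region containing its mean distance.

**Group statistics.** Pointwise comparison uses Welch's two-sample t-test
(robust default; the equal-variance test is available) at every 1-mm
point, two-sided, Bonferroni-corrected by the number of points actually
tested; regional metrics are tested at α/3 for the three regions.
Scan–rescan variability applies the same kernel machinery to per-point
differences of repeated scans; for iid per-point noise of SD s the
estimate converges to s·√2. Per-point percent-abnormal maps divide the
flagged count by the count of individuals with data at that point.

## The phantom

The synthetic subject emulates the acquisition the pipeline targets, with
every quantity known exactly:

* each hippocampus is a curved tube whose per-slice CSA follows a
  parametric profile — linear tail taper (8 mm), near-flat body
  (15 mm, drift 0.5 mm² ≪ the 2 mm²/mm rule), raised-cosine head bulge
  then taper (24 mm); defaults integrate to ≈ 2.7 mL, inside the
  healthy-control whole-volume band (2.40–3.39 mL) used for calibration.
  The centreline is a mild circular arc (sagitta 6 mm) in the sagittal
  plane so alignment has real work to do; the pair is mirrored about the
  midline at ±14 mm;
* masks are rasterised with 4× in-plane supersampling into fractional
  values (binary view thresholds at 0.5). Pure voxel-centre counting
  aliases per-slice areas by several mm² depending on lattice phase;
  the fractional sums stay within a fraction of a mm² of the analytic
  cross-section, and double as a stand-in for probabilistic multi-atlas
  segmentations. Per-slice truth = fractional sum × in-plane area of the
  *unposed* rasterisation;
* dual-echo signals are mono-exponential with tissue T2 116 ms (mid of
  the control band 108.5–123.8 ms), white-matter-like background 80 ms,
  S0 = 1000, additive Gaussian noise (SD 10 ≈ SNR 77 at TE1) — a
  deliberate simplification of Rician noise, adequate at this SNR;
* the T1-like volume is a textured brain ellipsoid with darker
  hippocampi; the texture is fixed across subjects so registration has
  common landmarks;
* cohorts draw multiplicative CSA scale (SD 0.05), additive tissue-T2
  offsets (SD 3 ms), TIV (1500 ± 120 mL), and uniform rigid poses
  (≤ 12°, ≤ 5 mm); focal lesions remove a fraction of CSA and/or add a
  qT2 offset over a short AP band, with the band retained as ground
  truth. One integer seed makes a subject or cohort bit-reproducible.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: whole-brain anatomy and true nonlinear
inter-subject shape variation (the affine-only default is exercised only
at phantom scale); Rician noise and B1/stimulated-echo effects;
partial-volume mixtures beyond edge voxels; CSF layers inside the
hippocampal folds; correlation between TIV and hippocampal size (drawn
independently here, so TIV correction adds variance rather than removing
it); segmentation errors (masks are ground truth by construction).

## Numerical choices and degenerate inputs

* Mask binarisation threshold is 0.5 after any resampling; resampling
  uses linear interpolation for scalar maps and fractional masks, nearest
  for labels; out-of-field fill is 0 for masks and NaN for qT2/distance
  maps so averages ignore them.
* "At least half" in majority voting is inclusive (a voxel in exactly
  N/2 of N segmentations is included).
* Slice-to-position tables weight voxels by mask fraction; non-monotone
  mean distances warn at table construction and error at profiling.
* The principal axis requires a first/second eigenvalue ratio ≥ 1.2;
  left/right axes disagreeing by > 45° abort reorientation.
* Profile tips (within ~5 mm of the support ends, where CSA tapers to a
  few mm²) are intrinsically unstable: sub-voxel alignment differences
  move relative CSA by tens of percent. Validation therefore asserts
  pointwise agreement on interior points (≥ 5 mm inside the support);
  tip behaviour is reported but not certified.
* Registration quality below an NCC threshold (−0.2) raises rather than
  returning a silently bad transform; template iteration stops early with
  a warning if the mean similarity worsens twice in a row.

## Problem sizes used in validation

Test- and acceptance-scale runs use the generator defaults for geometry
and noise but modest cohorts: 4–20 phantom subjects for image-level
pipelines, 111 profile-level simulated controls for normative
calibration (matching the normative cohort size the method was built
around), 10 seeded replicates for lesion localisation, 1000 replicates
for the null calibration of the pointwise tests, and 20 pairs for
scan–rescan. Template construction in tests runs 1–2 affine iterations
(the default remains 10); registration uses the same optimizer settings
throughout.

## Known limitations

Affine-only default registration; additive Gaussian noise; the 0.99
partial-volume rule and the ratio TIV correction are this package's
explicit choices where the method's published description defers to
earlier work; the kernel bandwidth (2 mm) and the Gaussian kernel itself
are defaults, configurable per call. The online deployment of the
original method (web service, real MNI-152 template path) is out of
scope; the template path runs on any AP-aligned template volume the user
supplies.
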