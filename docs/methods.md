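# Methods

## Problem and scope

`petgtv` analyzes gross-tumor-volume (GTV) delineation on PET/CT. Three
delineation routes are compared: manual contouring on CT, manual
contouring on fused FDG-PET/CT, and automatic PET segmentation by
signal-to-background-ratio (SBR) adaptive thresholding. The package
computes the geometric agreement between the resulting structures
(composite/common volumes, overlap fractions) and the inter- and
intra-observer variability of manual contouring. Because the clinical
cohort it models deposited no images, all image-level computation is
exercised on synthetic phantoms with known ground truth; the published
per-patient cohort tables are bundled so the study's summary statistics
can be recomputed exactly.

## Data model

Images are 3D scalar grids (`VoxelGrid`) with axis order (x, y, z), z
indexing transversal (axial) slices, 0-based voxel indices, and world
coordinates in mm at voxel centers — the NIfTI convention. Structures
are boolean masks (`BinaryMask`) on exactly the geometry of their
reference grid. Masks with mismatched geometry are rejected, never
resampled: silent resampling corrupts overlap statistics, and
resampling is deliberately outside this package's scope. Volumes are
(number of set voxels) × voxel volume, reported in cm³; full precision
is kept internally and rounding (half-even, 2 decimals) happens only at
display.

A `StructureSet` keys masks by (patient, modality ∈ {CT, PETCT, SBR},
observer, session ∈ {1, 2}), mirroring a two-session multi-observer
delineation design. It persists as NIfTI mask files plus a JSON
sidecar.

## SBR adaptive thresholding

The lesion *signal* S is the mean activity of the hottest voxel and its
eight in-plane neighbours (3×3 patch in the transversal slice); the
*background* B is the mean over a user-supplied ROI far from the
lesion. The threshold is

    q(SBR) = a + b / SBR,   SBR = S / B
    T = q·S                       (fraction_of_signal mode)
    T = B + q·(S − B)             (background_subtracted mode)

with defaults a = 0.30, b = 0.70 in fraction_of_signal mode. The
inverse-linear form is the standard published calibration family for
SBR thresholding; the coefficients are scanner- and
reconstruction-specific, so they are configuration, not constants.
`q` must lie in (0, 1) and SBR must exceed 1; violations raise at call
time. The GTV is the connected component (26-connectivity by default,
6/18 available) of the supra-threshold set containing the hottest
voxel, flagged `needs_visual_check` since clinical practice reviews
auto-contours before approval.

Deterministic details: ties for the hottest voxel break to the
lexicographically smallest (x, y, z) index. A hottest voxel on an
in-plane border is a hard error rather than a partial-neighbourhood
mean, which would silently bias S. The segmentation is invariant under
multiplying the grid by a positive constant (SBR, q are ratios; T
scales with S), so activity vs SUV units do not change the mask.

SUV conversion uses body-weight normalization, SUV = activity [kBq/mL]
× weight [kg] / dose [MBq] (density 1 g/mL); decay correction is
assumed done by the scanner.

## Overlap and observer-agreement statistics

For CT vs PET/CT GTVs of one observer: composite = union, common =
intersection. "Composite … is the sum" in the source study is
interpreted as set union, not arithmetic addition — its printed
composite values are far below the arithmetic sums and its text calls
the intersection the "joint volume". Overlap fractions divide the
intersection by a designated reference: OF_CT by the CT GTV, OF_PET/CT
by the PET/CT GTV, OF_SBR (of PET/CT vs SBR) by the SBR GTV. An empty
reference raises an explicit error.

The study the package models does not define its agreement indices, so
standard delineation-study conventions are adopted and documented as
configuration points:

* **Reliability (conformity) index** over K observers:
  vol(∩)/vol(∪) — the generalized conformity index, the strictest
  multi-observer overlap (never above any pairwise Jaccard). The
  alternative mean-pairwise-Jaccard convention is provided as
  `pairwise_jaccard_mean`.
* **Intra-observer concordance**: Jaccard index of one observer's two
  sessions.
* **Inter-/intra-observer variance decomposition**: two-way
  fixed-effects ANOVA of log volume on patient and observer, sessions
  pooled as replicates, so with two sessions per cell the residual mean
  square estimates the intra-observer variance. Volumes are positive
  with multiplicative error, hence the log transform. Zero total
  variance and incomplete crossed designs are errors, not silent F = 0.
* **Modality comparison**: both the paired t-test and the exact
  Wilcoxon signed-rank on per-patient volumes are reported, neither
  privileged — at n = 10 and an unnamed test in the source text there
  is no basis to choose.

## Synthetic phantoms

`make_phantom` digitizes a star-shaped lesion (sphere, ellipsoid, or
lobulated ellipsoid whose directional radius is modulated by a smooth
random angular field) at voxel centers, assigns two activity levels
(default lesion 8, background 1 kBq/mL — SBR 8, a typical FDG-avid
pelvic recurrence on quiet soft tissue), convolves with an isotropic
Gaussian PSF (default FWHM 6 mm, whole-body PET resolution) and applies
scaled-Poisson noise: `noise_scale × Poisson(mean / noise_scale)`,
variance proportional to the local mean. This is a post-reconstruction
approximation; no sinogram simulation is attempted. The CT channel is a
two-level HU image (40/55) for display and fusion plumbing only.

Default grid: 48³ voxels at 2 mm isotropic — desk scale while keeping
≥ 8 voxels across a typical lesion radius.

## Observer simulation

`simulate_observers` perturbs the truth boundary radially about its
centroid: observer o, session s gets displacement field

    d(u) = bias + σ_inter·f_o(u) + σ_intra·f_os(u)

where u is a unit direction and each f is a smooth unit-RMS random
field on the sphere (a sum of 12 von-Mises–Fisher-shaped bumps at
random poles; the concentration is 1/smoothness², smoothness defaulting
to 0.7 rad). A voxel at radius r along u is inside the perturbed
structure iff r ≤ r_truth(u) + d(u), implemented by sampling the truth
mask at the pulled-back radius r − d(u) with trilinear interpolation
and a 0.5 cut (the trilinear cut roughly halves the half-voxel
digitization bias of nearest-neighbour sampling). The perturbed radius
is clipped to ≥ 1 voxel so structures never vanish; displacements are
evaluated only on the truth bounding box padded by the maximum
displacement (|bias| + 4σ, to which the field is also clipped).

Defaults σ_inter = 2 mm, σ_intra = 1 mm give conformity indices in the
0.3–0.6 range observed in pelvic delineation studies. The pipeline uses
larger noise and a +1 mm bias for CT than for PET/CT, emulating the
better agreement and smaller volumes reported on fused images.

What the simulator does **not** model: real anatomical boundaries,
modality-specific visual ambiguity (bladder/vessel uptake), observer
drift over time, or non-star-shaped lesions. Passing parameter-recovery
tests therefore shows the *statistics* respond correctly to known
agreement levels, not that the noise magnitudes themselves are
clinically calibrated.

## Bundled cohort tables

The per-patient GTV volumes (five columns) and overlap columns of the
source study's two tables ship as CSV fixtures. Recomputing their
column means reproduces the study text exactly at printed precision:
mean GTV_CT1 43.65, GTV_PET/CT1 33.06, GTV_SBR 21.33 cm³; mean OF_CT1
0.63, OF_PET/CT1 0.90 (90.4% of the PET/CT GTV inside the CT GTV),
OF_SBR 0.97; paired t on CT1 vs PET/CT1 p ≈ 0.017. Three printed
inconsistencies are preserved and flagged rather than matched: two rows
print common > composite (impossible under set algebra), the printed
cohort composite/common means do not equal their column means, and the
printed SD of the SBR column (23.87) is not the sample SD of its values
(22.87). `reproduce_study()` reports the recomputed numbers and lists
these flags.

## Numerical and testing choices

* Geometry equality tolerance: 1e-6 mm on spacing and origin.
* Supra-threshold set uses ≥ T; thresholds are strictly inside the
  activity range on valid inputs, so the choice of ≥ vs > only moves
  measure-zero boundary cases.
* The blurred-sphere validation compares segmented volume against an
  independent oracle: the closed-form radial profile of a uniform ball
  convolved with an isotropic Gaussian, thresholded by root-finding.
  Voxel spacing in that test is radius-adaptive (1 mm below 15 mm
  radius, 1.5 mm above) so that raster digitization — up to ~6% volume
  error for an 8 mm sphere at 2 mm voxels — stays subordinate to the
  5% accuracy being verified, which concerns the threshold method, not
  the raster.
* ANOVA calibration is checked by simulation: 500 null datasets (10
  patients × 4 observers × 2 sessions, i.i.d. lognormal) give an
  observer-effect rejection rate of 0.054 at α = 0.05.
* All generators are pure functions of (spec, seed); the pipeline
  writes CSV with fixed float formatting and sorted JSON keys, so equal
  seeds give byte-identical reports.

## Known limitations

* The threshold coefficients (a, b) ship as literature-typical defaults,
  not a phantom calibration for any particular scanner; calibration
  fitting is out of scope.
* Overlap analysis requires identical geometry; cross-modality
  registration/resampling must happen upstream.
* Partial-volume correction, multi-lesion segmentation, surface-distance
  metrics (Hausdorff), kappa statistics and STAPLE consensus are out of
  scope.
* The observer model's reliability indices are in plausible clinical
  ranges but are not fitted to the source cohort, whose contours are
  unavailable.
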