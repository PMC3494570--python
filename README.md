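# petgtv

Analysis toolkit for PET/CT gross-tumor-volume (GTV) delineation:
signal-to-background-ratio (SBR) adaptive-threshold auto-segmentation of
FDG-PET lesions, overlap analysis between CT-, PET/CT- and SBR-derived
GTVs, and inter-/intra-observer variability statistics. It is aimed at
radiotherapy-physics and quantitative-imaging groups who compare
delineation techniques — the setting where several radiation
oncologists contour the same lesions on CT and on fused PET/CT, twice,
and an automatic PET contour is evaluated against them.

Because delineation cohorts rarely publish their images, the package
includes a synthetic PET/CT phantom generator and a multi-observer
contour simulator with known ground truth, plus the per-patient cohort
tables of a published 10-patient gynaecologic-cancer delineation study
so its summary statistics can be recomputed exactly.

## The method

**SBR segmentation.** The lesion signal S is the mean activity of the
hottest voxel and its eight in-plane neighbours (3×3 patch in the
transversal slice); the background B is the mean of a manually drawn
ROI far from the lesion. The threshold fraction follows the standard
inverse-linear calibration

q(SBR) = a + b/SBR,  SBR = S/B,  T = q·S

with configurable coefficients (defaults a = 0.30, b = 0.70). The GTV
is the 26-connected supra-threshold component containing the hottest
voxel.

**Agreement statistics.** For structures A₁…A_K delineated by K
observers: composite = ⋃Aᵢ, common = ⋂Aᵢ, reliability (conformity)
index = |⋂Aᵢ| / |⋃Aᵢ|; intra-observer concordance is the Jaccard index
of one observer's two sessions; overlap fractions OF = |A ∩ R| / |R|
against a designated reference R. Volume variance decomposes by two-way
fixed-effects ANOVA of log volume on patient and observer; modalities
are compared by paired t and exact Wilcoxon signed-rank tests.

## Worked example

Segment a noisy blurred 15 mm-radius lesion phantom (SBR 8, PSF FWHM
6 mm, 2 mm voxels):

```python
import json
import numpy as np
from petgtv import (PhantomSpec, ThresholdModel, BackgroundROI, BinaryMask,
                    make_phantom, segment_sbr, volume)

spec = PhantomSpec(lesion_radii_mm=(15.0, 15.0, 15.0), psf_fwhm_mm=6.0,
                   noise_scale=0.05, seed=7)
pet, ct, truth = make_phantom(spec)

bg = np.zeros(pet.shape, dtype=bool)           # background ROI, far corner
bg[1:5, 1:5, 1:5] = True
roi = BackgroundROI(BinaryMask(bg, pet.spacing))
search = np.zeros(pet.shape, dtype=bool)       # search box around the lesion
search[14:34, 14:34, 14:34] = True

result = segment_sbr(pet, ThresholdModel(a=0.30, b=0.70), roi,
                     BinaryMask(search, pet.spacing))
print(json.dumps(result.report(), indent=2))
print("truth volume:", round(volume(truth), 2), "cm3")
```

Output:

```
{
  "signal": 8.416666666666666,
  "background": 1.0078125000000002,
  "sbr": 8.35142118863049,
  "threshold": 3.2304687499999996,
  "volume_cm3": 16.224,
  "hottest_voxel": [25, 25, 26],
  "needs_visual_check": true
}
truth volume: 13.89 cm3
```

The estimated SBR of 8.35 sets the threshold at q = 0.30 + 0.70/8.35 ≈
38% of the signal, i.e. T ≈ 3.23 kBq/mL. The auto-contour (16.2 cm³)
overshoots the 13.9 cm³ ground truth because the 6 mm PSF smears
activity outward — exactly the partial-volume behaviour the adaptive
threshold family is calibrated against on real scanners;
`needs_visual_check` reminds the user that clinical auto-contours are
reviewed before approval.

The same analysis end-to-end on a simulated 10-patient cohort (4
observers × 2 sessions on CT and PET/CT, plus the SBR auto-contour):

```bash
petgtv pipeline --seed 1 --out run/
petgtv reproduce-study          # summary stats of the bundled cohort tables
```

`run/` then contains per-patient NIfTI images and masks,
`volumes_by_patient.csv`, `overlap_by_patient.csv` and `report.json`
with conformity indices, ANOVA F/p values and paired modality tests.

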