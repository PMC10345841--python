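# Methods

## Problem setting

Cross-sectional areas of muscle and fat measured on a single axial CT slice
at the third lumbar vertebra (L3) correlate strongly with whole-body
compartment masses, which makes opportunistic CT a practical surrogate for
DXA in body-composition assessment.  `bodycomp` implements the three
stages of such an analysis — tissue segmentation, per-tissue metrics, and
linear mass estimation — together with the agreement statistics used to
validate CT-based estimates against a DXA reference, and a synthetic data
generator that makes every stage testable end to end.

## Segmentation model

Pixels are classified by Hounsfield-unit windows applied inside spatial
compartments.  The windows are the standard body-composition thresholds,
inclusive at both ends:

| tissue | window (HU) |
|---|---|
| skeletal muscle | −29 .. 150 |
| subcutaneous adipose tissue (SAT) | −190 .. −30 |
| visceral adipose tissue (VAT) | −150 .. −50 |
| intramuscular adipose tissue (IMAT) | SAT window, inside the muscle band |

The SAT window contains the VAT window, so compartment membership decides
first and the HU window second.  Compartments are derived morphologically
from the image alone:

1. the **body** is the largest 8-connected component above −500 HU,
   hole-filled;
2. the **subcutaneous fat** is the union of SAT-window components touching
   the body surface;
3. the **muscle band** is the union of muscle-window components adjacent
   to the subcutaneous fat or the body surface; the single largest region
   the band encloses is the **visceral cavity**, while small enclosed
   holes (intramuscular fat) are annexed to the band;
4. the **subcutaneous zone** is the body outside the filled band.

The three compartments partition the body exactly; the −500 HU body
threshold and the 3×3 structuring element are fixed constants, overridable
in code.  IMAT has no dedicated HU window in the body-composition
literature; it is defined here as fat-range (SAT-window) signal inside the
muscle band.  This derivation stands in for the interactive/AI labelling
used by commercial body-composition software, which is out of scope; it
assumes a closed abdominal-wall muscle ring and a fat lining on its deep
surface, both true of the phantom and approximately true of real L3
anatomy, but it is not a clinically validated segmenter.

## Tissue metrics

For each slice: area(tissue) = pixel count × pixel area (mm² → cm²);
percentages are relative to the body-ROI area; indices divide areas by
height² (cm²/m², as in the skeletal muscle index SMI = SMA/h²); mean HU is
averaged per tissue, with an explicit "undefined" flag (not NaN) for empty
tissues.  FAT% — the fat predictor of the density-weighted model — counts
all three fat compartments: FAT% = (SFA + VFA + IMAT)/body area × 100.
Whether IMAT belongs in that numerator is a modelling choice (it is a
small term, ~1–2 % of the body area at defaults); including it keeps the
fat percentages additive with the tissue partition.

Aggregation over a slice stack (e.g. the 16 contiguous slices a scanner
yields around L3) averages areas and percentages across slices and
pixel-count-weights mean HU, so the aggregate mean HU equals the value
computed on the pooled pixel set.  Sums use compensated (`math.fsum`)
arithmetic so that aggregating identical slices reproduces the single-slice
values bit-for-bit — the single-slice vs multi-slice comparison is then
purely about anatomical variation, never float noise.

## Mass-estimation models

All three estimators are affine maps fit by ordinary least squares.

* **Model 1** (area form, clinical standard): FM = 0.042·fat_area + 11.2;
  FFM = 0.3·muscle_area + 6.06 (areas in cm² at L3, masses in kg).
* **Model 2**: same form refit on a mixed-BMI cohort: FM = 0.058·fat_area
  + 7.35; FFM = 0.27·muscle_area + 13.31.
* **Density-weighted model**: tissue density is approximated linearly from
  radiodensity, ρ ≈ HU/1000 + 1 (water = 0 HU → 1; fat ≈ −100 HU → 0.9).
  Body volume is extrapolated as V_total = weight/ρ_ROI from the whole-ROI
  mean HU, the fat volume as V_fat = V_total·FAT%/100, and the fat mass as
  M_fat = V_fat·ρ_FAT; the calibrated estimator is
  FM = 0.0069·(weight/ρ_ROI)·FAT%·ρ_FAT + 4.53, and FFM = weight − FM,
  which conserves mass by construction.  The density unit label "kg/cm³"
  follows the source convention of the printed equations (the magnitude is
  that of g/cm³); the slope absorbs the unit scale, so the formula is
  implemented exactly as printed.  ρ_FAT defaults to the pooled mean HU of
  all fat compartments (SAT + VAT + IMAT); a SAT-only variant is a
  one-line change via the `fat_mean_hu` argument.

`fit_linear` is plain OLS with an intercept (no weighting or robustness),
requiring ≥3 points and non-degenerate predictor variance; refitting never
silently replaces the printed defaults.  The Cohen sample-size helper
implements N = z²·s²/d² as printed, plus the ceiling-rounded value and a
variability inflation helper (e.g. 51 × 1.35 = 68.85); no unit conversion
between s and d is attempted, because none is defined for mixed-unit
inputs — users must pass s and d on the same scale.

## Agreement statistics

Differences are always estimate − reference (model − DXA), so negative
bias means underestimation.  Pearson r uses the Fisher z-transform CI at
95 %.  Bland-Altman limits of agreement are bias ± 1.96·SD of the
differences (SD with n−1).  The simplified error grid bins per-subject
relative errors |est − ref|/ref into contiguous bands <10 %, 10–25 %,
≥25 % (band edges configurable).  The QQ check pairs ordered sample
quantiles with standard-normal quantiles at plotting positions (i−0.5)/n
and reports the fitted QQ line.  The summary grid has one row per
model × {FM, FFM} × slice mode; Pearson r is omitted (NaN) for the
density-weighted model's FFM by default because that FFM is derived as
weight − FM rather than estimated directly — its correlation would merely
mirror the FM row.

## Synthetic data generator

The **phantom** emulates an L3 cross-section as concentric ellipses: body
(default 34 × 24 cm), a subcutaneous fat ring (30 mm), an abdominal-wall
muscle band (15 mm), and a visceral cavity containing a vertebral-body
bone placeholder, soft-tissue "organs", and visceral fat that lines the
deep surface of the wall (as retro-/intraperitoneal fat does; 4.5 mm
default) plus smoothed-noise blobs up to a target cavity fraction (0.35).
IMAT appears as random speckles strictly interior to the muscle band.  HU
values are truncated normals (± 3 SD) per tissue — muscle 40 ± 5, SAT
−100 ± 5, VAT −90 ± 5, organs 30 ± 10, bone 400 ± 40, air background
−1000 — so every tissue's HU support lies strictly inside its threshold
window and segmentation recovery is exact by construction.  Real L3
anatomy has open muscle gaps, bowel gas, partial-volume mixing at tissue
boundaries and scanner noise texture, none of which the phantom models;
passing the phantom oracle therefore demonstrates correctness of the
compartment/threshold logic, not clinical segmentation accuracy.  Default
grid 256² at 1.5 mm spacing; one global integer seed drives all sampling.

The **cohort** generator draws subjects uniformly: weight 55–145 kg,
height 1.50–1.90 m, FAT% 18–55, fat mean HU −105..−85, L3 body area
350–900 cm²; the whole-ROI mean HU interpolates linearly between lean soft
tissue (30 HU) and fat at the subject's FAT%, with 5 HU Gaussian scatter.
Reference masses follow the density-weighted form FM = m·(weight/ρ_ROI)·
FAT%·ρ_FAT + n + ε with m = 0.0069, n = 4.53 and ε ~ N(0, 3 kg) by
default (an area-form generator is available for exercising Models 1/2),
and FFM = weight − FM.  These ranges emulate a 70-subject mixed cohort
spanning normal BMI through severe obesity; intra-tissue HU variability in
real cohorts is not documented, so those SDs are plausible placeholders,
not calibrated values.  Because the references are generated from the
density-weighted form with the CT areas drawn independently of the masses,
the area-based models show poor agreement on these cohorts by
construction — the synthetic validation exercises the statistical
machinery, it does not adjudicate between the models on real data.

## Numerical choices

* Threshold windows are closed intervals at both ends; the muscle and SAT
  windows are disjoint (gap at (−30, −29)), so a pixel between them is
  "other".
* Mass conservation FM + FFM = weight holds exactly as written; note
  `(w − fm) + fm` may differ from `w` by one ulp in floats.
* OLS is solved by `numpy.linalg.lstsq`; tests verify it against the
  closed-form normal equations to 1e-9.
* Degenerate inputs fail loudly: all-air images, empty body masks, zero
  predictor variance, fewer than 3 points, nonphysical ρ_ROI ≤ 0, inverted
  HU windows or parameter ranges.
* Bodies touching the image edge are flagged `truncated` with a warning
  rather than rejected.

## Problem sizes

The bundled tests run the phantom at 128² pixels (2 mm spacing) and
cohorts of 20–70 subjects; parameter-recovery checks use 500 Monte-Carlo
replicates at n = 70 with 3 kg reference noise.  These sizes make the full
suite run in seconds while leaving every statistical check well-powered.

## Known limitations

* The compartment derivation assumes a closed muscle ring; severely
  discontinuous abdominal walls (hernias, post-surgical defects) would
  leak the cavity into the subcutaneous zone.
* Slice selection around L3 is the caller's responsibility; no vertebral
  level detection is included.
* Only pooled muscle area is reported, not per-muscle-group areas.
* The models are linear by design; non-linear estimators are out of scope.
* DICOM support covers single-frame CT with rescale tags; enhanced
  multi-frame CT and PACS networking are not supported.
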