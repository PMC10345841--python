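# bodycomp

Body-composition analysis from abdominal CT at the third lumbar vertebra
(L3), for researchers and clinicians who want whole-body fat mass (FM) and
fat-free mass (FFM) estimates — e.g. for sarcopenic-obesity assessment —
without a dedicated DXA scan.

The package implements the full chain:

1. **Segmentation** of an L3 slice into skeletal muscle, subcutaneous
   adipose tissue (SAT), visceral adipose tissue (VAT) and intramuscular
   adipose tissue (IMAT) using the standard Hounsfield-unit windows
   (muscle −29..150 HU, SAT −190..−30 HU, VAT −150..−50 HU) combined with
   morphologically derived spatial compartments (the SAT and VAT windows
   overlap, so HU alone cannot separate them).
2. **Tissue metrics**: areas (cm²), area percentages, height-normalized
   indices (SMI = SMA/height², etc.), per-tissue and whole-ROI mean HU,
   per slice or aggregated over a slice stack.
3. **Mass estimation** with three linear models:
   * Model 1 (area-based, the Mourtzakis form used in clinical practice):
     FM = 0.042·FM_CT_L3 + 11.2, FFM = 0.3·Muscle_CT_L3 + 6.06;
   * Model 2 (the same form refit on a mixed-BMI cohort):
     FM = 0.058·FM_CT_L3 + 7.35, FFM = 0.27·Muscle_CT_L3 + 13.31;
   * a **density-weighted model** that converts mean HU to tissue density
     via ρ ≈ HU/1000 + 1, extrapolates body volume as V = weight/ρ_ROI and
     estimates FM = 0.0069·(weight/ρ_ROI)·FAT%·ρ_FAT + 4.53, with
     FFM = weight − FM by construction.
4. **Agreement statistics** against a DXA reference: Pearson r with a
   Fisher-z CI, Bland-Altman bias and 95% limits of agreement, a
   simplified error grid (<10%, 10–25%, ≥25% relative error), QQ normality
   data, and a model × mass-type × slice-mode summary grid.
5. A **synthetic phantom/cohort generator** providing ground-truth labelled
   L3 cross-sections and paired DXA-style reference masses, so the entire
   pipeline is testable without clinical data.

## Worked example

```python
import bodycomp as bc

# simulate a ground-truth phantom and segment it blind
spec = bc.PhantomSpec(seed=42)
slices, truth = bc.generate_phantom(spec)
cm  = bc.derive_compartments(slices[0])
seg = bc.segment(slices[0], cm)
tm  = bc.compute_metrics(slices[0], seg, height_m=1.70)
print(tm.sma, tm.smi, tm.sfa, tm.vfa, tm.fat_pct, tm.roi_mean_hu)

# estimate masses for a 100 kg subject from these slice metrics
res = bc.model3_fm(100.0, tm.roi_mean_hu, tm.fat_pct, tm.fat_mean_hu)
print(res.fm_kg, bc.model3_ffm(100.0, res.fm_kg))

# validate all three models against DXA-style references on a synthetic cohort
subjects, ct = bc.generate_cohort(bc.CohortSpec(seed=42))
grid = bc.summarize_table2(subjects, {"1 slice": bc.predict_cohort(subjects, ct)})
print(grid[["model", "mass", "pearson", "loa_low", "bias", "loa_high"]].round(3))
```

Output:

```
SMA     99.0 cm2   SMI  34.27 cm2/m2
SFA    245.3 cm2   VFA  103.1 cm2   IMAT  2.02 cm2
FAT%  54.68     ROI mean HU  -32.06
density-weighted FM = 39.72 kg, FFM = 60.28 kg
    model mass  pearson  loa_low    bias  loa_high
   model1   FM    0.565  -22.914  -6.901     9.112
   model1  FFM   -0.032  -68.568 -16.560    35.449
   model2   FM    0.565  -22.819  -7.076     8.668
   model2  FFM   -0.032  -64.527 -14.424    35.678
focusedon   FM    0.957   -5.224   0.338     5.900
focusedon  FFM      NaN   -5.900  -0.338     5.224
```

Reading the numbers: the phantom's muscle wall measures 99 cm² (SMI 34.3
cm²/m² for a 1.70 m subject); fat occupies 54.7 % of the body cross-section
with a whole-ROI mean of −32 HU, giving a density-weighted FM of 39.7 kg
for a 100 kg subject.  On the synthetic cohort — whose reference masses are
generated from the density-weighted form — that model tracks the reference
tightly (r = 0.96, bias 0.3 kg), while the purely area-based models show
wide limits of agreement; the FFM row of the density-weighted model has no
Pearson r because its FFM is derived as weight − FM rather than estimated
directly, and its biases mirror the FM row with opposite sign.

The same stages are scriptable from the shell:

```bash
bodycomp simulate phantom --out run/ --seed 1
bodycomp segment --in run/phantom_ct.nii.gz --out run/labels.nii.gz
bodycomp metrics --ct run/phantom_ct.nii.gz --mask run/labels.nii.gz \
                 --height 1.70 --out run/metrics.csv
bodycomp simulate cohort --out run/cohort.csv --seed 1
bodycomp estimate --metrics run/cohort_ct.csv --cohort run/cohort.csv \
                  --out run/estimates.csv
bodycomp agree --estimates run/estimates.csv --cohort run/cohort.csv \
               --out run/table2.csv
bodycomp run --config pipeline.yaml     # everything, with a manifest
```

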