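# petrepeat

Lesion-level **test–retest repeatability analysis of PET SUV features**.

When a patient is scanned twice a few days apart with no intervening
therapy, any difference in a lesion's measured uptake is measurement error,
not biology. Quantifying that error — per feature, per lesion size class —
tells you how large a longitudinal change must be before it can be read as
treatment response. `petrepeat` implements this analysis for the four
standard lesion features of PSMA-PET (and FDG-PET) reporting:

* **SUV_max** — maximum standardized uptake value in the lesion ROI
* **SUV_mean** — mean SUV in the ROI
* **volume** — ROI volume in cm³
* **SUV_total** — sum of ROI SUVs × voxel volume (SUV·cm³)

## The statistics

Each matched lesion contributes a log-ratio `r = ln(x_retest / x_test)`.
Because patients carry many lesions and share scan-level conditions, σ is
estimated with a one-way variance decomposition (patients as groups) for
limits of agreement with multiple observations per individual:

```
d̄  = mean(r)
σ² = max(0, (MS_between − MS_within)/m₀) + MS_within
95% LOA = (e^{d̄ ∓ 1.96σ} − 1) × 100 %
```

plus the two-way absolute-agreement ICC(A,1) on raw values, the RMS
within-subject coefficient of variation, volume-threshold stratification
(all lesions, >1 cm³, >1.5 cm³), and log–log Bland–Altman plots with
per-patient coloring. See `docs/methods.md` for the full model, estimator
and design rationale.

Inputs are either paired NIfTI SUV volumes with integer lesion label masks
(lesions are matched across time points by ROI centroids), or a lesion
feature CSV (`patient_id, lesion_id, timepoint, suv_max, suv_mean,
suv_total, volume_cc`). A seeded synthetic cohort generator — matched
feature tables, or voxelized ellipsoid phantoms with segmentation boundary
jitter — provides data with analytically known repeatability for
validation.

## Worked example

```python
import petrepeat as pr

# 22 patients, ~300 matched lesions, patient bias tau=0.09, lesion noise sigma_w=0.09
pairs, truth = pr.generate_paired_features(pr.CohortParams(seed=1))
print(len(pairs))                      # 304
table = pr.repeatability_table(pairs)  # 4 features x 3 volume strata
print(table.round(3).to_string(index=False))
```

```
  feature stratum  n_lesions  bias_pct  loa_lower_pct  loa_upper_pct   icc  wcov_pct
  suv_max     all        304    -0.839        -27.262         35.182 0.957    11.043
 suv_mean     all        304    -0.446        -25.617         33.245 0.966    10.370
suv_total     all        304    -1.381        -38.772         58.846 0.969    16.794
volume_cc     all        304    -0.939        -25.980         32.572 0.985    10.402
  suv_max    >1cc        204    -0.309        -27.240         36.592 0.956    11.204
 suv_mean    >1cc        204    -0.258        -25.862         34.190 0.968    10.534
suv_total    >1cc        204    -1.366        -39.574         61.003 0.967    17.205
volume_cc    >1cc        204    -1.111        -26.439         32.938 0.983    10.544
  suv_max  >1.5cc        173    -0.383        -27.622         37.108 0.955    11.358
 suv_mean  >1.5cc        173    -0.120        -26.104         35.000 0.966    10.692
suv_total  >1.5cc        173    -0.656        -39.715         63.707 0.966    17.498
volume_cc  >1.5cc        173    -0.537        -26.450         34.506 0.982    10.725
```

Reading the first row: across 304 lesions, a retest SUV_max anywhere from
27% below to 35% above the test value is within ordinary measurement
variability (bias is near zero), the ICC of 0.957 says lesions remain
well-ranked between scans, and the within-lesion CV is ~11%. SUV_total is
the least repeatable feature because it compounds uptake noise and
delineation noise multiplicatively.

The same analysis from the shell:

```sh
petrepeat simulate --n-patients 22 --seed 1 --out sim/
petrepeat analyze --table sim/features.csv --out report/
petrepeat run --config config.yaml        # config-driven end-to-end
```

`analyze`/`run` write `repeatability_report.csv`/`.json`, one Bland–Altman
PNG per feature per stratum, a `manifest.json` and a `run.log`. Outputs are
byte-identical across runs with the same seed and config.

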