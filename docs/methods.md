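# Methods

## Problem

Two PET/CT scans of the same patient taken a few days apart, with no
intervening therapy, should report the same lesion-level quantities; the
extent to which they do not is measurement variability, and it bounds how
small a longitudinal change can be interpreted as real. `petrepeat`
quantifies this test–retest repeatability at the lesion level for four
standard uptake features — SUV_max, SUV_mean, SUV_total and lesion volume —
given paired SUV volumes with lesion label masks, or a pre-extracted lesion
feature table.

## Statistical model

For a feature value pair (x_test, x_retest) of lesion *j* in patient *i*, the
analysis works on the natural-log ratio

    r_ij = ln(x_retest / x_ij,test).

SUV-derived quantities are strictly positive and right-skewed, so the ratio
scale is the natural one, and multiplicative errors become additive.

Because each patient contributes many lesions and shares scan-level
conditions (dose, uptake time, calibration, positioning), the r_ij within a
patient are correlated. The spread σ entering the limits of agreement is
estimated by a one-way random-effects (method-of-moments) decomposition with
patients as groups — the standard approach for limits of agreement with
multiple observations per individual whose true values differ:

    d̄          = mean of all r_ij                    (log-scale bias)
    MS_between  = Σ_i m_i (r̄_i − d̄)² / (n − 1)
    MS_within   = Σ_ij (r_ij − r̄_i)² / (N − n)
    m₀          = (N − Σ_i m_i²/N) / (n − 1)
    σ²_between  = max(0, (MS_between − MS_within)/m₀)   (clamped at zero)
    σ           = √(σ²_between + MS_within)

with n patients, N lesions, m_i lesions in patient i. The 95% limits of
agreement are back-transformed to percentages:

    bias = (e^d̄ − 1)·100,   LOA = (e^{d̄ ∓ 1.96σ} − 1)·100.

The multiplier is the fixed normal quantile 1.96, not a t quantile. The
back-transformed bounds are asymmetric (the lower bound can never pass
−100%), which is the correct geometry for ratio data.

Degenerate groupings: with a single patient, or with every patient
contributing exactly one lesion, MS_within has a 0/0 denominator; both cases
are defined to reduce σ to the ordinary sample SD of r, which is the limit
of the estimator as the grouping becomes uninformative.

### ICC

The intraclass correlation is computed on the *raw* (untransformed) feature
values with lesions as subjects and the two scans as k = 2 repeated
measurements, in the two-way absolute-agreement single-measurement form
ICC(A,1):

    ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)).

A one-way ICC(1,1) variant is available (`icc(..., variant="one_way")`).
Both are validated against explicit sums-of-squares oracles and against
pingouin's implementation in the test suite. Raw-value ICC is a deliberate
default: log-scale ICC is available simply by transforming the inputs.

### wCOV

The within-subject coefficient of variation uses the root-mean-square of
per-lesion CVs: per pair, within-pair SD = |x₁ − x₂|/√2 and mean
m = (x₁ + x₂)/2; wCOV = 100·√(mean of (SD/m)²). A pooled alternative
(pooled within-pair SD over grand mean, `method="pooled"`) is provided for
comparison. Note that the per-pair CV responds to *all* within-pair
disagreement, including any patient-level bias: under the generative model
below its population value is 100·√((τ² + 2σ_w²)/2), which reduces to
100·σ_w only when τ = 0.

### Stratification

Repeatability degrades for small lesions, so every metric is recomputed
after excluding lesions at or below 1 cm³ and 1.5 cm³ (strict "greater
than"). A lesion's volume for this purpose is the mean of its test and
retest volumes (config flag `volume_statistic: test` uses the test scan
alone). All four features use the same filtered lesion set per stratum.

## Synthetic cohort generator

No suitable public paired-scan dataset with lesion masks exists, so the
package ships a generator whose estimands are analytically known:

* true lesion volume ~ LogNormal(μ_V = 0.56, s_V = 1.57) on the cm³ scale,
  chosen so ~64% of lesions exceed 1 cm³ and ~54% exceed 1.5 cm³;
* true lesion SUV_mean ~ LogNormal(1.4, 0.6); SUV_max sits above SUV_mean by
  a per-lesion log offset |N(0.35, 0.1²)|;
* a patient-level retest bias b_i ~ N(0, τ²) on the log scale shared by all
  of a patient's lesions (applied to the retest scan only — splitting it
  across scans is equivalent up to sign and less identifiable);
* independent per-lesion, per-feature, per-scan noise N(0, σ_w²) on the log
  scale for SUV_max, SUV_mean and volume; SUV_total is SUV_mean × volume *by
  construction* on both scans, so it inherits two noise terms and the bias
  factor squared — volumetric uptake is noisier than either factor, as
  observed in practice;
* defaults: 22 patients, Poisson(13.5) lesions each (min 1) ≈ 300 lesions,
  τ = 0.09, σ_w = 0.09, which put SUV wCOV near 9% and the limits of
  agreement near −25%/+35%.

The log-ratio of a directly noised feature therefore has SD
σ = √(τ² + 2σ_w²), the quantity the variance estimator must recover; the
parameter-recovery and coverage tests check exactly this. Seeding: one
`numpy` SeedSequence child per patient, spawned in patient order, so
enlarging the cohort appends patients without perturbing existing ones.

### Phantom mode

`generate_phantom_pair` voxelizes one patient's lesions as mildly
anisotropic ellipsoids of uniform plateau SUV on a constant background
(0.2), on a configurable grid (default 64³ voxels at 4 mm isotropic, a
typical whole-body PET sampling). The retest mask flips each boundary voxel
(6-connectivity, per lesion) independently with probability
`jitter_boundary_prob`; since flip counts scale with surface area while
volume scales with r³, relative volume error grows as lesions shrink — the
voxel-quantization "noise floor" that makes small-lesion volumetry fragile.
Placement enforces a minimum center separation (default 30 mm) so lesions
never touch and centroid matching is unambiguous; a bounded number of
placement retries precedes a diagnostic error. An optional Gaussian blur
(`smooth_sigma_mm`) adds partial-volume realism at the cost of the exact
plateau/feature equality that the zero-noise consistency test relies on; it
is off by default.

### What the generator does not emulate

No scanner physics (reconstruction, scatter, attenuation, resolution
recovery), no intensity gradients within lesions, no correlated
inter-feature noise in table mode (feature noises are drawn independently;
phantom mode induces realistic correlation between volume and SUV_total),
no lesion appearance/disappearance between scans, and no organ context for
false-positive segmentations. Passing tests therefore demonstrate the
*statistical machinery* is correct under a faithful error structure, not
that any particular clinical dataset would yield these numbers.

## Lesion matching

Real pipelines match lesions across scans by image registration. Here,
lesions are reduced to unweighted ROI centroids in physical mm (voxel-center
convention: voxel (i,j,k) is centered at ((i+½)dx, (j+½)dy, (k+½)dz)) and
paired by greedy global-nearest-distance one-to-one matching with a maximum
distance (default 10 mm), ties broken by smaller test label then smaller
retest label. An optional pre-supplied 4×4 affine is applied to retest
centroids first (default identity). Greedy matching is chosen over optimal
assignment for transparency; in the well-separated regime the phantoms
enforce, the two coincide. Unmatched lesions are excluded from all
downstream statistics. Split or merged lesions are not modelled; matching is
strictly one-to-one.

## Numerical choices

* Negative between-patient variance estimates are clamped to zero
  (method-of-moments convention).
* Nonpositive or non-finite feature values abort with an error naming the
  patient and lesion; they are never silently dropped.
* Non-finite SUV voxels inside an ROI are an error (corrupt input).
* Strata with fewer than two lesions are skipped with a logged warning.
* ICC is undefined (error) when all lesions have identical values.
* Feature extraction accumulates in float64 in voxel order and matches a
  per-voxel loop bit-for-bit; `suv_total = suv_mean × volume_cc` holds to
  1e−9 relative on every extraction.
* Report JSON is written with sorted keys so fixed-seed runs are
  byte-identical.

## Problem sizes used by the test suite

Monte-Carlo checks use ≈5 000-lesion cohorts (500 patients × 10 lesions for
parameter recovery, averaged over 3 replicates because the patient-level
bias term is estimated from n_patients, not n_lesions; 250 × 20 for coverage
and ICC recovery), 100 random 16³ grids for extraction exactness, and 20–100
phantom seeds for the jitter and matching properties. These sizes put
Monte-Carlo standard errors well inside the asserted tolerances.

## CLI

`petrepeat` exposes `simulate`, `extract`, `match`, `analyze` and `run`
(config-driven end-to-end). Report rendering is part of `analyze`/`run`
(`--plots/--no-plots`); a separate render verb would only re-read what
`analyze` just wrote.

## Known limitations

Patient-level repeatability aggregation, radiomic texture features,
deformable registration, response-classification thresholds and DICOM
ingestion are out of scope. The ICC and wCOV definitional variants (raw vs
log ICC; RMS vs pooled wCOV) genuinely matter at the third decimal; both
alternatives are implemented and flagged so results can be reconciled
against other software.
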