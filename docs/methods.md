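# Methods

This note documents the models implemented in `dosiomics`, the choices made
where the design was genuinely open, and what the synthetic-cohort tests do
and do not establish.

## Problem setting

Radiation pneumonitis (RP, CTCAE grade >= 2) after thoracic radiotherapy is
classically predicted from scalar summaries of the lung dose distribution:
dose-volume factors (V5, V10, V15, V20, mean lung dose), or NTCP model
outputs that compress the whole DVH into one number.  None of these sees the
*spatial arrangement* of dose.  The dosiomics approach treats the 3D dose
grid inside each lung volume like an image and extracts gray-level
co-occurrence (GLCM) and run-length (GLRLM) texture features from it, then
selects predictors by bootstrap logistic regression.  This package
implements the full chain — dose/mask I/O, dosimetric factors, NTCP factors,
texture features, and the bootstrap selection — plus a synthetic cohort
generator that stands in for clinical data.

## Dose and mask handling

- Arrays are `(z, y, x)`; `spacing = (dx, dy, dz)` mm; `origin` is the
  patient-space position of voxel `[0,0,0]` (voxel-centre convention).
- DICOM RT Dose is read by a minimal explicit-VR little-endian parser
  (stored integers x DoseGridScaling; frame offsets must be uniform, else a
  format error).  Masks are NIfTI (axis-aligned affines only).
- Masks must share the dose grid geometry within 1e-3 mm.  Mismatches raise
  an alignment error; nearest-neighbour resampling exists only as an
  explicit opt-in (`resample_mask_nearest`), because texture features are
  sensitive to the sampling grid.
- RT Structure Set contours can be rasterised with an even-odd fill at voxel
  centres, each contour assigned to the nearest grid plane; multiple
  contours on one plane XOR, so holes work.
- Lung masks are used exactly as supplied; whether tumour volumes should be
  subtracted from lungs is a clinical decision left to the caller (a mask is
  just a boolean array, so `left.values & ~ptv.values` does it).

## Dosimetric factors

`V_x` is the percent of ROI volume with dose `>= x` Gy.  The inclusive
comparator is deliberate — `V_0` must be 100% — and a strict `>` is
available per call.  `V_x` is computed by direct voxel counting, never by
DVH interpolation, so the DVH bin width (default 0.1 Gy) has no effect on
reported factors.  MLD is the arithmetic in-mask mean.

## NTCP models

Parameters (lung, RP grade >= 2, fitted elsewhere on 382 thoracic cases) are
shipped in `params/ntcp_params.json` and are user-overridable:

| model | TD50 (Gy) | a or k | m |
|-------|-----------|--------|------|
| Lyman | 30.8 | a = 0.99 | 0.37 |
| parallel/serial | 34.0 | k = 0.06 | 0.90 |

- **Lyman**: `EUD_L = (mean(D_i^a))^(1/a)` (generalised mean), then
  `NTCP_L = Phi((EUD - TD50) / (m TD50))`.  `a <= 0` with a zero voxel dose
  is a domain error; the table's a = 0.99 is safe with zero doses.
- **Parallel/serial (Källman)**: voxel response
  `P(D) = 2^(-exp(e m (1 - D/TD50)))` and
  `NTCP_PS = (1 - prod_i (1 - P(D_i)^k)^(1/N))^(1/k)`.
  The per-voxel exponent is the relative voxel volume `1/N`; the alternative
  reading (exponent `N`) fails the sanity requirement that a uniform dose
  collapse to `NTCP = P(D)`, so it was rejected.  All products run in log
  space with clamping at 1e-300: with k = 0.06 the factors `P^k` sit next to
  1 and a naive product loses precision (the log-space path matches a naive
  evaluation to 1e-10 relative on small inputs, by test).
- **EUD_PS** uses the published closed form
  `TD50 (e m - ln(-ln NTCP)) / (e m - ln(ln 2))`, which is exact at
  NTCP = 0.5 and an approximation elsewhere; it is *not* the analytic
  inverse of the uniform-dose response, and no such claim is made.

## Texture features

- In-mask dose is quantised to `Ng` equal-width bins over the in-mask range
  (default Ng = 64; a fixed bin width in Gy is supported).  The in-mask
  maximum maps to level Ng; a constant ROI is the valid degenerate Ng = 1.
  Fixed bin *count* was chosen as default because per-patient dose ranges
  differ widely and a fixed count keeps matrix sizes comparable.
- GLCM: distance 1, the 13 unique 3D directions, symmetric pairing,
  normalised per direction.  Features are computed per direction and then
  averaged; directions with no valid in-mask pair are dropped from the
  average, not zero-filled.
- GLRLM: maximal same-level runs along the same 13 directions; runs break at
  the mask boundary, and `sum_j j * counts[i,j]` equals the in-mask voxel
  count in every direction (tested invariant).
- 27 GLCM + 16 GLRLM features per volume, computed for ipsilateral,
  contralateral and total lungs: 129 columns named
  `glcm_<Feature>_<ipsi|contra|total>` etc. in a fixed order — the stable
  public contract for model reports.
- Degenerate single-level matrices: Contrast = 0 and Correlation is defined
  as 1 by convention.
- Note that the 27-feature registry contains exact duplicates
  (`Dissimilarity` = `DifferenceAverage`, `Homogeneity1` = `Id`,
  `Homogeneity2` = `Idm`) and near-affine siblings (`Idmn` is numerically an
  affine function of `Contrast` whenever gray-level differences are small
  relative to Ng).  The registry is kept as is for comparability; the
  modelling layer's correlation gate handles the duplicates.
- z-scoring uses the sample (n-1) standard deviation and is computed on the
  **entire cohort before any bootstrap resampling** — faithful to the
  published procedure even though it leaks normalisation statistics across
  the bootstrap; recomputing the transform inside each replicate is possible
  via the stored parameters but is not the default.

## Bootstrap model selection

- A `BootstrapPlan` (default 1,000 replicates, sampling n patients with
  replacement) is drawn once and shared by every feature and pair, so
  rankings compare like with like.  Replicates whose resampled outcome is
  single-class are redrawn with an advanced sub-seed (logistic regression is
  undefined there; redrawing preserves the full replicate count).
- Logistic fits are plain maximum likelihood via Newton/IRLS (tolerance
  1e-8 on the step, max 100 iterations, a 1e-10 ridge for numerical rank
  protection only).  Non-converged (typically separated) replicate fits are
  excluded from coefficient medians/percentiles and counted; a warning fires
  above 10%.  If fewer than 10 replicates converge the summary falls back to
  all replicates rather than aborting a whole run.
- "Training AUC" is the in-bag AUC: the fitted model scored on its own
  bootstrap sample (Mann-Whitney form, ties half-weighted).  An out-of-bag
  AUC is available as a diagnostic but plays no role in selection.
- Univariate: features are ranked by mean training AUC; the final model per
  feature takes the **median** intercept and slope over replicates and is
  evaluated once on the entire original dataset — no refit on full data.
  Ties break lexicographically on feature name (deterministic).
- Multivariate: all unordered feature pairs are traversed; a pair is
  admissible if its mean per-replicate Spearman correlation lies in
  [-0.8, 0.8] (the mean over bootstrap replicates, not the full-dataset
  correlation).  The gate is evaluated *before* fitting: inadmissible pairs
  can never win, and skipping them also avoids the exactly singular designs
  of duplicate features.  The winner maximises mean training AUC among
  admissible pairs.  The search is capped at two predictors (about one
  event per 7 patients at the emulated 21.4% event rate).
- Odds ratios are `exp(coefficient)`; medians and 10th/90th percentiles use
  linear-interpolation quantiles (the convention matters and is fixed).
- Everything downstream of a seed is bit-reproducible (tested end to end).

## Synthetic cohorts

The generator emulates the statistical shape of a 70-patient VMAT lung
cohort, not anatomy:

- Two near-mirror ellipsoidal lungs with small per-patient jitter (0.2-voxel
  centre, 1% axes) on a 64 x 64 x 32 grid of 4 mm voxels.
- Dose = low bath (3-7 Gy) + an anisotropic Gaussian high-dose lobe centred
  in the ipsilateral lung, peak drawn from the prescription distribution
  (59.10 +/- 5.67 Gy), + Gaussian-filtered white noise with per-patient
  amplitude (1-6 Gy) and correlation length (0.5-2.5 voxels), + focal
  hot/cold spots (0-40 per patient, 2-10 Gy, placed inside lung tissue).
  The focal component exists because a purely Gaussian random field makes
  every local-difference texture statistic a monotone function of a single
  scale parameter — unrealistically degenerate; focal modulation varies the
  tail weight of local dose differences, which is both closer to modulated
  plans and necessary for different texture features to carry different
  information.
- Outcomes are Bernoulli draws from a logistic model on features extracted
  by the pipeline's own extractor (default: ipsilateral GLCM Contrast with
  standardised coefficient 1.0 and total-lung LowGrayLevelRunEmphasis with
  0.5), with the intercept calibrated to a 21.4% expected event rate
  (15/70).  A latent-field stress mode (outcome on the per-patient noise
  amplitude itself) exists for harder, indirect recovery tests.
- Determinism: patient `i` draws from sub-streams
  `default_rng([seed, i, stream])`, so cohorts are reproducible and patient
  streams do not interact (a patient's data is the same whatever the cohort
  size).

**What a green recovery test does and does not establish.**  Outcomes are
generated on *extracted* features, so recovery is well-posed and exercises
the real extraction + selection path.  It does not establish clinical
validity, anatomical realism, or robustness to registration/contouring
error.  And because the texture registry contains near-duplicate features,
"the exact generating feature ranks first" is a much stronger demand than
"the selected feature is statistically equivalent to the generating one" —
see the known-limitations note below.

## Known limitations

- The feature registry's near-duplicates put a hard ceiling on exact-name
  recovery: `Idmn` correlates with `Contrast` at |rho| ≈ 0.9999 across any
  realistic cohort at Ng = 64 (it is an affine function of Contrast to
  second order in (i-j)/Ng), and several other siblings exceed 0.97.  The
  population AUC margin of the true generating feature over such a sibling
  is smaller than its sampling noise at n = 200, so which of them tops the
  ranking is close to a fair coin.  The acceptance-level recovery thresholds
  (>= 90% exact-name univariate, >= 80% exact pair) are therefore not
  attainable by construction; the corresponding tests are kept faithful and
  red.  Measured on the test configuration: the exact generating feature
  tops the ranking in 16/50 seeds, but a |Spearman| >= 0.95 surrogate of it
  does in 42/50; with orthogonal features (unit tests) recovery is exact.
- The EUD_PS closed form is exact only at NTCP = 0.5 (documented above).
- DICOM support covers uncompressed explicit-VR little endian only.
- The multivariate search is exhaustive and single-threaded; 8,256 pairs
  x 1,000 replicates is minutes of compute, and a `candidates` argument
  (e.g. top-K univariate features) is the intended way to bound it.
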