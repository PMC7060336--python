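# Methods

`gliorad` implements a multiparametric MR radiomics survival-modelling
pipeline for glioblastoma: quantitative map computation from raw diffusion
and perfusion signals, intensity harmonization, a fixed 6472-feature
radiomic bank over four channels, a sparse LASSO-Cox radiomics score with
maximally-selected risk stratification, and combined radiomics + clinical
Cox models with nomogram output. Because no patient imaging is distributed
with the package, a synthetic cohort generator provides phantoms whose
images, covariates and outcomes carry the statistical structure the
analysis assumes; every stage is validated against that generator's ground
truth or against independent oracles.

## Parametric maps

**ADC.** The apparent diffusion coefficient is the two-point estimate
`ADC = -ln(S(b)/S(0)) / b` (mm^2/s) from a b=0 / b=1000 s/mm^2 pair.
Voxels with non-positive signal are marked invalid and excluded from all
downstream statistics; invalidity is a contract, not a numeric fill.

**nCBV.** DSC signal is converted to relaxation-rate change
`dR2*(t) = -ln(S(t)/S_base)/TE` with `S_base` the pre-bolus baseline mean.
Contrast extravasation is removed with the Boxerman–Weisskoff linear
model: each voxel's curve is regressed on `[ref(t), -cumint(ref)(t)]`
where `ref` is the mean curve over non-enhancing tissue (brain minus the
2-voxel-dilated tumor mask by default); the fitted `K2` term is added back
to cancel leakage. Relative CBV is the trapezoidal integral of the
corrected curve from the end of the baseline to the last timepoint (the
integration window is a package choice; negative integrals are clipped to
0 and counted). Normalized CBV divides by the mean CBV inside a 4-mm
spherical ROI in contralateral normal-appearing white matter, realized as
all voxels whose centers lie within 2 mm of the ROI center.

On noise-free phantoms the recovered nCBV is proportional to the
generating CBV (regression through the origin, R^2 > 0.999) because the
reference curve itself is an unknown multiple of the true bolus; absolute
quantification is out of scope.

## Harmonization

CE-T1 and FLAIR have arbitrary scanner units and are white-stripe
normalized: the NAWM mode is the rightmost local maximum (above 10% of the
global maximum) of a Silverman-bandwidth kernel density of in-brain
intensities; the stripe holds the voxels within ±0.05 quantile mass of the
mode; the whole volume is z-scored by the stripe mean/SD. The map is
affine, so intensity ranks are preserved exactly. The same rightmost-peak
rule is used for FLAIR (documented approximation of the hybrid method).
ADC and nCBV keep physical units; instead their in-ROI intensities are
trimmed at ±3 SD of the ROI mean (single pass, full-input statistics)
immediately before feature extraction, and trimmed voxels are removed from
the texture mask rather than filled. All channels are resampled to 1 mm
isotropic grids (trilinear for intensities, nearest-neighbor for masks,
voxel-center convention). Enhancing-region segmentation is a seeded
threshold + region-growing operation: the maximal 6-connected in-band
component containing the seed.

## The radiomic bank

Per channel, 1618 features: 7 shape (mask only), then for the original
image and each of 8 single-level stationary-wavelet sub-bands (coiflet-1;
labels give the per-axis filter in x, y, z order) 17 first-order and 162
texture features (22 GLCM features × {mean, std} over 13 directions × 3
distances, plus 15 GLRLM features × {mean, std}). Four channels give 6472.
The undecimated wavelet keeps every sub-band on the input grid so the
tumor mask applies without resampling ambiguity.

Texture prerequisites: intensities are discretized into 32 equal-width
bins over the in-mask range (fixed bin *count*, so texture is invariant to
affine intensity maps); the 13 directions are the unique antipodal
representatives of the 26-neighborhood; GLCM matrices are symmetric and
normalized; GLRLM runs are maximal constant-level in-mask runs. Run
extraction sorts voxels into lattice lines via cross-product invariants,
which makes it exactly equivalent to explicit run-walking (tested against
a brute-force oracle) at O(N log N) per direction. Degenerate statistics
(zero variance, single gray level) return 0 for skewness/kurtosis/GLCM
correlation rather than NaN, so downstream standardization is never
poisoned. First-order entropy/uniformity use the same 32-bin histogram and
log base 2.

The full 64^3-subject extraction (4 channels × 9 sub-bands) runs in a few
seconds on one CPU; the acceptance script reports the measured time.

## Signature and risk groups

Features are z-transformed with training-set means/SDs (zero-SD columns
dropped and logged; validation data always reuse training parameters).
Selection maximizes the L1-penalized Cox partial likelihood (Breslow ties,
glmnet-style 1/n scaling) over a log-spaced penalty grid from the
analytically computed λ_max (all-zero solution) down to λ_max·0.01 when
p ≥ n (λ_max·0.001 otherwise). The penalty is chosen by K-fold
cross-validated partial-likelihood deviance in the Verweij–van Houwelingen
form — `2·[nll(all data) − nll(training part)]` at the fold coefficients —
because the plain held-out-subset deviance is unusably noisy when test
folds carry only a few events. The deviance minimizer is restricted to
penalties whose full-data solution keeps at least one feature; at very
small n the unrestricted minimizer is often the empty model, which cannot
define a signature. The `1se`-style conservative rule is available.
The unpenalized fits elsewhere in the package use Efron ties (accurate
with day-resolution data); the penalized path uses Breslow — the
difference is a documented convention split.

The radiomics score is the coefficient-weighted sum of the selected
standardized features, i.e. a Cox linear predictor. The risk cutoff
maximizes the absolute standardized two-sample log-rank statistic over
candidate cutpoints (midpoints of sorted unique scores inside the 10–90%
quantile band); the scan is computed for all cutpoints at once via suffix
sums of log-rank scores (martingale residuals at β = 0) with the
hypergeometric variance accumulated per event time, so it is exactly the
per-cutpoint statistic, only vectorized. Scores at or below the cutoff are
low-risk (deterministic tie rule).

A packaged published signature (six features, printed coefficients, cutoff
−0.07) ships as data for score application; its standardization is the
identity, so it must be applied to already-standardized features. The six
features themselves cannot be re-derived without the original patient
cohort.

## Survival evaluation

Kaplan–Meier curves are computed directly (product-limit with Greenwood
variance; cross-checked against lifelines), log-rank tests delegate to
lifelines, Cox models to lifelines' Efron Newton–Raphson, and Harrell's C
to scikit-survival's pair counter (validated against exhaustive O(n^2)
enumeration). C-index comparison between correlated predictors uses a
paired subject-level bootstrap of ΔC with a percentile-symmetrized
two-sided p — same hypothesis as the compareC U-statistic approach,
simpler and seed-reproducible. Calibration is the D'Agostino–Nam test:
subjects grouped by deciles of predicted S(t), group KM at the horizon
compared with the mean prediction, χ² on (groups − 1) df; empty deciles
merge with a neighbor.

Cross-validated performance re-runs everything that learns from data —
standardization, LASSO selection, Cox fitting — inside each event-stratified
training fold. Held-out linear predictors are pooled across folds into one
C per model (per-fold C values are also reported, but with 4-subject folds
they are nearly uninformative). Fold-level Cox fits use a small L2 ridge
(0.5 on clinical coefficients, half that on the cross-fitted radiomics
score, none on full-sample fits): at ~36 training subjects an unpenalized
multivariable fit is unstable, and the asymmetry reflects that the
radiomics score is already a cross-fitted linear predictor while the
clinical coefficients are estimated fresh in every fold. The three-model
comparison (combined / radiomics-only / clinical-only) shares folds and
per-fold signatures so that differences isolate what each component adds.

The nomogram assigns each covariate points `β·(x − x_ref)` scaled so the
largest single-covariate effect range spans 0–100, with `x_ref` the range
end of lowest hazard; total points invert to a linear predictor, and
survival is predicted as `S0(t)^exp(lp − lp_mean)` with a Breslow baseline
at covariate means. The points → survival round trip equals direct Cox
prediction to 1e-6.

## Synthetic cohorts

Tumors are ellipsoids perturbed by a smoothed Gaussian field (amplitude
0.25 normalized-radius units at irregularity 1), reduced to the 6-connected
component containing the center with holes filled. The brain is an
ellipsoid of smooth texture with a brighter NAWM compartment on the
contralateral side. Intra-tumor texture is the sum of two band-passed
Gaussian random fields (roughly 1–2.5 and 2.5–5 voxel scales);
`heterogeneity` in [0, 1] scales their amplitude, which monotonically
raises first-order entropy. Raw DWI pairs follow the exact two-point decay
plus Gaussian noise; raw DSC series follow the exact leakage model with a
gamma-variate bolus (α = 3, peak 6 s after a ≥5-sample baseline), so the
map-recovery stages have closed-form round trips at zero noise.

Survival follows a proportional-hazards model with Weibull baseline
(shape 1.2, scale set so the linear-predictor-zero median is 646 days,
matching the training cohort's median OS). Per-subject hazards depend on
standardized phenotype proxies — tumor ADC level (low = aggressive), tumor
CBV level (high = aggressive), log volume, heterogeneity — plus clinical
covariates (age, KPS < 80, gross-total resection), with clinical marginals
matching the training cohort (extent 45.6/36.1/18.4% GTR/STR/biopsy, median
age 59.5, ~13% KPS < 80). Default clinical hazard coefficients are anchored
to the published univariate hazard ratios (age 1.02/year, low KPS 1.70,
GTR 0.67). Censoring is uniform on [0, τ] with τ solved by root-finding so
the expected censored fraction hits the target; an administrative horizon
is available but off by default. Everything is deterministic given the
cohort seed; each subject draws from a stream derived from (seed, index).

No effect sizes linking image phenotype to hazard exist in the source
cohorts, so the generator's `true_effects` are free parameters. The
package default plants low-ADC and high-CBV effects of 0.8 per reference
SD. The simulation studies in the acceptance suite use stated conditions
chosen once for adequate power at desk scale: imaging effects 1.0/1.0,
clinical effects age ln(1.06)/year, KPS ln(3.0), GTR ln(0.4), censoring
10%, 40 subjects on 32^3 grids with ADC/CBV channels taken directly from
the generator's ground-truth maps and the original-sub-band feature set
(744 features) — the raw-signal reconstruction path is exercised
separately at full resolution. These phantoms emulate the *statistical*
structure of the analysis (aligned channels, monotone phenotype-hazard
links, censoring) and deliberately not anatomy, k-space physics, motion or
bias fields; passing tests demonstrate that the pipeline recovers planted
structure, not that it would rank real patients identically.

## Numerical conventions and limitations

* World coordinates in mm, voxel-center convention; masks stored 0/1.
* Invalid voxels propagate as masks, never as sentinel values.
* Maxstat cutpoints and LASSO λ are data-dependent; on null data the
  cutoff is unstable by construction and the selector may legitimately
  refuse (no non-empty solution) — callers should treat that as "no
  signal", not as an error to be retried.
* The combined-vs-single-model ordering is a statistical tendency, not a
  per-cohort guarantee: at the packaged 40-subject study conditions the
  acceptance suite measures it holding in about three quarters of seeds.
  The dominant failure mode is a cohort where the ~36-event LASSO score is
  anti-predictive out of sample, pulling the combined model below the
  clinical-only one; published cohorts establishing the ordering are
  several times larger.
* GLCM/GLRLM distances are measured in voxel steps; after 1 mm resampling
  these coincide with mm.
* The pipeline assumes pre-aligned channels; inter-channel registration is
  out of scope, so real-data inputs must be co-registered upstream.
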