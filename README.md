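# gliorad

Multiparametric MR radiomics survival modelling for glioblastoma.

Glioblastoma prognosis varies widely between patients, and conventional
contrast-enhanced MRI captures only part of that variation. Diffusion
(ADC) and perfusion (CBV) maps add physiology — tumor cellularity and
angiogenesis — and high-dimensional radiomic texture analysis can turn all
four image channels into a single prognostic score. `gliorad` implements
that full analysis as a tested Python library for imaging researchers:

* **Parametric maps** — two-point ADC (`ADC = -ln(S_b/S_0)/b`) and
  leakage-corrected relative CBV from dynamic susceptibility contrast
  series (Boxerman–Weisskoff reference-curve model,
  `dR2*(t) = K1·ref(t) − K2·∫ref`), normalized by a 4-mm contralateral
  white-matter ROI.
* **Harmonization** — white-stripe z-normalization of CE-T1/FLAIR, ±3 SD
  in-ROI outlier trimming of ADC/nCBV, 1 mm isotropic resampling, seeded
  threshold + region-growing segmentation.
* **Radiomic bank** — 1618 features per channel (7 shape, 17 first-order,
  162 GLCM/GLRLM texture, 1432 from 8 stationary-wavelet sub-bands), 6472
  per subject over CE-T1, FLAIR, ADC, CBV.
* **Radiomics signature** — cross-validated L1-penalized Cox selection;
  the score is `Σ coef_i · z_i`, a Cox linear predictor; risk groups split
  at the maximally selected log-rank cutpoint. The published six-feature
  signature (cutoff −0.07) ships as data for score application.
* **Survival evaluation** — Kaplan–Meier/log-rank, Efron-ties Cox, Harrell
  C with paired-bootstrap comparison, D'Agostino–Nam calibration,
  leakage-safe cross-validated model comparison, and a Cox nomogram for
  1- and 2-year survival.
* **Synthetic cohorts** — a phantom generator (images, clinical covariates
  and Weibull proportional-hazards outcomes whose hazard depends on the
  planted imaging phenotype) so the whole pipeline is testable without
  patient data. Real-data entry points accept NIfTI volumes + CSV tables
  in the same layout.

## Worked example

```python
from gliorad.features import ExtractionConfig
from gliorad.pipeline import cohort_feature_table
from gliorad.signature import (lasso_cox_select, maxstat_cutoff,
                               radiomics_score, stratify, z_transform)
from gliorad.survival_eval import logrank_test
from gliorad.synthetic import PhantomConfig, default_radius_range

pcfg = PhantomConfig(grid_shape=(32, 32, 32), n_subjects=40, seed=1,
                     tumor_radius_range_mm=default_radius_range(32),
                     simulate_raw_signals=False, censor_rate=0.1)
features, clinical, time, event = cohort_feature_table(
    pcfg, ExtractionConfig(subbands=("orig",)))

z, params = z_transform(features)
model = lasso_cox_select(z, time, event, cv_folds=5, seed=0, n_alphas=30)
scores = radiomics_score(z, model)
cutoff, stat = maxstat_cutoff(scores, time, event)
chi2, _, p = logrank_test(time, event, stratify(scores, cutoff))
print(len(model.features), round(cutoff, 3), round(chi2, 2), f"{p:.2g}")
```

prints

```
3 0.038 11.79 0.00059
```

— the LASSO kept 3 of 744 features, the maximally selected cutpoint on the
resulting score is 0.038, and splitting the cohort there separates
survival with log-rank χ² = 11.79 (p ≈ 6 × 10⁻⁴): the planted low-ADC /
high-CBV hazard signal was recovered from the images. The `examples/`
directory walks through each capability (simulation, map recovery, feature
extraction, signature training, model evaluation and nomogram, applying
the published signature); each script prints the numbers it computes with
a note on what they mean.

A thin CLI mirrors the pipeline stages:

```bash
gliorad simulate --n 20 --seed 1 --grid 48 --out cohort/
gliorad extract --images cohort/ --out features.csv
gliorad train-signature --features features.csv --clinical cohort/clinical.csv --out model.json
gliorad run --out run1/          # full pipeline, config optional
```

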