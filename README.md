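# wmhnet

Regional disconnectivity of white-matter lesion masks against a reference
streamline connectome, with periventricular/deep partitioning of the lesion
mask and ordinal outcome modeling.

The package implements, at desk scale and fully synthetically testable:

- **ChaCo scoring** (`wmhnet.connectome`): per brain region, the fraction of
  reference streamlines connected to that region that pass through a binary
  lesion mask, plus the value-cleaning rule (values < 0.02 → 0, values > 1 → 1).
- **Periventricular / deep partition** (`wmhnet.topology`): splits a WMH mask
  at a Euclidean distance threshold (default 10 mm, anisotropy-aware) to the
  ventricles; mask volumetry in ml.
- **Group statistics** (`wmhnet.group_stats`): one-sample disconnection
  t-tests per region, paired mask-type comparisons per cortical/subcortical
  stratum, and the skewness/median region-exclusion filter.
- **Outcome models** (`wmhnet.outcome`, `wmhnet.ordinal`): median-dichotomized
  regional disconnectivity entered into a proportional-odds (cumulative-logit)
  model of an ordinal disability grade, with age and lesion-burden covariates
  residualized against the region's continuous disconnectivity, OR/CI/p
  extraction (Wald or profile), Nagelkerke/McFadden pseudo-R² gain over a base
  model, and Benjamini–Hochberg FDR across the region family. The
  proportional-odds MLE is implemented in-package (softplus-increment
  cutpoints, analytic gradient, Newton polish) and is validated against
  logistic regression and `statsmodels.OrderedModel` in the test suite.
- **Synthetic data** (`wmhnet.synthetic`): seeded toy atlases, ventricle
  ellipsoids, noisy streamline connectomes, per-patient WMH/stroke masks with
  periventricular and deep components, and ordinal outcomes generated from a
  proportional-odds model with known effects — every downstream stage runs
  with no external data.
- **Pipeline** (`wmhnet.pipeline`): simulate/load → split → ChaCo →
  group stats → outcome models for each mask type (wmh, pwmh, dwmh), with a
  SHA-256 manifest; reruns with the same seed are bit-identical.

## CLI

All stages are subcommands of one entry point:

```sh
# generate a synthetic cohort
wmhnet simulate --config sim.yaml --out data/ --seed 1

# individual stages
wmhnet split-wmh --wmh p000_wmh.nii --ventricles ventricles.nii \
    --threshold-mm 10 --out-prefix p000
wmhnet chaco --mask p000_pwmh.nii --connectome connectome.tck \
    --atlas atlas.nii --out chaco.csv
wmhnet group-stats --chaco chaco.csv --out stats/
wmhnet outcome-model --chaco chaco.csv --cohort cohort.csv \
    --mask-type pwmh --base-adjust wmh_volume --out results.csv

# everything end to end from a YAML run config
wmhnet run --config run.yaml
```

A run config contains a seed, an output directory, either a `simulation:`
block (SimulationConfig fields) or an `inputs:` block (paths to NIfTI masks,
a TCK or plain-text connectome, and a cohort CSV), and an `options:` block
(floor, threshold_mm, skew_limit, r2_kind, ci_method, fdr_alpha, base_adjust).

Streamlines are read from TCK or from a plain-text dialect (one streamline
per block, one `x y z` line per point, blank-line separated). Cohort CSVs
carry `patient_id, age, nihss, mrs, lesion_volume_ml, wmh_volume_ml, ...`.

## A note on residualization

Residualizing a covariate against regional disconnectivity deliberately
credits variance shared between that covariate and disconnectivity to the
disconnectivity predictor. Consequently the per-region test is calibrated
only under nulls in which the residualized covariates carry no true outcome
effect; when they do, the dichotomized predictor inherits part of their
effect by construction. The null-calibration tests use such a genuine null.
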