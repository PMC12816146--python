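# underserved

Explainable machine-learning pipeline for modelling which dentists practice in
underserved settings (safety-net clinics, dental shortage areas, rural
shortage areas). The real survey data behind the original analysis are
restricted, so the pipeline is driven by a seeded synthetic cohort generator
whose marginals match the published sample description and whose
outcome-generating mechanism plants known, recoverable effects.

## What's inside

| Module | Purpose |
| --- | --- |
| `underserved.cohort` | Synthetic dentist cohorts: published-sample marginals, calibrated rare-outcome prevalences, planted nonlinear effects (piecewise debt response, experience change-point, race-by-debt interaction, school-state effects), seeded missingness. |
| `underserved.preprocess` | Missingness (>60%) and collinearity (r > 0.8) filters, median imputation, full one-hot encoding, z-scoring — all fit on training data only. |
| `underserved.ensemble` | Calibrated soft-voting classifier (ridge logistic + gradient-boosted trees with cross-fitted isotonic calibration), MCC-optimal thresholding, Monte Carlo cross-validation with imbalance-aware metrics (AUC, sensitivity, specificity, precision, lift, MCC). |
| `underserved.importance` | AUC-based SAGE (permutation-sampling Shapley values of an AUC value function), logistic coefficient ranking, feature-inclusion curves and top-k selection. |
| `underserved.attribution` | Per-instance Shapley attributions under one marginal-removal game: exact enumeration oracle, closed-form linear SHAP, exact polynomial-time tree SHAP, and model-agnostic permutation sampling with Monte Carlo standard errors. |
| `underserved.cluster_tree` | Supervised clustering tree over attribution space: per-node PCA, seeded k-means over candidate cluster counts, silhouette-gated splits, prevalence-labelled leaves, high-prevalence driver summaries. |
| `underserved.reporting` / `underserved.cli` | Plot-ready dependence / heatmap / force data products, the end-to-end pipeline runner with hashed artifact manifest, and the `underserved` command-line interface. |

## CLI

```bash
underserved simulate --n 20000 --seed 7 --out cohort/
underserved preprocess --train cohort/features.csv --plan plan.json --out X.csv
underserved train --features cohort/features.csv --outcomes cohort/outcomes.csv \
    --outcome fqhc --iters 30 --seed 11 --report report.json
underserved sage  --features cohort/features.csv --outcomes cohort/outcomes.csv \
    --outcome fqhc --perms 64 --seed 3 --out sage.json
underserved shap  --features cohort/features.csv --outcomes cohort/outcomes.csv \
    --outcome fqhc --flavor marginal --samples 64 --seed 5 --out shap
underserved cluster --shap shap.csv --outcomes cohort/outcomes.csv \
    --outcome fqhc --min-sil 0.4 --seed 9 --out tree.json
underserved run-all --seed 1 --out pipeline_out/
```

Models are refit from seeded inputs rather than pickled, so every artifact on
disk is plain CSV/JSON and reruns with the same config produce byte-identical
artifact hashes (see `manifest.json`).

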