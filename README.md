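# habitatpipe

Habitat radiomics pipeline for predicting 6-month durable clinical benefit
(PFS6) of immunotherapy in non-small-cell lung cancer from pre-treatment CT,
exercised end to end on a synthetic CT cohort with known ground truth.

Tumors are biologically heterogeneous; clustering the voxels of the
segmented tumor (the VOI) by imaging characteristics yields spatially
coherent sub-regions — *habitats* — whose texture can carry outcome signal
that whole-tumor features average away.  This package implements that whole
analysis chain as a tested library for people who want to study, stress or
reuse the methodology: medical-image-analysis researchers, radiomics
methodologists, and reviewers who want to see what the pipeline's claims do
and do not rest on.  Because no patient data from such studies are publicly
deposited, the package includes a synthetic cohort generator that plants
habitats and outcome signal, so every stage is verifiable against ground
truth.

## The pipeline

1. **Preprocess** — resample CT + mask to 1 mm isotropic, min–max normalize
   intensities to 0–255 using VOI statistics.
2. **Habitat mapping** — per-voxel features (intensity, local entropy
   H = −Σ p_b log₂ p_b over a 3³ window, 32 bins); per-patient K-means with
   the cluster count k chosen once per cohort by Monti consensus clustering
   (k = 2..10, elbow on the relative consensus-CDF area, PAC reported);
   habitats renumbered by ascending centroid intensity.
3. **Features** — 93 IBSI-style first-order + GLCM/GLRLM/GLSZM/GLDM/NGTDM
   features per habitat and for the whole tumor (+14 shape), written from
   first principles and tested against exhaustive brute-force oracles; plus
   a 512-dimensional 3D-ResNet descriptor of the tumor ROI (numpy forward
   pass, fixed-seed weights).
4. **Selection cascade** — ICC(2,1) ≥ 0.75 against a second rater's mask,
   z-score, Pearson pruning at |r| > 0.9, Welch t-test at α = 0.05, and
   LASSO-logistic with a cross-validated 1-SE λ (the t-test screen is
   repeated inside the CV folds, which keeps the cascade honest on null
   data: see `docs/methods.md`).
5. **Models** — RBF-SVMs per habitat / whole tumor / deep features and all
   their fusions with the deep features; stratified 5-fold tuning; Platt
   probabilities; test metrics (accuracy, precision, recall, F1, AUC with
   bootstrap CI, MCC, PLR, NLR) at the training Youden cutoff.
6. **Survival & DCA** — Kaplan–Meier curves and log-rank tests for PFS/OS by
   high/low risk at the same cutoff; decision-curve net benefit.
7. **Explanation** — kernel SHAP (exact for ≤ 12 features) of the best fused
   model.

Array convention: volumes are numpy arrays indexed `[z, y, x]` with
`spacing_mm` in the same axis order; voxel coordinates are 0-based.

## Worked example

The numbered scripts under `analysis/` run the demo study (60 synthetic
patients, 3 planted habitats, outcome signal at 1.5 SD in the brightest
habitat) and write their tables under `results/run_demo/`:

```bash
python analysis/01_simulate_cohort.py  --seed 1
python analysis/02_habitat_mapping.py  --seed 1
python analysis/03_extract_features.py --seed 1
python analysis/04_select_and_model.py --seed 1
python analysis/05_survival_and_dca.py --seed 1
python analysis/06_shap_explanation.py --seed 1
```

Script 02 prints the consensus scan and selects k = 3 — the planted habitat
count — with the delta-area elbow collapsing after k = 3 (0.398 → 0.099);
script 03 reports the habitat maps recovering the planted sub-regions at
median ARI 0.856.  Script 04 prints the held-out metric table (abridged
below; full numbers in `results/run_demo/metrics.csv`):

```
held-out test performance (training-Youden cutoff):
         model  accuracy  precision  recall    f1   auc   mcc  plr   nlr
      habitat1      0.60        NaN   0.000   NaN 0.500   NaN  NaN 1.000
      habitat3      0.85      0.857   0.750 0.800 0.938 0.685  9.0 0.273
         whole      1.00      1.000   1.000 1.000 1.000 1.000  NaN 0.000
            DL      0.60      0.500   0.500 0.500 0.688 0.167  1.5 0.750
   habitat3+DL      0.80      0.833   0.625 0.714 0.896 0.579  7.5 0.409
all_habitat+DL      0.80      0.833   0.625 0.714 0.896 0.579  7.5 0.409
```

The structure is the planted truth showing through: the signal habitat
(habitat 3, the brightest) predicts well (AUC 0.938) while the non-signal
habitats collapse to the no-information model (their selection cascades
rightly retain nothing, hence the NaN columns at a degenerate cutoff); at
this effect size the whole-tumor features also capture the signal, because
inflating one habitat's SD by 1.75× moves whole-VOI statistics too.
Script 05 stratifies the held-out patients into high/low risk
(PFS log-rank χ² = 19.0, p = 1.3e-05; OS p = 0.040) and writes the KM and
decision-curve tables; script 06 ranks the explained model's features by
mean |SHAP|.

The same pipeline is scriptable through the CLI
(`habitatpipe run-all --config cfg.yaml --out runs/r0 --seed 1`, with
per-stage subcommands and resumable run directories) or the library
(`habitatpipe.experiment.run_experiment`).

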