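# dynconn

Dynamic gray–white matter functional connectivity analysis as a tested,
reusable pipeline:

- **synthetic cohort generation** (`dynconn.synthetic`) — multi-subject,
  multi-site node BOLD time series from a latent-factor model with planted
  *static* coupling and *time-varying* coupling (sinusoidal or Markov-switching
  schedules), site batch effects, class imbalance presets, and clinical-scale
  scores linearly coupled to the planted dynamic variability.
- **data-driven parcellation** (`dynconn.parcellation`) — K-means clustering of
  voxel time series with subset-reproducibility validation via
  Hungarian-matched Dice coefficients.
- **connectivity** (`dynconn.connectivity`) — band-pass filtering, static
  Fisher-z correlation matrices (328 × 328 for the default 200 gray + 128
  white atlas), and tapered sliding-window dynamic FC with the SD-of-z
  variability statistic (Hamming/Gaussian/rectangular windows, 1-TR step).
- **graph metrics** (`dynconn.graphs`) — proportional thresholding; strength,
  weighted clustering, local/global efficiency, characteristic path length,
  seeded Louvain modularity; dynamic mean/SD variants over window stacks.
- **statistics** (`dynconn.stats`) — parametric empirical-Bayes ComBat site
  harmonization, edge-wise two-sample differential-connection tests with
  none/Bonferroni/FDR correction, subnetwork chord aggregation, ANOVA + Tukey
  HSD, chi-square tests, clinical-scale correlations, cross-cohort matrix
  similarity.
- **classification** (`dynconn.classify`) — L1 (LASSO) feature selection,
  SMOTE oversampling, kernel SVMs, stratified 10-fold cross-validation with
  all leakage-prone steps refit per training fold, and midrank ROC/AUC.
- **orchestration** (`dynconn.pipeline`, `dynconn.cli`) — a deterministic
  end-to-end `simulate → connect → features → stats → classify` pipeline with
  a hashed output manifest.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` implements the acceptance criteria. One assertion
(`test_criterion_5_chi_square_printed_p_value`) is intentionally left failing:
the claimed p < 0.001 for the 2×2 APOE allele table is not reproducible from
the table's own counts (Pearson chi-square gives p = 0.0034; Yates and Fisher
exact are larger). The computed statistic is asserted exactly in
`tests/test_stats.py`.

## CLI

```bash
dynconn simulate --out sim_dir --seed 1
dynconn connect --in sim_dir --out conn_dir --windows static,gau20,ham30
dynconn parcellate --k 12 --subsets 4 --seed 1 --out parc_dir
dynconn stats --features feats.tsv --meta sim_dir/subjects.tsv \
    --groups CN,CI --alpha 0.05 --out diff.tsv
dynconn classify --features feats.tsv --meta sim_dir/subjects.tsv \
    --groups CN,CI --kernel rbf --folds 10 --seed 1 --out cv.json
dynconn run --out pipeline_out --seed 1     # full demo pipeline + manifest
```

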