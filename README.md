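# ovca

Molecular subtype discovery and functional screen analysis for epithelial
ovarian cancer expression data, built as a reusable, fully tested pipeline
with a synthetic-data module standing in for the original cohorts.

The pipeline covers:

- **I/O** (`ovca.io_formats`) — strict readers/writers for TSV and GCT 1.2
  expression matrices, GMT gene-set collections, clinical tables, shRNA
  hairpin libraries and screen count matrices.
- **Synthetic data** (`ovca.simulate`) — multi-batch expression cohorts with
  planted subtype signature blocks, gene sets with decoys, exponential
  survival with per-subtype hazard ratios, pooled shRNA screens with planted
  essential genes, and Hill-curve dose-response tables. Every generator is a
  pure function of (config, seed).
- **Batch adjustment** (`ovca.batch`) — parametric empirical-Bayes
  location/scale batch correction with protected biological covariates,
  SD-threshold gene filtering (default SD > 1.05) and gene centering.
- **Consensus subtyping** (`ovca.subtyping`) — resampled consensus
  clustering (average linkage, Euclidean, 0.8 subsampling), k-selection
  metrics (consensus-CDF delta area, PAC, within-cluster consensus),
  silhouette widths with core-sample flags (SW > 0), a Gaussian-null
  two-cluster significance test, and label concordance/ARI.
- **ssGSEA** (`ovca.ssgsea`) — per-sample weighted-ECDF gene-set enrichment
  scores, SAM-style moderated statistics with permutation FDR, ROC AUC, and
  subtype-specific set selection (default q = 0, AUC > 0.85).
- **Prediction** (`ovca.predictor`) — one-vs-rest Bayesian probit metagene
  classifiers trained on top-50 core samples per subtype (signature gene
  selection by label correlation, SVD metagenes, truncated-normal
  data-augmentation Gibbs sampling), with k-fold and three-way-split
  cross-validation.
- **Screens** (`ovca.screen`) — perfect-match read counting against a
  hairpin library, depth normalization, cross-screen compilation with batch
  adjustment, signal-to-noise hairpin ranking, weighted-KS gene enrichment
  with a hairpin-permutation null (BH FDR per direction, default q < 0.005,
  hairpin score >= 0.2), Cohen's d, and the siRNA validation decision rule.
- **Survival statistics** (`ovca.survival`) — Kaplan-Meier curves, k-group
  log-rank, Breslow-ties Cox proportional hazards, Fisher's exact test,
  Mann-Whitney U, Spearman correlation matrices, and GI50 estimation from
  dilution-series viability curves (4-parameter logistic with interpolation
  fallback).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the release criteria (oracle equivalence,
planted-signal recovery, error-rate calibration); the other files are
per-module unit and property suites.

## CLI

The `ovca` entry point (also `python -m ovca.cli`) exposes the pipeline:

```sh
# synthetic inputs
ovca simulate cohort --config cfg.yaml --out cohort/ --seed 1
ovca simulate screen --config screen.yaml --out screen/ --seed 1
ovca simulate survival --labels cohort/labels.tsv --hr C2=2.0 --out surv.tsv
ovca simulate dose --gi50 10 --out dose.tsv

# preprocessing: batch adjust, SD filter, center
ovca preprocess --expr cohort/expression.tsv --batches cohort/labels.tsv \
    --sd-threshold 1.05 --center median --out adj.tsv

# subtype discovery and validation
ovca subtype discover --expr adj.tsv --k 5 --kmax 8 --iters 1000 \
    --subsample 0.8 --seed 7 --out subtypes/

# per-sample enrichment and subtype-specific set selection
ovca ssgsea --expr adj.tsv --gmt sets.gmt --alpha 0.25 --out es.tsv
ovca select-sets --es es.tsv --labels subtypes/subtypes.tsv \
    --qmax 0 --aucmin 0.85 --out selection.tsv

# probit metagene prediction
ovca predict train --expr adj.tsv --labels subtypes/subtypes.tsv --out models/
ovca predict apply --models models/ --expr new.tsv --out pred.tsv

# screens: counting and gene calling
ovca screen count --reads reads.fastq --library lib.tsv --out counts.tsv
ovca screen riger --counts screen/counts.tsv --library screen/library.tsv \
    --groups screen/groups.tsv --perms 1000 --qmax 0.005 --hairpin-min 0.2 \
    --seed 7 --out riger/

# survival
ovca survival km --clinical surv.tsv --out km.tsv
ovca survival logrank --clinical surv.tsv
ovca survival cox --clinical surv.tsv --out cox.tsv
ovca gi50 --doses dose.tsv
```

`ovca io validate <path> --format {tsv,gct,gmt,library,clinical,counts}`
checks any input file against its format contract.

## Layout

```
src/ovca/          io_formats, simulate, batch, subtyping, ssgsea,
                   predictor, screen, survival, cli
tests/             per-module suites + test_acceptance.py
scripts/acceptance.py
```
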