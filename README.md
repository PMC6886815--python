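# mapperflow

Composable risk-minimizing morphisms and Mapper-graph local-model ensembles
for imbalanced, mixed-type binary classification.

The package is built around a small algebra of **morphisms** — parametric
maps bundled with an empirical risk function and a parameter prior, fitted by
risk minimisation. Morphisms compose sequentially or jointly, add as direct
sums when their risks decompose, and assemble into full workflows. The
flagship workflow:

1. **encode** a mixed continuous/categorical table (full one-hot dummy
   coding),
2. **partition** the cohort with a from-scratch Mapper construction
   (first-principal-component filtration, overlapping interval cover,
   deterministic k-medoids under Gower distance, small-node pruning,
   shared-sample edges),
3. **train a local classifier pipeline on each graph node** (optional node
   PCA, optional SMOTE/ROSE-style resampling of training folds, logistic /
   SVM / random-forest / AdaBoost classifiers tuned by stratified CV AUC),
4. **blend node probabilities with convex weights** (closest, equal,
   inverse-distance, or CV-AUC-proportional over the one or two nearest
   nodes), and
5. **threshold** the blended probability (Youden-J tuned on pooled CV
   hold-out scores; boundary-inclusive).

Mapper parameters (interval count `k`, overlap `o`, cluster bound `b`) are
selected by grid search on cross-validated hold-out AUC. An exact graph edit
distance (exhaustive node-assignment search, graphs ≤ 8 nodes) is provided as
a graph-comparison utility, along with DOT / TSV graph exports and seeded
synthetic-cohort generators with planted group structure.

## Layout

| module | contents |
| --- | --- |
| `mapperflow.core` | `Morphism`, priors, spaces, `compose`, `direct_sum`, collections |
| `mapperflow.morphisms` | encoder, standardization (KL risk), PCA, linear regression, classifier wrappers, SMOTE/ROSE samplers, decision threshold |
| `mapperflow.mapper` | Gower distance, PC1 filtration, cover, k-medoids, graph build/assignment, exact GED, exports |
| `mapperflow.ensemble` | node pipelines, convex weighting, `fit_workflow`, prediction |
| `mapperflow.synthetic` | seeded mixed-type imbalanced cohorts, noisy circle, orthogonal designs |
| `mapperflow.evaluation` | rank-based AUC and threshold metrics, repeated stratified holdout, comparison tables |
| `mapperflow.cli` | `synth`, `fit`, `compare`, `mapper-viz` subcommands |

## Quick start

```python
from mapperflow.synthetic import CohortSpec, generate_mixed_imbalanced, column_spec_for
from mapperflow.ensemble import fit_workflow, ensemble_predict_proba, predict

spec = CohortSpec(n=776, minority_frac=0.173, effect_flip=(1.0, -1.0), seed=0)
X, y, groups = generate_mixed_imbalanced(spec)

config = {
    "mapper": {"grid": {"k": [5, 10], "o": [0.4], "b": [10]}, "min_node_size": 40},
    "pipeline": {"sampler": "smote", "classifier": "logistic"},
    "weights": {"scheme": "auc_proportional", "max_nodes": 2},
    "column_spec": column_spec_for(spec),
}
wf = fit_workflow(X, y, config, seed=0)
proba = ensemble_predict_proba(wf, X)
labels = predict(wf, X)
```

## CLI

```bash
mapperflow synth --n 776 --seed 0 --out cohort           # CSV + sidecars
mapperflow fit --data cohort.csv --columns cohort.columns.json --seed 0
mapperflow compare --data cohort.csv --columns cohort.columns.json \
    --configs configs.json --n-runs 10 --seed 0 --out table.csv
mapperflow mapper-viz --data cohort.csv --columns cohort.columns.json \
    --k 10 --o 0.4 --b 10 --out graph.dot
```

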