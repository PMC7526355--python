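# edgebiomark

Network-edge biomarker discovery from gene-expression cohorts.

In outcome prediction from expression data (the motivating application is
breast-cancer metastasis within five years), single-gene features are
notoriously unstable: top-gene lists barely overlap between patient
subsets. This package implements an *edge-based* alternative: every edge
of a gene network (protein–protein interaction or co-expression) becomes
a feature whose per-sample value is the **sum of the two genes'
expression**. It then provides the full comparative machinery:

- **Prediction benchmarking** — repeated stratified cross-validation of
  random forest, linear SVM and L1 logistic regression on gene vs edge
  features, scored by AUC, positive-class F1 and Cohen's κ, with class
  predictions either at the default cut or at the *optimal probability
  threshold* minimizing the ROC distance to the perfect corner,
  `d = √((1−sensitivity)² + (1−specificity)²)`, chosen on a held-out
  validation split. Paired t-tests summarize each comparison as
  Win/Lose × significant/not.
- **Calibrated robustness** — comparing list stability across feature
  types of wildly different dimension is only fair when the
  chance-expected overlap is equalized: selecting the top
  `X = ⌊√(T·e)⌋` of `T` features twice independently gives expected
  overlap `X²/T = e`. Robustness is the observed/expected fold
  enrichment of top-list overlap between two class- and
  subtype-balanced disjoint halves of the cohort, with an upper-tail
  hypergeometric p-value.
- **Importance aggregation & biomarker ranking** — a random forest
  scores only the features it samples, so importances are aggregated
  over many independently seeded forests (a zero score means "never
  sampled", not "unimportant"), and final rankings come from
  bootstrapped refits (65% resamples) with tree counts scaled linearly
  with feature dimension. Gene-level biomarker lists are pooled from
  top-ranked edges for downstream enrichment tools.
- **Synthetic cohorts** — a seeded generator emulating a 12-study,
  1616-patient compendium (exact per-cohort poor/good counts,
  single-factor co-expressed gene modules, per-gene cohort batch
  offsets, per-sample mean-centering) with *planted* signal edges whose
  pair sum carries more class signal than either gene alone, so every
  stage is testable without the original data.
- **Co-expression network construction** — mutual top-k neighbors under
  Pearson correlation (two genes are linked iff each is in the other's
  k most co-expressed genes; k = 84 matches protein-interaction density
  at compendium scale).

## Worked example

```python
import edgebiomark as eb
from edgebiomark.evaluate import CVConfig

dataset, network, planted = eb.default_bundle(seed=1)
genes = eb.gene_feature_matrix(dataset)
edges = eb.edge_feature_matrix(dataset, eb.restrict_network(network, dataset))

cfg = CVConfig(n_folds=5, n_repetitions=10, model="RF", seed=7)
gene_auc = eb.run_cv(genes, dataset.labels, cfg)["AUC"]
edge_auc = eb.run_cv(edges, dataset.labels, cfg)["AUC"]
print(eb.summarize_comparison(edge_auc, gene_auc))

result = eb.robustness_protocol(
    dataset, {"gene": genes, "PPIEdge": edges},
    expectation_levels=(2, 10, 50), n_splits=10, seed=3,
    importance_params={"gene": (100, 3), "PPIEdge": (100, 6)},
)
```

prints (exact numbers; everything is seeded):

```
cohort: 240 samples (72 poor / 168 good), 160 gene and 400 edge features
gene RF AUC 0.739 | edge RF AUC 0.820 -> Win-SS (paired t p = 4.2e-05)
expectation  2: overlap ratio gene 2.88 vs edge 4.49
expectation 10: overlap ratio gene 1.43 vs edge 1.80
expectation 50: overlap ratio gene 1.05 vs edge 1.16
```

Edge features win the AUC comparison significantly, and their top-list
overlap between independent cohort halves exceeds the gene baseline at
every calibration level — at expectation 2, the edge lists share 4.5×
more features than chance, versus 2.9× for genes. Fold enrichment
decays toward 1 as the lists grow, because longer lists admit
progressively noisier features.

The same pipeline is scriptable from the shell (`edgebiomark synth`,
`coexpress`, `features`, `bench`, `robust`, `rank`); every command
writes plain TSV plus a JSON provenance sidecar recording its seed.

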