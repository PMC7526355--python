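# Methods

This note documents the statistical models and procedures implemented in
`edgebiomark`, the defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the numerical
conventions that make runs reproducible.

## Problem setting

Samples are patients with a binary outcome (positive/"poor" = event,
e.g. metastasis within five years; negative/"good" = event-free),
grouped into cohorts (studies) with heterogeneous sizes and class
ratios. The measured variables are log-scale, per-sample mean-centered
expression values for a fixed gene panel. A gene network (curated
protein–protein interactions, or a co-expression network built from the
data) defines gene pairs.

Two feature representations are compared throughout:

- **gene features**: each gene's expression as-is;
- **edge features**: for each network edge (i, j), the per-sample sum
  `x_i + x_j`. The sum (not the mean) is the convention: tree ensembles
  are scale-invariant, but L1-penalized linear models are not, so the
  choice is fixed once and applied everywhere.

Edge feature spaces are an order of magnitude larger than gene spaces
(at compendium scale, ~160–180 thousand edges vs ~12.75 thousand
genes), which drives most of the methodological care below.

## Co-expression network

Pearson correlation is computed between all usable gene pairs
(zero-variance genes are excluded with a warning rather than aborting
the run — real matrices contain flat probes). An edge is created iff
each gene is among the other's k highest-correlation partners (self
excluded). Ranking uses *signed* correlation by default — "most
co-expressed" is read as most positively correlated — with an
`absolute` flag for |r| ranking, since either reading is defensible.
Ties at the k-th rank are broken by lexicographic gene id, which makes
the network independent of gene and sample order and of the platform's
sort stability. The default k = 84 is the neighborhood size that
matches protein-interaction edge density at 12750 genes; at other
scales k should be chosen to hit the desired density. Mutuality caps
the edge count at n·k/2 and the edge set grows monotonically with k.

## Cross-validated benchmarking

Folds are stratified by class. The published protocol this follows is
silent on stratification, but several cohorts have single-digit
positive counts and unstratified folds routinely produce single-class
test sets; a repetition containing such a fold is skipped with a
warning. Defaults follow the protocol the package reproduces: RF with
100 trees (other settings at library defaults), linear-kernel SVM at
defaults, and L1 logistic regression with C ∈ {0.001, 0.01, 0.1, 1,
10, 100} chosen by an inner stratified 5-fold search on the training
folds. Scores for AUC are: fraction of trees voting positive (RF —
vote fraction, documented because averaged leaf frequencies are the
main alternative), the decision margin (SVM), and the positive-class
probability (LR).

With `threshold_mode="optimal"`, each repetition splits the non-test
folds 80/20 (stratified) into train and validation; the model is fit
on the 80%, and every distinct validation score is evaluated as a cut
(predict positive at score ≥ cut, boundary convention fixed and
tested). The cut minimizing √((1−sens)² + (1−spec)²) is applied to the
test fold; ties break toward the higher threshold (fewer predicted
positives). The threshold is a function of validation data only, so no
test information leaks into it.

Metrics: rank-based AUC with ties counted half; F1 of the positive
class only (class imbalance makes macro-averaging misleading, and the
event class is the clinical interest), 0 by convention when there are
no predicted or true positives; Cohen's κ = (p_o − p_e)/(1 − p_e), NaN
when p_e = 1. Feature types are compared per metric by a two-sided
paired t-test over repetition means at α = 0.05 (sidedness is a fixed
convention); identical vectors give a NaN p-value and an "Equal/NaN"
outcome.

## Calibrated robustness

Selecting the top X of T features twice independently yields an
expected overlap of X²/T, so equal fold enrichment at equal *expected*
overlap is comparable across feature types of different dimension. For
a target expectation e the list size is X = ⌊√(T·e)⌋. Flooring is the
convention (the worked sizing table this reproduces floors, e.g.
⌊√(12750·20)⌋ = 504 where rounding would give 505); the realized
expectation X²/T is then within 2% of e whenever T·e ≥ 10⁴, which
covers every level/total combination the analysis uses (levels 2–50,
totals ≥ 12750; note the bound genuinely fails for very small T·e,
e.g. T = 1000, e = 2 realizes 1.936).

Cohort halves come from a stratified bipartition: samples are shuffled
within each (class, subtype) stratum; odd strata donate their extra
sample to whichever half keeps — in priority order — the per-class
difference, the total size difference, and the per-subtype difference
smallest. This guarantees disjoint exhaustive halves with sizes and
per-class counts differing by ≤ 1 (per-subtype balance is best-effort
within ±2, the residual of satisfying the two harder constraints).

Importance profiles are aggregated per half: the forest is retrained
`n_iterations` times with derived seeds on the same data, and a
feature's score is the mean of its non-zero impurity importances
(zero = never sampled). Per-iteration seeds extend deterministically,
so coverage (fraction of features ever scored) is monotone in the
iteration count. Features never scored cannot be ranked; if the
calibrated X exceeds the scored count the protocol raises an error
whose remedy is more iterations — the reason multi-iteration training
exists. Compendium-scale defaults are 300/500/500 trees and 50/200/200
iterations for gene/CE-edge/PPI-edge types; the test suite and
acceptance script use 100 trees with 3 (gene) and 6 (edge) iterations,
which reach 100% coverage at their reduced dimensions (160 genes, 400
edges).

Each of 20 bipartitions yields, per type and level, an observed
overlap, the ratio to X²/T, and an upper-tail hypergeometric p-value
P(overlap ≥ observed) for two independent X-subsets of T, summed in
log space so compendium-scale tails (~1e−78) do not underflow. Ratio
vectors are compared between types by paired t-test. Under label
permutation the observed overlap is exactly hypergeometric, so the
null mean ratio is 1; the null check in the acceptance suite uses the
exact hypergeometric standard error rather than a plug-in sample SE,
which is unreliable for the small integer counts at low expectation
levels.

## Biomarker ranking

Final rankings use bootstrapped refits: each of `n_repetitions`
(default 1000; tests use 10–30) draws ⌈0.65·n⌉ samples with
replacement, refits the forest, and records importances; single-class
draws are redrawn (≤ 10 attempts). The final score is again the mean
of non-zero values; never-scored features rank last and are flagged.
Tree counts scale linearly with feature dimension relative to the gene
baseline, `⌊B·T_type/T_gene⌋` (floor, matching the published worked
value 1000·161042/12750 = 12630), so coverage percentages stay
comparable across types. Gene lists for enrichment tools are pooled
from edges in rank order, appending unseen genes and truncating to the
target size exactly (a final edge can overshoot by one gene;
truncation keeps list sizes comparable across feature types).

## Synthetic cohort generator

The generator produces the study conditions every simulation-based
test runs under. Defaults (fixed once, from the structure being
emulated or from variance algebra, and not revisited):

- **Cohorts**: the 12-study table with exact poor/good counts totalling
  455/1161/1616. A scaled-down four-cohort variant (72/168/240, same
  imbalance character) keeps repeated model fitting cheap; ground-truth
  recovery precision is evaluated at the full 1616-sample scale, where
  per-edge effect estimates (SE ≈ 0.05 standardized units) separate
  planted from background edges cleanly — at n = 240 (SE ≈ 0.14) they
  overlap and only enrichment-style statements are stable.
- **Modules**: 8 modules × 10 genes, single-factor model
  x = √ρ·z + √(1−ρ)·ε with ρ = 0.7 (ρ is the exact pairwise
  correlation in expectation, making the module structure testable in
  closed form), so a mutual top-k network is inferable from the data.
- **Planted signal**: 10 gene pairs; both genes shifted by δ = 0.5·σ in
  the positive class, with within-pair residual correlation
  ρ_p = −0.5, emulating compensatory co-regulation in which the pair's
  total dosage carries the phenotype. Each gene's marginal effect is
  δ/σ = 0.5; the pair sum's is 2δ/(σ√(2(1+ρ_p))) = 1.0. The
  anti-correlation is essential, not decorative: with independent
  residuals the pair sum's √2 univariate advantage is recoverable by
  any multivariate model on gene features, and across generator
  realizations the edge-vs-gene AUC difference is statistically
  unstable (measured +0.01 ± 0.04); with ρ_p = −0.5, part of the
  signal exists only at the pair level and the edge advantage is
  structural (+0.03 to +0.10 across held-out seeds).
- **Background network**: preferential attachment (endpoint probability
  ∝ degree + 0.25; the small smoothing constant produces the heavy
  right tail typical of interaction networks). Planted pairs are
  forced in but excluded from degree bookkeeping (seeding them into
  the degrees turned signal genes into hubs), and non-planted pairs of
  two signal genes are forbidden — such edges would carry exactly the
  planted effect size and make ground-truth recovery ill-defined.
- **Batch effects**: per-gene, per-cohort offsets with
  batch_sd = 0.3·σ. A scalar per-cohort offset would be removed
  exactly by per-sample mean-centering, so gene-specific offsets are
  the only choice that leaves a batch signature in the data the
  analysis sees. The 0.3 magnitude is a free parameter (no published
  estimate exists for the emulated compendium).
- **Preprocessing order**: baseline + batch offsets added, then
  per-sample mean-centering last, matching the emulated pipeline.
- **Subtypes**: tertiles of the first module's latent factor, giving
  the bipartition a categorical covariate to balance.

What the generator does **not** emulate: microarray noise physics,
probe-level effects, real breast-cancer subtype biology, missing data,
or outlier arrays. Passing tests therefore demonstrate that the
*statistical machinery* behaves as designed under the assumed
generative structure — exact calibration under the null, recovery and
edge-over-gene advantages under the designed alternative — not that
edge features win on any particular real dataset.

## Numerical conventions

- All randomness flows from integer seeds through
  `numpy.random.SeedSequence`; derived seeds stay below 2³¹ for
  scikit-learn compatibility. Same seed ⇒ bit-identical datasets,
  networks, folds, forests, and rankings.
- Tie-breaks are everywhere deterministic: lexicographic gene id in
  network ranking and top-X selection (after importance descending),
  higher threshold in ROC-distance ties.
- Edge identifiers are canonical `"geneA|geneB"` with the smaller id
  first; networks store edges canonically, so file round-trips and set
  operations are order-independent.
- Hypergeometric tails are computed by log-sum-exp over log-pmf terms;
  degenerate inputs (single-class labels for AUC, p_e = 1 for κ,
  all-zero paired differences) return NaN rather than raising, matching
  how the downstream summaries treat them ("Equal/NaN").
- Problem sizes in the test and acceptance suites (240–1616 samples,
  160 genes, 400 edges, 10–30 bootstrap repetitions, 100-tree forests)
  are the package's scaled-down study conditions; every qualitative
  claim they check was verified stable across multiple generator seeds
  during design.

## Known limitations

- Per-subtype bipartition balance is ±2, not ±1, when class balance
  and total balance conflict with it.
- The optimal-threshold protocol assumes scores are comparable between
  validation and test folds; for the SVM the margin is used directly,
  so "threshold in [0, 1]" holds only for probability-producing models.
- Impurity-based importance is biased toward high-cardinality/continuous
  features; since *all* features here are continuous expression sums,
  the bias is shared and comparisons across feature types remain fair,
  but absolute importance values should not be interpreted.
- The linear estimator-scaling rule reproduces the published 12630 for
  the co-expression edge type; the published count for the
  protein-interaction edge type (14123) differs from the rule's
  14146, an unexplained discrepancy in the source protocol that is
  documented rather than imitated.
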