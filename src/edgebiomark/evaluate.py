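"""Classifier benchmarking of feature types with repeated cross-validation.

Three models are supported — random forest (RF, 100 trees by default),
linear-kernel SVM with library defaults, and L1-penalized logistic
regression with the inverse-regularization strength C chosen by an inner
5-fold grid search — and three metrics: AUC (from raw scores), F1 of the
positive (poor-outcome) class, and Cohen's kappa (both from class
predictions).  Class predictions come either from the model's default
decision rule or from an *optimal probability threshold* chosen on a
held-out validation split as the ROC point closest to the perfect
corner:

    distance = sqrt((1 - sensitivity)^2 + (1 - specificity)^2)

Paired t-tests over repetition-level metric values compare feature
types, summarized as Win/Lose x significant/not at alpha = 0.05.

Conventions fixed here: folds are stratified (several cohorts are tiny
and imbalanced; unstratified folds produce single-class test sets); RF
probabilities are the fraction of trees voting positive; the threshold
rule predicts positive when score >= cut; F1 is reported for the
positive class only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "ThresholdSearchResult",
    "MetricVector",
    "ComparisonSummary",
    "auc",
    "f1_and_kappa",
    "optimal_threshold",
    "run_cv",
    "paired_ttest",
    "summarize_comparison",
]

MODELS = ("RF", "SVM", "LR")
DEFAULT_C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol settings.

    ``threshold_mode="default"`` scores class predictions at the model's
    native decision rule; ``"optimal"`` carves a stratified 80/20
    train/validation split out of each repetition's non-test folds, fits
    on the 80%, picks the ROC-corner-distance-minimizing threshold on
    the 20%, and applies it to the test fold.
    """

    n_folds: int = 5
    n_repetitions: int = 100
    model: str = "RF"
    rf_estimators: int = 100
    lr_c_grid: tuple[float, ...] = DEFAULT_C_GRID
    threshold_mode: str = "default"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.threshold_mode not in ("default", "optimal"):
            raise ValueError("threshold_mode must be 'default' or 'optimal'")
        if not self.lr_c_grid:
            raise ValueError("lr_c_grid must be non-empty")


@dataclass(frozen=True)
class ThresholdSearchResult:
    """Chosen probability cut with its validation-set operating point."""

    threshold: float
    sensitivity: float
    specificity: float
    distance: float


@dataclass
class MetricVector:
    """One metric value per cross-validation repetition (mean over folds)."""

    metric: str
    values: np.ndarray
    feature_type: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass(frozen=True)
class ComparisonSummary:
    """Edge-vs-gene outcome for one dataset/metric at alpha = 0.05."""

    outcome: str  # Win-SS | Win-NSS | Lose-SS | Lose-NSS | Equal/NaN
    p_value: float
    mean_difference: float


def _seed_for(*parts: int) -> int:
    """Deterministic 31-bit seed derived from integer parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def auc(probabilities, labels) -> float:
    """Rank-based AUC with ties counted half (Mann-Whitney form).

    Returns NaN when only one class is present.
    """
    scores = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def f1_and_kappa(predictions, labels) -> tuple[float, float]:
    """F1 of the positive class and Cohen's kappa from class predictions.

    F1 is 0 by convention when there are no predicted or no true
    positives; kappa is (p_o - p_e)/(1 - p_e) and NaN when the chance
    agreement p_e is 1 (both vectors constant and identical classes).
    """
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    if tp == 0:
        f1 = 0.0
        if (tp + fp) == 0 or (tp + fn) == 0:
            logger.debug("no predicted or true positives; F1 set to 0 by convention")
    else:
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1 = 2 * precision * recall / (precision + recall)
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = float("nan") if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return float(f1), float(kappa)


def optimal_threshold(val_probabilities, val_labels) -> ThresholdSearchResult:
    """Probability cut minimizing the ROC distance to the perfect corner.

    Every distinct predicted probability is a candidate cut; a sample is
    predicted positive when its probability >= cut.  Ties in distance are
    broken toward the higher threshold (fewer predicted positives).
    """
    scores = np.asarray(val_probabilities, dtype=float)
    y = np.asarray(val_labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("validation set must contain both classes")
    best: ThresholdSearchResult | None = None
    for cut in sorted(set(scores.tolist()), reverse=True):
        pred = scores >= cut
        sens = float((pred & (y == 1)).sum() / n_pos)
        spec = float((~pred & (y == 0)).sum() / n_neg)
        dist = math.sqrt((1.0 - sens) ** 2 + (1.0 - spec) ** 2)
        if best is None or dist < best.distance:
            best = ThresholdSearchResult(float(cut), sens, spec, dist)
    assert best is not None
    return best


def _fit_model(cfg: CVConfig, X, y, seed: int):
    if cfg.model == "RF":
        model = RandomForestClassifier(n_estimators=cfg.rf_estimators, random_state=seed)
    elif cfg.model == "SVM":
        model = SVC(kernel="linear", random_state=seed)
    else:
        inner = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        model = GridSearchCV(
            LogisticRegression(penalty="l1", solver="liblinear", max_iter=1000, random_state=seed),
            {"C": list(cfg.lr_c_grid)},
            cv=inner,
            scoring="roc_auc",
        )
    model.fit(X, y)
    return model


def _scores(cfg: CVConfig, model, X) -> np.ndarray:
    """Positive-class score: RF tree-vote fraction, SVM margin, LR probability."""
    if cfg.model == "RF":
        votes = np.stack([tree.predict(X) for tree in model.estimators_])
        return votes.mean(axis=0)
    if cfg.model == "SVM":
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def run_cv(feature_matrix: FeatureMatrix, labels, cv_config: CVConfig) -> dict[str, MetricVector]:
    """Repeated stratified k-fold CV; returns AUC/F1/Kappa metric vectors.

    Each repetition reshuffles the stratified folds; the metric value
    for a repetition is the mean over its folds.  Repetitions containing
    a single-class fold are skipped (NaN) with a warning.  With
    ``threshold_mode="optimal"`` the cut applied to each test fold is
    chosen purely on that repetition's validation split, so no test
    information leaks into the threshold.
    """
    cfg = cv_config
    X = np.asarray(feature_matrix.values, dtype=float)
    y = np.asarray(labels, dtype=int)
    out = {m: np.full(cfg.n_repetitions, np.nan) for m in ("AUC", "F1", "Kappa")}
    for rep in range(cfg.n_repetitions):
        folds = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=_seed_for(cfg.seed, rep, 1)
        )
        fold_auc, fold_f1, fold_kappa = [], [], []
        skipped = False
        for fold_i, (train_idx, test_idx) in enumerate(folds.split(X, y)):
            if len(set(y[test_idx])) < 2 or len(set(y[train_idx])) < 2:
                logger.warning("repetition %d skipped: single-class fold", rep)
                skipped = True
                break
            model_seed = _seed_for(cfg.seed, rep, 2, fold_i)
            if cfg.threshold_mode == "optimal":
                tr, val = train_test_split(
                    train_idx,
                    test_size=0.2,
                    stratify=y[train_idx],
                    random_state=_seed_for(cfg.seed, rep, 3, fold_i),
                )
                model = _fit_model(cfg, X[tr], y[tr], model_seed)
                cut = optimal_threshold(_scores(cfg, model, X[val]), y[val]).threshold
                test_scores = _scores(cfg, model, X[test_idx])
                pred = (test_scores >= cut).astype(int)
            else:
                model = _fit_model(cfg, X[train_idx], y[train_idx], model_seed)
                test_scores = _scores(cfg, model, X[test_idx])
                pred = np.asarray(model.predict(X[test_idx]), dtype=int)
            fold_auc.append(auc(test_scores, y[test_idx]))
            f1, kappa = f1_and_kappa(pred, y[test_idx])
            fold_f1.append(f1)
            fold_kappa.append(kappa)
        if not skipped:
            out["AUC"][rep] = np.nanmean(fold_auc)
            out["F1"][rep] = np.nanmean(fold_f1)
            out["Kappa"][rep] = np.nanmean(fold_kappa)
    return {
        m: MetricVector(metric=m, values=v, feature_type=feature_matrix.feature_type, model=cfg.model)
        for m, v in out.items()
    }


def paired_ttest(values_a, values_b) -> float:
    """Two-sided paired t-test p-value; NaN when all differences are zero."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired values")
    diff = a - b
    if np.all(diff == 0.0):
        return float("nan")
    return float(stats.ttest_rel(a, b).pvalue)


def summarize_comparison(
    edge_metrics: MetricVector, gene_metrics: MetricVector, alpha: float = 0.05
) -> ComparisonSummary:
    """Classify an edge-vs-gene comparison as Win/Lose x SS/NSS.

    "Win" means the edge feature type outperformed the gene baseline in
    mean metric value; "SS" marks paired-t significance at ``alpha``.
    Identical vectors (or an undefined test) give "Equal/NaN".
    """
    mask = ~(np.isnan(edge_metrics.values) | np.isnan(gene_metrics.values))
    e = edge_metrics.values[mask]
    g = gene_metrics.values[mask]
    p = paired_ttest(e, g)
    delta = float(np.mean(e - g))
    if delta == 0.0 or math.isnan(p):
        outcome = "Equal/NaN"
    else:
        side = "Win" if delta > 0 else "Lose"
        sig = "SS" if p < alpha else "NSS"
        outcome = f"{side}-{sig}"
    return ComparisonSummary(outcome=outcome, p_value=p, mean_difference=delta)
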