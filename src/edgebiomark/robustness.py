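"""Dimensionality-calibrated robustness of feature rankings.

Comparing the stability of top-feature lists across feature types of
very different dimension (thousands of genes vs hundreds of thousands
of edges) is only fair if the *chance-expected* overlap between two top
lists is equalized first.  Selecting the top X of T features twice
independently gives an expected overlap of X^2/T, so for a target
expectation level e the list size is

    X = floor(sqrt(T * e))

Robustness is then the fold enrichment observed/expected of the overlap
between the top-X lists derived from two disjoint, class- and
subtype-balanced halves of the cohort, with an upper-tail hypergeometric
(Fisher) p-value for significance.

Because a random forest scores only the features it happened to sample,
a zero importance means "never sampled", not "unimportant".  Importance
is therefore aggregated over many independently seeded forests on the
same data, and a feature's score is the mean of its *non-zero* values;
features never sampled in any iteration cannot be ranked at all.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.ensemble import RandomForestClassifier

from .dataio import ExpressionDataset
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapDesign",
    "ImportanceProfile",
    "RobustnessResult",
    "DEFAULT_EXPECTATION_LEVELS",
    "DEFAULT_IMPORTANCE_PARAMS",
    "top_feature_count",
    "expected_overlap",
    "overlap_significance",
    "balanced_bipartition",
    "aggregate_importance",
    "top_features",
    "robustness_protocol",
]

#: Expectation levels (expected chance overlaps) used throughout.
DEFAULT_EXPECTATION_LEVELS: tuple[int, ...] = (2, 5, 10, 20, 50)

#: Per-feature-type (n_estimators, n_iterations) for importance
#: aggregation at compendium scale; edge types need more trees and
#: iterations than genes to reach full sampling coverage.
DEFAULT_IMPORTANCE_PARAMS: dict[str, tuple[int, int]] = {
    "gene": (300, 50),
    "CEEdge": (500, 200),
    "PPIEdge": (500, 200),
}


def top_feature_count(total_features: int, expected_overlaps: float) -> int:
    """List size X = floor(sqrt(total * expected)) for a target expectation."""
    if total_features < 0 or expected_overlaps < 0:
        raise ValueError("inputs must be non-negative")
    product = total_features * expected_overlaps
    if float(product).is_integer():
        return math.isqrt(int(product))
    return int(math.floor(math.sqrt(product)))


def expected_overlap(top_x: int, total_features: int) -> float:
    """Chance-expected overlap X^2/T of two independent top-X selections."""
    if total_features <= 0:
        raise ValueError("total_features must be positive")
    if top_x > total_features:
        raise ValueError("top_x cannot exceed total_features")
    return top_x * top_x / total_features


def overlap_significance(total_features: int, x1: int, x2: int, observed: int) -> float:
    """Upper-tail hypergeometric P(overlap >= observed) of two random lists.

    Two independent selections of x1 and x2 features from a universe of
    ``total_features`` share a hypergeometric number of features; the
    tail is summed in log space so extreme significances (p ~ 1e-78 at
    compendium scale) do not underflow.
    """
    if not 0 <= observed <= min(x1, x2) <= total_features:
        raise ValueError(
            f"inconsistent counts: observed={observed}, x1={x1}, x2={x2}, "
            f"total={total_features}"
        )
    if observed == 0:
        return 1.0
    support = np.arange(observed, min(x1, x2) + 1)
    logp = stats.hypergeom.logpmf(support, total_features, x1, x2)
    return float(min(1.0, math.exp(logsumexp(logp))))


@dataclass(frozen=True)
class OverlapDesign:
    """Calibrated list size for one feature type and expectation level."""

    total_features: int
    expected_overlaps: float
    top_x: int = -1

    def __post_init__(self) -> None:
        if self.top_x < 0:
            object.__setattr__(
                self, "top_x", top_feature_count(self.total_features, self.expected_overlaps)
            )

    @property
    def realized_expectation(self) -> float:
        return expected_overlap(self.top_x, self.total_features)


def balanced_bipartition(dataset: ExpressionDataset, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Split samples into two disjoint class/subtype-balanced halves.

    Returns two index arrays into the dataset's sample axis.  Samples
    are shuffled within each (class, subtype) stratum; odd strata donate
    their extra sample to whichever half keeps — in priority order —
    the per-class difference, the overall size difference, and the
    per-subtype difference smallest.  Guarantees: halves disjoint and
    exhaustive, sizes differ by <= 1, per-class counts differ by <= 1.
    """
    rng = np.random.default_rng(seed)
    y = dataset.labels
    sub = dataset.subtype
    strata: dict[tuple[int, str], list[int]] = {}
    for i in range(dataset.n_samples):
        strata.setdefault((int(y[i]), sub[i]), []).append(i)

    class_diff: dict[int, int] = {0: 0, 1: 0}
    subtype_diff: dict[str, int] = {}
    total_diff = 0
    half_a: list[int] = []
    half_b: list[int] = []
    for (label, subtype), members in sorted(strata.items()):
        members = list(members)
        rng.shuffle(members)
        if len(members) == 1:
            logger.warning(
                "stratum (label=%d, subtype=%s) has a single sample", label, subtype
            )
        half = len(members) // 2
        half_a.extend(members[:half])
        half_b.extend(members[half : 2 * half])
        if len(members) % 2:
            extra = members[-1]
            sdiff = subtype_diff.setdefault(subtype, 0)
            cost_a = (abs(class_diff[label] + 1), abs(total_diff + 1), abs(sdiff + 1))
            cost_b = (abs(class_diff[label] - 1), abs(total_diff - 1), abs(sdiff - 1))
            if cost_a <= cost_b:
                half_a.append(extra)
                class_diff[label] += 1
                subtype_diff[subtype] += 1
                total_diff += 1
            else:
                half_b.append(extra)
                class_diff[label] -= 1
                subtype_diff[subtype] -= 1
                total_diff -= 1
    return np.array(sorted(half_a)), np.array(sorted(half_b))


@dataclass
class ImportanceProfile:
    """Aggregated forest importances with sampling-coverage bookkeeping.

    ``mean_nonzero_importance`` is NaN for features never sampled in any
    iteration; ``times_sampled`` counts iterations with a non-zero score.
    """

    feature_ids: list[str]
    mean_nonzero_importance: np.ndarray
    times_sampled: np.ndarray
    n_iterations: int
    n_estimators: int

    @property
    def coverage(self) -> float:
        """Fraction of features scored non-zero in at least one iteration."""
        return float((self.times_sampled > 0).mean())

    @property
    def n_scored(self) -> int:
        return int((self.times_sampled > 0).sum())


def aggregate_importance(
    feature_matrix: FeatureMatrix,
    labels,
    n_estimators: int,
    n_iterations: int,
    seed: int = 0,
) -> ImportanceProfile:
    """Average non-zero impurity importances over repeated forest fits.

    The forest is retrained ``n_iterations`` times on the *same* data
    with per-iteration seeds derived from ``seed``; repeated training
    gives every feature a chance to be sampled.  Seeds are derived so
    that profiles at increasing ``n_iterations`` (same base seed) extend
    each other, making coverage monotone in the iteration count.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")
    X = np.asarray(feature_matrix.values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_features = feature_matrix.n_features
    total = np.zeros(n_features)
    count = np.zeros(n_features, dtype=int)
    for it in range(n_iterations):
        it_seed = int(np.random.SeedSequence([seed, it]).generate_state(1)[0] % (2**31))
        forest = RandomForestClassifier(n_estimators=n_estimators, random_state=it_seed)
        forest.fit(X, y)
        imp = forest.feature_importances_
        nz = imp > 0.0
        total[nz] += imp[nz]
        count += nz
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return ImportanceProfile(
        feature_ids=list(feature_matrix.feature_ids),
        mean_nonzero_importance=mean,
        times_sampled=count,
        n_iterations=n_iterations,
        n_estimators=n_estimators,
    )


def top_features(profile: ImportanceProfile, top_x: int) -> list[str]:
    """Top-X feature ids by mean non-zero importance.

    Never-sampled features cannot be ranked; requesting more features
    than were ever scored is an error whose fix is more iterations.
    Ties are broken by (importance desc, feature id asc).
    """
    if top_x > profile.n_scored:
        raise ValueError(
            f"top_x={top_x} exceeds the {profile.n_scored} features with a "
            "non-zero importance score; increase n_iterations or n_estimators"
        )
    scored = [
        (float(-profile.mean_nonzero_importance[i]), fid)
        for i, fid in enumerate(profile.feature_ids)
        if profile.times_sampled[i] > 0
    ]
    scored.sort()
    return [fid for _, fid in scored[:top_x]]


@dataclass
class RobustnessResult:
    """Per-split overlap ratios and significances at each expectation level.

    ``records`` has one row per (feature_type, level, split) with columns
    observed, expected, ratio, p_value, top_x, total_features;
    ``paired_pvalues`` holds paired t-test p-values of the per-split
    ratio vectors between each edge type and the gene baseline.
    """

    records: pd.DataFrame
    paired_pvalues: pd.DataFrame
    expectation_levels: tuple[float, ...]

    def ratios(self, feature_type: str, level: float) -> np.ndarray:
        rows = self.records[
            (self.records.feature_type == feature_type) & (self.records.level == level)
        ]
        return rows.sort_values("split").ratio.to_numpy()

    def mean_ratio(self, feature_type: str, level: float) -> float:
        return float(self.ratios(feature_type, level).mean())


def robustness_protocol(
    dataset: ExpressionDataset,
    feature_matrices: Mapping[str, FeatureMatrix],
    expectation_levels: Sequence[float] = DEFAULT_EXPECTATION_LEVELS,
    n_splits: int = 20,
    seed: int = 0,
    importance_params: Mapping[str, tuple[int, int]] | None = None,
    baseline_type: str = "gene",
) -> RobustnessResult:
    """Calibrated overlap robustness of several feature types.

    For each of ``n_splits`` balanced bipartitions, an importance
    profile is aggregated on each half for every feature type; at every
    expectation level the calibrated top-X lists from the two halves are
    intersected, giving observed/expected fold enrichment and a
    hypergeometric p-value.  ``importance_params`` maps feature-type
    name to (n_estimators, n_iterations); omitted types fall back to
    :data:`DEFAULT_IMPORTANCE_PARAMS` or (100, 10).
    """
    if any(level <= 0 for level in expectation_levels):
        raise ValueError("expectation levels must be positive")
    params = dict(DEFAULT_IMPORTANCE_PARAMS)
    if importance_params:
        params.update(importance_params)
    rows = []
    for split in range(n_splits):
        split_seed = int(np.random.SeedSequence([seed, split]).generate_state(1)[0] % (2**31))
        idx_a, idx_b = balanced_bipartition(dataset, seed=split_seed)
        assert not set(idx_a.tolist()) & set(idx_b.tolist())
        for name, fm in feature_matrices.items():
            n_estimators, n_iterations = params.get(name, (100, 10))
            profiles = [
                aggregate_importance(
                    fm.subset_samples(idx),
                    dataset.labels[idx],
                    n_estimators=n_estimators,
                    n_iterations=n_iterations,
                    seed=int(
                        np.random.SeedSequence([seed, split, side]).generate_state(1)[0]
                        % (2**31)
                    ),
                )
                for side, idx in ((1, idx_a), (2, idx_b))
            ]
            total = fm.n_features
            for level in expectation_levels:
                top_x = top_feature_count(total, level)
                tops = [set(top_features(p, top_x)) for p in profiles]
                observed = len(tops[0] & tops[1])
                expected = expected_overlap(top_x, total)
                rows.append(
                    {
                        "feature_type": name,
                        "level": level,
                        "split": split,
                        "top_x": top_x,
                        "total_features": total,
                        "observed": observed,
                        "expected": expected,
                        "ratio": observed / expected,
                        "p_value": overlap_significance(total, top_x, top_x, observed),
                    }
                )
    records = pd.DataFrame(rows)

    comparisons = []
    for name in feature_matrices:
        if name == baseline_type or baseline_type not in feature_matrices:
            continue
        for level in expectation_levels:
            a = records[(records.feature_type == name) & (records.level == level)]
            b = records[(records.feature_type == baseline_type) & (records.level == level)]
            diff = a.sort_values("split").ratio.to_numpy() - b.sort_values("split").ratio.to_numpy()
            if np.all(diff == 0.0):
                p = float("nan")
            else:
                p = float(stats.ttest_rel(
                    a.sort_values("split").ratio.to_numpy(),
                    b.sort_values("split").ratio.to_numpy(),
                ).pvalue)
            comparisons.append(
                {"feature_type": name, "level": level, "mean_ratio_difference": float(diff.mean()), "p_value": p}
            )
    paired = pd.DataFrame(comparisons)
    return RobustnessResult(
        records=records,
        paired_pvalues=paired,
        expectation_levels=tuple(expectation_levels),
    )
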