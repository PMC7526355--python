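"""Bootstrapped forest-importance biomarker ranking and gene-list export.

Features are ranked by the mean of their non-zero impurity importances
over many bootstrap refits of a random forest (65% of samples drawn
with replacement per repetition).  Because higher-dimensional feature
types need proportionally more trees for comparable sampling coverage,
the tree count is scaled linearly with the feature count relative to
the gene baseline, e.g. a 1000-tree gene model maps to
round(1000 * 161042 / 12750) = 12630 trees for a 161042-edge type.

For edge feature types a gene-level biomarker list is derived by
walking edges in rank order and pooling unseen genes until the target
list size is reached, so gene- and edge-derived lists are directly
comparable in downstream enrichment tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureMatrix, split_edge_id

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapRankConfig",
    "RankedBiomarkers",
    "scale_estimators",
    "bootstrap_rank",
    "pool_genes_from_edges",
    "export_gene_list",
]


@dataclass(frozen=True)
class BootstrapRankConfig:
    """Bootstrap protocol for importance ranking.

    ``base_estimators`` is the tree count of the gene-baseline model;
    pass ``n_gene_features``/``n_type_features`` to
    :func:`scale_estimators` to get the count for a larger feature type.
    """

    n_repetitions: int = 1000
    sample_fraction: float = 0.65
    with_replacement: bool = True
    base_estimators: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must lie in (0, 1]")
        if self.n_repetitions < 1 or self.base_estimators < 1:
            raise ValueError("counts must be at least 1")


@dataclass
class RankedBiomarkers:
    """Descending-importance feature ranking with derived gene list.

    ``final_importance`` follows ``ranked_feature_ids`` order; features
    never scored in any bootstrap repetition are ranked last and listed
    in ``unscored_feature_ids``.
    """

    ranked_feature_ids: list[str]
    final_importance: np.ndarray
    unscored_feature_ids: list[str]
    feature_type: str
    gene_list: list[str]


def scale_estimators(base_estimators: int, n_gene_features: int, n_type_features: int) -> int:
    """Tree count scaled linearly with feature dimension: floor(B * n_type / n_gene).

    Truncation (not rounding) keeps the convention of the published
    worked example, 1000 * 161042 / 12750 = 12630.
    """
    if base_estimators < 1 or n_gene_features < 1 or n_type_features < 1:
        raise ValueError("counts must be at least 1")
    return base_estimators * n_type_features // n_gene_features


def bootstrap_rank(
    feature_matrix: FeatureMatrix,
    labels,
    config: BootstrapRankConfig | None = None,
    n_estimators: int | None = None,
    gene_list_size: int | None = None,
) -> RankedBiomarkers:
    """Rank features by mean non-zero importance over bootstrap refits.

    Each repetition draws ``ceil(fraction * n)`` samples (with
    replacement by default), refits the forest, and records its
    importances; a draw that happens to contain one class is redrawn
    (up to 10 attempts).  The final score is the mean of the non-zero
    scores; ties are broken by feature id for determinism.  For edge
    feature types a gene list is pooled from the top edges
    (``gene_list_size`` defaults to min(500, distinct genes)).
    """
    cfg = config if config is not None else BootstrapRankConfig()
    X = np.asarray(feature_matrix.values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    n = len(y)
    n_draw = int(np.ceil(cfg.sample_fraction * n))
    trees = n_estimators if n_estimators is not None else cfg.base_estimators
    total = np.zeros(feature_matrix.n_features)
    count = np.zeros(feature_matrix.n_features, dtype=int)
    rng = np.random.default_rng(cfg.seed)
    for rep in range(cfg.n_repetitions):
        for attempt in range(10):
            idx = rng.choice(n, size=n_draw, replace=cfg.with_replacement)
            if len(set(y[idx].tolist())) == 2:
                break
            logger.warning("bootstrap draw %d attempt %d had one class; redrawing", rep, attempt)
        else:
            raise RuntimeError("could not draw a two-class bootstrap sample in 10 attempts")
        it_seed = int(np.random.SeedSequence([cfg.seed, rep]).generate_state(1)[0] % (2**31))
        forest = RandomForestClassifier(n_estimators=trees, random_state=it_seed)
        forest.fit(X[idx], y[idx])
        imp = forest.feature_importances_
        nz = imp > 0.0
        total[nz] += imp[nz]
        count += nz

    score = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    scored_order = sorted(
        (i for i in range(feature_matrix.n_features) if count[i] > 0),
        key=lambda i: (-score[i], feature_matrix.feature_ids[i]),
    )
    unscored = sorted(i for i in range(feature_matrix.n_features) if count[i] == 0)
    order = scored_order + unscored
    ranked_ids = [feature_matrix.feature_ids[i] for i in order]
    unscored_ids = [feature_matrix.feature_ids[i] for i in unscored]
    if unscored_ids:
        logger.info("%d feature(s) never scored; ranked last", len(unscored_ids))

    if feature_matrix.feature_type == "gene":
        target = gene_list_size if gene_list_size is not None else min(500, len(ranked_ids))
        gene_list = ranked_ids[:target]
    else:
        ranked_scored = [feature_matrix.feature_ids[i] for i in scored_order]
        distinct = len({g for fid in ranked_scored for g in split_edge_id(fid)})
        target = gene_list_size if gene_list_size is not None else min(500, distinct)
        gene_list = pool_genes_from_edges(ranked_scored, target)
    return RankedBiomarkers(
        ranked_feature_ids=ranked_ids,
        final_importance=score[order],
        unscored_feature_ids=unscored_ids,
        feature_type=feature_matrix.feature_type,
        gene_list=gene_list,
    )


def pool_genes_from_edges(ranked_edge_ids: Sequence[str], target_gene_count: int) -> list[str]:
    """Pool unseen genes from edges in rank order until the target size.

    The final edge may overshoot by one gene; the list is truncated to
    exactly ``target_gene_count``.  If the ranking contains fewer
    distinct genes than requested, all of them are returned with a
    warning.
    """
    genes: list[str] = []
    seen: set[str] = set()
    for fid in ranked_edge_ids:
        for g in split_edge_id(fid):
            if g not in seen:
                seen.add(g)
                genes.append(g)
        if len(genes) >= target_gene_count:
            return genes[:target_gene_count]
    if len(genes) < target_gene_count:
        logger.warning(
            "only %d distinct genes available for a target of %d",
            len(genes),
            target_gene_count,
        )
    return genes


def export_gene_list(gene_list: Sequence[str], path: str | Path) -> None:
    """Write one gene id per line, preserving rank order."""
    with Path(path).open("w") as fh:
        for g in gene_list:
            fh.write(f"{g}\n")
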