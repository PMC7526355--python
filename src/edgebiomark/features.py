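"""Feature-matrix construction: gene features and edge (gene-pair) features.

A gene feature is a gene's expression profile as-is.  An edge feature is
the per-sample *sum* of the two genes joined by a network edge — the sum
(not the mean) is deliberate: tree models are scale-invariant but
L1-regularized linear models are not, and the sum is the convention this
pipeline is built around.  Edge feature ids are canonical
``"geneA|geneB"`` strings with the lexicographically smaller gene first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import ExpressionDataset, GeneNetwork

__all__ = ["FeatureMatrix", "gene_feature_matrix", "edge_feature_matrix", "edge_id", "split_edge_id"]

FEATURE_TYPES = ("gene", "CEEdge", "PPIEdge")


def edge_id(g1: str, g2: str) -> str:
    """Canonical feature id for an unordered gene pair."""
    return f"{min(g1, g2)}|{max(g1, g2)}"


def split_edge_id(feature_id: str) -> tuple[str, str]:
    g1, g2 = feature_id.split("|")
    return g1, g2


@dataclass
class FeatureMatrix:
    """Samples x features values for a named feature type."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    feature_type: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"feature_type must be one of {FEATURE_TYPES}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature identifiers")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, indices) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[idx].copy(),
            feature_type=self.feature_type,
        )


def gene_feature_matrix(dataset: ExpressionDataset) -> FeatureMatrix:
    """Gene expression as a samples x genes feature matrix."""
    return FeatureMatrix(
        feature_ids=list(dataset.gene_ids),
        sample_ids=list(dataset.sample_ids),
        values=dataset.values.T.copy(),
        feature_type="gene",
    )


def edge_feature_matrix(
    dataset: ExpressionDataset, network: GeneNetwork, feature_type: str = "PPIEdge"
) -> FeatureMatrix:
    """One column per network edge: the sum of the two genes' expression.

    The network must already be restricted to measured genes (see
    :func:`~edgebiomark.dataio.restrict_network`); an edge referencing a
    gene absent from the dataset is an error.  Columns follow the
    canonical sorted edge-id order.
    """
    gene_index = {g: i for i, g in enumerate(dataset.gene_ids)}
    edges = network.sorted_edges()
    missing = [e for e in edges if e[0] not in gene_index or e[1] not in gene_index]
    if missing:
        raise ValueError(
            f"{len(missing)} edge(s) reference unmeasured genes "
            f"(e.g. {missing[0]}); restrict the network first"
        )
    if edges:
        i1 = np.array([gene_index[a] for a, _ in edges])
        i2 = np.array([gene_index[b] for _, b in edges])
        values = (dataset.values[i1] + dataset.values[i2]).T
    else:
        values = np.empty((dataset.n_samples, 0))
    return FeatureMatrix(
        feature_ids=[edge_id(a, b) for a, b in edges],
        sample_ids=list(dataset.sample_ids),
        values=values,
        feature_type=feature_type,
    )
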