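import numpy as np
import pytest

import edgebiomark as eb


@pytest.fixture(scope="session")
def bundle():
    """Scaled-down synthetic bundle shared by simulation-based tests."""
    return eb.default_bundle(seed=1)


@pytest.fixture(scope="session")
def edge_matrix(bundle):
    dataset, network, _ = bundle
    return eb.edge_feature_matrix(dataset, eb.restrict_network(network, dataset))


@pytest.fixture(scope="session")
def gene_matrix(bundle):
    dataset, _, _ = bundle
    return eb.gene_feature_matrix(dataset)


@pytest.fixture()
def tiny_dataset():
    """3 genes x 4 samples with hand-readable values."""
    return eb.ExpressionDataset(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [0.5, -1.0, 2.5, 0.0],
                [2.0, 2.0, 1.0, 3.0],
            ]
        ),
        labels=np.array([1, 0, 1, 0]),
        cohort=["c1", "c1", "c2", "c2"],
        subtype=["S1", "S1", "S2", "S2"],
    )
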