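"""Tabular I/O for expression matrices, sample metadata and gene networks.

All formats are plain TSV so that fixtures and real exports stay
diff-able and language-neutral:

* expression matrix: first column ``gene_id``, remaining columns are
  sample ids, one gene per row, decimal text values;
* metadata: columns ``sample_id``, ``label``, ``cohort``, ``subtype``;
* network: two gene-id columns per row (extra columns ignored), no
  header required; the writer emits the canonical two-column form.

Gene identifiers are opaque strings (probe ids, symbols — whatever the
upstream platform uses); no identifier mapping happens here.  The class
label convention is fixed package-wide: *poor* outcome (event within the
follow-up horizon) is the positive class 1, *good* outcome is 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_LABEL_MAP = {"0": 0, "1": 1, "good": 0, "poor": 1}


@dataclass
class ExpressionDataset:
    """Genes x samples expression values plus per-sample annotations.

    ``values`` is log-scale expression, genes in rows in the order of
    ``gene_ids`` and samples in columns in the order of ``sample_ids``.
    ``labels`` holds 0/1 outcome classes (1 = poor outcome, the positive
    class), ``cohort`` the study each sample came from, and ``subtype``
    an optional categorical annotation ("NA" when absent).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    cohort: list[str]
    subtype: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.subtype:
            self.subtype = ["NA"] * len(self.sample_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("labels length does not match sample count")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if len(self.cohort) != len(self.sample_ids):
            raise ValueError("cohort length does not match sample count")
        if len(self.subtype) != len(self.sample_ids):
            raise ValueError("subtype length does not match sample count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        """Return a dataset restricted to the given sample positions."""
        idx = list(indices)
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx].copy(),
            labels=self.labels[idx].copy(),
            cohort=[self.cohort[i] for i in idx],
            subtype=[self.subtype[i] for i in idx],
        )


def canonical_edge(g1: str, g2: str) -> tuple[str, str]:
    """Order an unordered gene pair lexicographically (smaller id first)."""
    return (g1, g2) if g1 < g2 else (g2, g1)


@dataclass
class GeneNetwork:
    """Undirected, self-edge-free gene network.

    Edges are stored canonically (lexicographically smaller gene first)
    so that set operations and file round-trips are order-independent.
    """

    nodes: set[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        self.edges = {canonical_edge(a, b) for a, b in self.edges}
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge {a!r} is not allowed")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) references a missing node")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)


def _parse_label(raw: object) -> int:
    key = str(raw).strip().lower()
    if key not in _LABEL_MAP:
        raise ValueError(
            f"label {raw!r} not understood; expected 0/1 or good/poor"
        )
    return _LABEL_MAP[key]


def read_expression(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionDataset:
    """Read an expression TSV plus metadata TSV into an :class:`ExpressionDataset`.

    Samples are ordered as in the metadata file.  A sample present in
    only one of the two files is an error, as are duplicate identifiers
    and non-numeric matrix cells.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if matrix.columns[0] != "gene_id":
        raise ValueError("expression matrix must start with a 'gene_id' column")
    gene_ids = matrix["gene_id"].astype(str).tolist()
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene identifiers in expression matrix")
    sample_cols = [str(c) for c in matrix.columns[1:]]
    try:
        values = matrix.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value: {exc}") from exc

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("NA")
    required = {"sample_id", "label", "cohort"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    meta_ids = meta["sample_id"].tolist()
    if len(set(meta_ids)) != len(meta_ids):
        raise ValueError("duplicate sample identifiers in metadata")
    if set(meta_ids) != set(sample_cols):
        only_meta = sorted(set(meta_ids) - set(sample_cols))
        only_matrix = sorted(set(sample_cols) - set(meta_ids))
        raise ValueError(
            "sample sets differ between matrix and metadata: "
            f"metadata-only={only_meta}, matrix-only={only_matrix}"
        )

    order = [sample_cols.index(s) for s in meta_ids]
    labels = np.array([_parse_label(v) for v in meta["label"]], dtype=int)
    subtype = meta["subtype"].tolist() if "subtype" in meta.columns else ["NA"] * len(meta_ids)
    return ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=meta_ids,
        values=values[:, order],
        labels=labels,
        cohort=meta["cohort"].tolist(),
        subtype=subtype,
    )


def write_expression(dataset: ExpressionDataset, matrix_path: str | Path, metadata_path: str | Path) -> None:
    """Write the dataset back to the two-file TSV layout read by :func:`read_expression`."""
    frame = pd.DataFrame(dataset.values, columns=dataset.sample_ids)
    frame.insert(0, "gene_id", dataset.gene_ids)
    frame.to_csv(matrix_path, sep="\t", index=False, float_format="%.17g")
    meta = pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "label": dataset.labels,
            "cohort": dataset.cohort,
            "subtype": dataset.subtype,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_network(edgelist_path: str | Path) -> GeneNetwork:
    """Read a 2+ column TSV edge list into a canonical :class:`GeneNetwork`.

    Self-edges and duplicate (unordered) pairs are dropped silently with
    a logged count; an empty file yields an empty network with a warning.
    """
    path = Path(edgelist_path)
    edges: set[tuple[str, str]] = set()
    n_self = 0
    n_dup = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed edge row {line!r}")
            g1, g2 = parts[0].strip(), parts[1].strip()
            if g1 == g2:
                n_self += 1
                continue
            edge = canonical_edge(g1, g2)
            if edge in edges:
                n_dup += 1
            else:
                edges.add(edge)
    if not edges:
        logger.warning("network file %s contains no edges", path)
    if n_self:
        logger.info("dropped %d self-edge(s) while reading %s", n_self, path)
    if n_dup:
        logger.info("dropped %d duplicate edge(s) while reading %s", n_dup, path)
    nodes = {g for e in edges for g in e}
    return GeneNetwork(nodes=nodes, edges=edges)


def write_network(network: GeneNetwork, edgelist_path: str | Path) -> None:
    """Write edges as a sorted canonical 2-column TSV (no header)."""
    with Path(edgelist_path).open("w") as fh:
        for g1, g2 in network.sorted_edges():
            fh.write(f"{g1}\t{g2}\n")


def restrict_network(network: GeneNetwork, dataset: ExpressionDataset) -> GeneNetwork:
    """Keep only edges whose both genes are measured in the dataset.

    The node set of the result is exactly the genes appearing in at
    least one surviving edge.
    """
    measured = set(dataset.gene_ids)
    edges = {e for e in network.edges if e[0] in measured and e[1] in measured}
    nodes = {g for e in edges for g in e}
    n_dropped = len(network.edges) - len(edges)
    if n_dropped:
        logger.info("restricted network: dropped %d edge(s) with unmeasured genes", n_dropped)
    return GeneNetwork(nodes=nodes, edges=edges)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as headered TSV."""
    frame.to_csv(path, sep="\t", index=False)


def write_provenance(path: str | Path, **entries: object) -> None:
    """Write a JSON sidecar recording seeds and configuration of a run."""
    with Path(path).open("w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
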