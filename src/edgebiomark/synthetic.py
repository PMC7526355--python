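"""Seeded synthetic multi-cohort expression data with planted edge signal.

The generator emulates the statistical structure of a multi-study
breast-cancer metastasis compendium (12 cohorts, 1616 patients, ~28%
poor-outcome class) without attempting to mimic microarray physics:

* exact per-cohort poor/good class counts (defaults reproduce the
  compendium's study table, 455 poor / 1161 good / 1616 total);
* correlated gene modules via a single-factor Gaussian model
  ``x = sqrt(rho) * z_module + sqrt(1 - rho) * eps`` so the within-module
  Pearson correlation is ``rho`` in expectation;
* planted signal carried by gene *pairs*: both genes of a signal edge
  are shifted by ``+delta`` in the poor class, and their residual noise
  is anti-correlated within the pair (``within_pair_correlation`` = rho_p,
  default -0.5, emulating compensatory co-regulation where the pair's
  total dosage is the biologically meaningful quantity).  The pair sum
  then has standardized effect ``2*delta / (sigma*sqrt(2*(1+rho_p)))``
  — 1.0 at the defaults — while each gene alone stays at
  ``delta / sigma`` = 0.5, so part of the class signal is only visible
  at the edge level, the regime edge features are designed for;
* per-gene cohort batch offsets (gene-specific, so they survive
  per-sample centering, as real batch effects do);
* per-sample mean-centering applied last, matching the log-normalized,
  sample-centered preprocessing the analysis assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataio import ExpressionDataset, GeneNetwork, canonical_edge

__all__ = [
    "CohortSpec",
    "SignalPlan",
    "ACES_COHORTS",
    "generate_cohorts",
    "generate_background_network",
    "default_bundle",
    "SMALL_COHORTS",
]


@dataclass(frozen=True)
class CohortSpec:
    """Per-study sample counts: ``n_poor`` positives and ``n_good`` negatives."""

    name: str
    n_poor: int
    n_good: int

    def __post_init__(self) -> None:
        if self.n_poor < 0 or self.n_good < 0:
            raise ValueError("cohort counts must be non-negative")
        if self.n_poor + self.n_good < 1:
            raise ValueError(f"cohort {self.name!r} is empty")

    @property
    def n_total(self) -> int:
        return self.n_poor + self.n_good


#: Study table of the 12-cohort compendium the generator emulates
#: (poor = metastasis/recurrence within 5 years; totals 455/1161/1616).
ACES_COHORTS: tuple[CohortSpec, ...] = (
    CohortSpec("Desmedt", 56, 127),
    CohortSpec("Hatzis", 102, 48),
    CohortSpec("Ivshina", 30, 72),
    CohortSpec("Loi", 24, 33),
    CohortSpec("Pawitan", 33, 114),
    CohortSpec("Miller", 21, 68),
    CohortSpec("Minn", 21, 44),
    CohortSpec("Schmidt", 24, 145),
    CohortSpec("Symmans", 37, 187),
    CohortSpec("WangY", 10, 42),
    CohortSpec("WangYE", 88, 169),
    CohortSpec("Zhang", 9, 112),
)

#: Scaled-down four-cohort layout (72 poor / 168 good / 240 total) with
#: class imbalance comparable to the full table; used for simulation
#: studies where repeated model fitting at full scale would be wasteful.
SMALL_COHORTS: tuple[CohortSpec, ...] = (
    CohortSpec("CohortA", 15, 45),
    CohortSpec("CohortB", 20, 40),
    CohortSpec("CohortC", 25, 35),
    CohortSpec("CohortD", 12, 48),
)


@dataclass(frozen=True)
class SignalPlan:
    """Layout of modules, planted signal edges and noise for a synthetic cohort.

    ``per_gene_shift`` is the class mean shift delta added to each signal
    gene in the poor class, in the same (log-expression) units as
    ``noise_sd``.  ``batch_sd`` scales per-gene cohort offsets; its
    default is 0.3 x ``noise_sd``, a moderate batch effect (no published
    magnitude exists for the emulated compendium, so this is a free
    parameter of the generator).
    """

    n_modules: int = 8
    module_size: int = 10
    within_module_correlation: float = 0.7
    n_signal_edges: int = 10
    per_gene_shift: float = 0.5
    within_pair_correlation: float = -0.5
    noise_sd: float = 1.0
    batch_sd: float = 0.3
    seed: int = 0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_modules < 0 or self.module_size < 0 or self.n_signal_edges < 0:
            raise ValueError("counts must be non-negative")
        if self.n_modules and not 0.0 < self.within_module_correlation < 1.0:
            raise ValueError("within_module_correlation must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not -1.0 < self.within_pair_correlation < 1.0:
            raise ValueError("within_pair_correlation must lie in (-1, 1)")

    @property
    def n_structured_genes(self) -> int:
        return self.n_modules * self.module_size + 2 * self.n_signal_edges


def _signal_gene_slices(plan: SignalPlan) -> tuple[slice, slice]:
    m = plan.n_modules * plan.module_size
    return slice(0, m), slice(m, m + 2 * plan.n_signal_edges)


def signal_edges(gene_ids: Sequence[str], plan: SignalPlan) -> list[tuple[str, str]]:
    """The planted gene pairs, as canonical edges, for a given gene universe."""
    _, sig = _signal_gene_slices(plan)
    genes = list(gene_ids)[sig]
    return [canonical_edge(genes[2 * i], genes[2 * i + 1]) for i in range(plan.n_signal_edges)]


def generate_cohorts(
    gene_ids: Sequence[str],
    cohort_specs: Sequence[CohortSpec] = ACES_COHORTS,
    signal_plan: SignalPlan | None = None,
) -> ExpressionDataset:
    """Generate a seeded multi-cohort dataset with the planned structure.

    Gene layout is deterministic: the first ``n_modules * module_size``
    genes form the co-expressed modules, the next ``2 * n_signal_edges``
    genes carry the planted pair signal (consecutive pairs form the
    signal edges; see :func:`signal_edges`), and the remainder are pure
    noise.  Class counts per cohort are exact.  With a fixed
    ``signal_plan.seed`` the output is bit-reproducible.
    """
    plan = signal_plan if signal_plan is not None else SignalPlan()
    gene_ids = [str(g) for g in gene_ids]
    n_genes = len(gene_ids)
    if plan.n_structured_genes > n_genes:
        raise ValueError(
            f"gene universe of {n_genes} cannot hold "
            f"{plan.n_modules}x{plan.module_size} module genes plus "
            f"{2 * plan.n_signal_edges} signal genes"
        )
    rng = np.random.default_rng(plan.seed)
    mod_slice, sig_slice = _signal_gene_slices(plan)

    baseline = rng.normal(plan.baseline_mean, plan.baseline_sd, size=n_genes)
    batch = rng.normal(0.0, plan.batch_sd, size=(len(cohort_specs), n_genes))

    blocks: list[np.ndarray] = []
    labels: list[int] = []
    cohorts: list[str] = []
    sample_ids: list[str] = []
    factor0: list[np.ndarray] = []
    rho = plan.within_module_correlation
    for c_idx, spec in enumerate(cohort_specs):
        n = spec.n_total
        y = np.concatenate([np.ones(spec.n_poor, int), np.zeros(spec.n_good, int)])
        x = rng.normal(0.0, 1.0, size=(n_genes, n))
        if plan.n_modules:
            z = rng.normal(0.0, 1.0, size=(plan.n_modules, n))
            mod = np.repeat(z, plan.module_size, axis=0)
            x[mod_slice] = math.sqrt(rho) * mod + math.sqrt(1.0 - rho) * x[mod_slice]
            factor0.append(z[0])
        else:
            factor0.append(np.zeros(n))
        if plan.n_signal_edges:
            # mix each pair's iid residuals into anti-correlated ones:
            # corr(a, b) = c1^2 - c2^2 = rho_p, variances stay 1
            rho_p = plan.within_pair_correlation
            c1 = math.sqrt((1.0 + rho_p) / 2.0)
            c2 = math.sqrt((1.0 - rho_p) / 2.0)
            base = sig_slice.start
            for pair in range(plan.n_signal_edges):
                a, b = base + 2 * pair, base + 2 * pair + 1
                w, v = x[a].copy(), x[b].copy()
                x[a] = c1 * w + c2 * v
                x[b] = c1 * w - c2 * v
        x *= plan.noise_sd
        x[sig_slice] += plan.per_gene_shift * y[None, :]
        x += baseline[:, None] + batch[c_idx][:, None]
        blocks.append(x)
        labels.extend(y.tolist())
        cohorts.extend([spec.name] * n)
        sample_ids.extend(f"{spec.name}_s{i:04d}" for i in range(n))

    values = np.concatenate(blocks, axis=1)
    values -= values.mean(axis=0, keepdims=True)  # per-sample mean-centering, last

    f0 = np.concatenate(factor0)
    tertiles = np.quantile(f0, [1 / 3, 2 / 3])
    subtype = np.where(f0 <= tertiles[0], "S1", np.where(f0 <= tertiles[1], "S2", "S3"))

    return ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        labels=np.asarray(labels),
        cohort=cohorts,
        subtype=subtype.tolist(),
    )


def generate_background_network(
    gene_ids: Sequence[str],
    n_edges: int,
    seed: int = 0,
    include_pairs: Sequence[tuple[str, str]] = (),
    forbidden_pairs: Sequence[tuple[str, str]] = (),
) -> GeneNetwork:
    """Heavy-tailed random network via preferential attachment.

    Edges are drawn one at a time with endpoint probability proportional
    to ``degree + 0.25``; the small smoothing constant lets early edges
    concentrate on emerging hubs, producing the heavy-tailed degree
    distribution typical of protein-interaction networks.  Pairs listed
    in ``include_pairs`` are forced into the network (used to guarantee
    planted signal edges are present in the background network);
    ``forbidden_pairs`` are never drawn (used to keep the planted pairs
    the only edges joining two signal genes, so ground-truth recovery
    stays well defined).
    """
    gene_ids = [str(g) for g in gene_ids]
    n_genes = len(gene_ids)
    include = {canonical_edge(a, b) for a, b in include_pairs}
    forbidden = {canonical_edge(a, b) for a, b in forbidden_pairs} - include
    for a, b in include:
        if a == b:
            raise ValueError("include_pairs may not contain self-pairs")
        if a not in set(gene_ids) or b not in set(gene_ids):
            raise ValueError(f"include pair ({a!r}, {b!r}) outside the gene universe")
    max_edges = n_genes * (n_genes - 1) // 2 - len(forbidden)
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds C({n_genes},2)={max_edges}")
    if n_edges < len(include):
        raise ValueError(
            f"n_edges={n_edges} smaller than {len(include)} forced include_pairs"
        )

    rng = np.random.default_rng(seed)
    # Forced pairs are unioned in at the end and kept out of the degree
    # bookkeeping, so they do not bias attachment toward their genes.
    degree = np.zeros(n_genes)
    edges: set[tuple[str, str]] = set(include)
    grown: set[tuple[str, str]] = set()
    while len(grown) + len(include) < n_edges:
        w = degree + 0.25
        u = rng.choice(n_genes, p=w / w.sum())
        w[u] = 0.0
        v = rng.choice(n_genes, p=w / w.sum())
        edge = canonical_edge(gene_ids[u], gene_ids[v])
        if edge in edges or edge in forbidden:
            continue
        edges.add(edge)
        grown.add(edge)
        degree[u] += 1
        degree[v] += 1
    nodes = {g for e in edges for g in e} if edges else set()
    return GeneNetwork(nodes=nodes, edges=edges)


def default_bundle(
    seed: int = 0,
    n_genes: int = 160,
    n_background_edges: int = 400,
    cohort_specs: Sequence[CohortSpec] = SMALL_COHORTS,
    signal_plan: SignalPlan | None = None,
) -> tuple[ExpressionDataset, GeneNetwork, list[tuple[str, str]]]:
    """Scaled-down dataset + background network + planted edge list.

    The bundle keeps the full generator's structure (imbalanced cohorts,
    modules, planted pair signal, batch offsets, centering) at a size
    where repeated cross-validation and importance aggregation run in
    seconds.  Returns ``(dataset, network, planted_edges)`` with the
    planted edges guaranteed present in the network.
    """
    plan = signal_plan if signal_plan is not None else SignalPlan(seed=seed)
    width = len(str(n_genes - 1))
    gene_ids = [f"G{i:0{width}d}" for i in range(n_genes)]
    dataset = generate_cohorts(gene_ids, cohort_specs, plan)
    planted = signal_edges(gene_ids, plan)
    sig_genes = sorted({g for e in planted for g in e})
    confounders = [
        (a, b) for i, a in enumerate(sig_genes) for b in sig_genes[i + 1 :]
    ]
    network = generate_background_network(
        gene_ids,
        n_background_edges,
        seed=seed + 1,
        include_pairs=planted,
        forbidden_pairs=confounders,
    )
    return dataset, network, planted
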