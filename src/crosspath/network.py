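"""Pathway coordination network.

Nodes are (pathway, tissue) pairs. A candidate edge exists only where
biology already suggests one: the two pathways are curated to be linked
(in any tissue combination, including the same tissue), or the two nodes
are the same pathway observed in two different tissues. A candidate
becomes an edge when the Spearman correlation of the two nodes' PCI
profiles across animals exceeds a threshold calibrated by permutation:
gene row labels are shuffled within each tissue, PCIs and all candidate
correlations are recomputed each round, and the pooled absolute
correlations form the empirical null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import ExpressionMatrix, GeneNetwork, PathwayDB, warn
from .pci import PCIMatrix, normalize_expression, pci_from_transformed, sigmoid_transform

logger = logging.getLogger(__name__)

Node = tuple[str, str]  # (pathway, tissue)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    A constant vector has undefined rank correlation; 0 is returned with
    a warning so callers never see NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = rankdata(x), rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warn("constant vector in spearman; returning r=0")
        return 0.0
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _rank_standardize(rows: np.ndarray) -> np.ndarray:
    """Mid-rank each row, center and scale to unit norm (0 rows stay 0)."""
    r = rankdata(rows, axis=1).astype(float)
    r -= r.mean(axis=1, keepdims=True)
    norm = np.sqrt((r * r).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0
    return r / norm


def candidate_pairs(nodes: Sequence[Node], links: set[frozenset[str]],
                    ) -> list[tuple[Node, Node]]:
    """Enumerate candidate node pairs under curated gating.

    Curated-linked pathways pair across every tissue combination
    (including within one tissue); the same pathway pairs across every
    two different tissues. Links naming pathways without any scored node
    are skipped with a warning.
    """
    by_pathway: dict[str, list[Node]] = {}
    for node in nodes:
        by_pathway.setdefault(node[0], []).append(node)

    pairs: set[frozenset[Node]] = set()
    for link in links:
        p, q = sorted(link)
        if p not in by_pathway or q not in by_pathway:
            warn(f"curated link ({p}, {q}) references an unscored pathway; skipped")
            continue
        for a in by_pathway[p]:
            for b in by_pathway[q]:
                pairs.add(frozenset((a, b)))
    for p, plist in by_pathway.items():
        for i in range(len(plist)):
            for j in range(i + 1, len(plist)):
                pairs.add(frozenset((plist[i], plist[j])))
    return [tuple(sorted(fs)) for fs in sorted(pairs, key=lambda fs: tuple(sorted(fs)))]


def candidate_correlations(pci: PCIMatrix, pairs: Sequence[tuple[Node, Node]],
                           animals: Sequence[str] | None = None) -> pd.Series:
    """Spearman r for each candidate pair (vectorized over all pairs)."""
    values = pci.values if animals is None else pci.values[list(animals)]
    z = _rank_standardize(values.to_numpy())
    pos = {node: i for i, node in enumerate(values.index)}
    ia = np.array([pos[a] for a, _ in pairs])
    ib = np.array([pos[b] for _, b in pairs])
    r = np.einsum("ij,ij->i", z[ia], z[ib])
    idx = pd.MultiIndex.from_tuples([(a, b) for a, b in pairs])
    return pd.Series(r, index=idx, name="spearman")


@dataclass
class NullDistribution:
    """Pooled permutation null of absolute candidate correlations."""

    values: np.ndarray  # sorted ascending, in [0, 1]
    n_perm: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size

    def p_value(self, r: float | np.ndarray) -> float | np.ndarray:
        """Empirical upper-tail p with add-one smoothing: never exactly 0."""
        r = np.abs(r)
        n = self.values.size
        ge = n - np.searchsorted(self.values, r, side="left")
        p = (1.0 + ge) / (1.0 + n)
        return float(p) if np.isscalar(r) or np.ndim(r) == 0 else p


def permutation_null(exprs: Mapping[str, ExpressionMatrix], pathways: PathwayDB,
                     network: GeneNetwork, n_perm: int = 1000, *,
                     animals: Sequence[str] | None = None, seed: int = 0,
                     include_diagonal: bool = True, normalize: str = "size",
                     ) -> NullDistribution:
    """Permutation null for the pathway co-expression threshold.

    Each round shuffles gene row labels within each tissue's (already
    z-scored and sigmoid-transformed) matrix, recomputes every PCI and
    every candidate pairwise |Spearman r|, and pools the values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if animals is not None:
        exprs = {t: e.subset_animals(animals) for t, e in exprs.items()}
    rng = np.random.default_rng(seed)

    transformed: dict[str, tuple[np.ndarray, dict[str, int]]] = {}
    for tissue in sorted(exprs):
        e = exprs[tissue]
        h = sigmoid_transform(normalize_expression(e).to_numpy())
        transformed[tissue] = (h, {g: i for i, g in enumerate(e.genes)})
    animal_ids = list(exprs[next(iter(exprs))].animals)

    # cache the dense adjacency per scored (pathway, tissue) node
    subnets: dict[Node, np.ndarray] = {}
    nodes: list[Node] = []
    for pathway in sorted(pathways.members):
        for tissue in sorted(exprs):
            _, gene_idx = transformed[tissue]
            scored = [g for g in pathways.members[pathway] if g in gene_idx]
            if scored:
                subnets[(pathway, tissue)] = network.subnetwork(scored)
                nodes.append((pathway, tissue))
    pairs = candidate_pairs(nodes, pathways.links)
    if not pairs:
        raise ValueError("no candidate pairs to permute")

    pooled = np.empty((n_perm, len(pairs)))
    for k in range(n_perm):
        permuted = {}
        for tissue, (h, gene_idx) in transformed.items():
            perm = rng.permutation(h.shape[0])
            permuted[tissue] = (h[perm], gene_idx)
        pci = pci_from_transformed(permuted, pathways, animal_ids,
                                   include_diagonal=include_diagonal,
                                   normalize=normalize, subnets=subnets)
        pooled[k] = np.abs(candidate_correlations(pci, pairs).to_numpy())
    return NullDistribution(pooled.ravel(), n_perm=n_perm, seed=seed)


def threshold_for_p(null: NullDistribution, p_cut: float) -> float:
    """Smallest |r| whose empirical p-value falls below ``p_cut``.

    With add-one smoothing no statistic can reach p < 1/(1+n); such a
    ``p_cut`` yields +inf with a warning. ``p_cut`` >= 1 admits any
    correlation, i.e. threshold 0.
    """
    if not 0.0 < p_cut:
        raise ValueError("p_cut must be positive")
    if p_cut >= 1.0:
        return 0.0
    v = null.values
    n = v.size
    # p(v[i]) = (1 + n - first_index_of(v[i])) / (1 + n); find smallest passing value
    first = np.searchsorted(v, v, side="left")
    p = (1.0 + n - first) / (1.0 + n)
    passing = np.nonzero(p < p_cut)[0]
    if passing.size == 0:
        warn(f"p_cut={p_cut} unreachable with {n} null draws; threshold = +inf")
        return float("inf")
    return float(v[passing[0]])


def build_network(pci: PCIMatrix, links: set[frozenset[str]], threshold: float, *,
                  animals: Sequence[str] | None = None,
                  null: NullDistribution | None = None) -> nx.Graph:
    """Assemble the pathway coordination network.

    Every scored (pathway, tissue) node is included; a candidate pair
    becomes an edge iff |Spearman r| >= ``threshold``. The signed r (and
    the empirical p when a null is supplied) is stored on the edge.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    nodes = list(pci.values.index)
    pairs = candidate_pairs(nodes, links)
    g = nx.Graph()
    for node in nodes:
        g.add_node(node, pathway=node[0], tissue=node[1])
    if pairs:
        r = candidate_correlations(pci, pairs, animals=animals)
        for (a, b), rv in r.items():
            if abs(rv) >= threshold:
                attrs = {"spearman": float(rv), "kind": "coexpression"}
                if null is not None:
                    attrs["p"] = float(null.p_value(rv))
                g.add_edge(a, b, **attrs)
    g.graph["threshold"] = threshold
    return g
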