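"""Trait-relevant and trait-linking pathways; the merged trait-pathway network.

A (pathway, tissue) node is *relevant* to a trait when the Spearman
correlation between its PCI profile and the trait across animals is
significant against an empirical null built by permuting the trait
vector over animals. A node *links* traits when it satisfies any of
three rules: relevant to two or more traits (direct); relevant to one
trait and adjacent, in the pathway coordination network, to a node
relevant to a different trait (path2); adjacent to nodes whose relevance
jointly covers two different traits (path3 — the node itself need not be
relevant to anything). Relevant and linking nodes, coexpression edges
among them, and trait-relevance edges merge into the trait-pathway
network, which is then refined by dropping weakly attached nodes.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import TraitTable, warn
from .network import Node, NullDistribution, _rank_standardize
from .pci import PCIMatrix

logger = logging.getLogger(__name__)

LINKING_CLASSES = ("direct", "path2", "path3")


def trait_pci_correlations(pci: PCIMatrix, trait: pd.Series) -> pd.Series:
    """Spearman r between every PCI row and one trait (missing dropped)."""
    trait = trait.dropna()
    common = [a for a in pci.animals if a in trait.index]
    if len(common) < 3:
        raise ValueError("need >=3 animals with both PCI and trait values")
    rows = _rank_standardize(pci.values[common].to_numpy())
    t = _rank_standardize(trait.loc[common].to_numpy()[None, :])[0]
    return pd.Series(rows @ t, index=pci.values.index, name="spearman")


def trait_permutation_null(pci: PCIMatrix, trait: pd.Series, n_perm: int = 1000,
                           *, seed: int = 0) -> NullDistribution:
    """Null |r| pooled over all PCI rows, trait permuted over animals."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    trait = trait.dropna()
    common = [a for a in pci.animals if a in trait.index]
    rows = _rank_standardize(pci.values[common].to_numpy())
    t_ranked = rankdata(trait.loc[common].to_numpy())
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(t_ranked) for _ in range(n_perm)])
    perms = _rank_standardize(perms)  # already ranks; this just standardizes
    null = np.abs(rows @ perms.T)  # (rows, n_perm)
    return NullDistribution(null.ravel(), n_perm=n_perm, seed=seed)


def trait_relevant(pci: PCIMatrix, traits: TraitTable, *, p_cut: float = 0.005,
                   n_perm: int = 1000, seed: int = 0,
                   r_threshold: float | None = None,
                   ) -> dict[str, set[Node]]:
    """Relevant (pathway, tissue) nodes per trait.

    Default mode builds a trait-permutation null per trait and keeps
    nodes with empirical p < ``p_cut``; passing ``r_threshold`` switches
    to a fixed absolute-correlation cutoff instead. A constant or
    all-missing trait yields an empty set with a warning.
    """
    out: dict[str, set[Node]] = {}
    for i, name in enumerate(traits.traits):
        vec = traits.trait(name).dropna()
        if vec.empty:
            warn(f"trait {name!r} has no observed values; empty relevant set")
            out[name] = set()
            continue
        if vec.nunique() <= 1:
            warn(f"trait {name!r} is constant; empty relevant set")
            out[name] = set()
            continue
        r = trait_pci_correlations(pci, vec)
        if r_threshold is not None:
            keep = r.index[np.abs(r.to_numpy()) >= r_threshold]
        else:
            null = trait_permutation_null(pci, vec, n_perm, seed=seed + i)
            p = null.p_value(np.abs(r.to_numpy()))
            keep = r.index[p < p_cut]
        out[name] = {tuple(node) for node in keep}
    return out


def classify_linking(relevant: Mapping[str, set[Node]], net: nx.Graph,
                     ) -> dict[Node, set[str]]:
    """Assign each node every trait-linking class it satisfies.

    direct: relevant to >=2 traits. path2: relevant to some trait and
    adjacent to a node relevant to a different trait (both endpoints of
    such a pair are marked). path3: the union of the neighbors' relevance
    covers >=2 distinct traits, regardless of the node's own relevance.
    """
    traits_of: dict[Node, set[str]] = {}
    for trait, nodes in relevant.items():
        for node in nodes:
            traits_of.setdefault(node, set()).add(trait)

    out: dict[Node, set[str]] = {}
    universe = set(net.nodes) | set(traits_of)
    for v in universe:
        classes: set[str] = set()
        own = traits_of.get(v, set())
        if len(own) >= 2:
            classes.add("direct")
        neigh = list(net.neighbors(v)) if v in net else []
        if own:
            for u in neigh:
                if traits_of.get(u, set()) - own:
                    classes.add("path2")
                    break
        covered: set[str] = set()
        for u in neigh:
            covered |= traits_of.get(u, set())
        if len(covered) >= 2:
            classes.add("path3")
        if classes:
            out[v] = classes
    return out


def assemble(relevant: Mapping[str, set[Node]], linking: Mapping[Node, set[str]],
             net: nx.Graph, traits: Sequence[str]) -> nx.Graph:
    """Merge relevance and coexpression into the trait-pathway network.

    Pathway nodes = relevant nodes union linking nodes; coexpression
    edges are the coordination-network edges restricted to that set;
    each trait gains a node with relevance edges to its relevant
    pathways. Traits with no relevant pathway remain isolated nodes.
    """
    tpn = nx.Graph()
    for trait in traits:
        tpn.add_node(trait, kind="trait")
    included: set[Node] = set()
    for nodes in relevant.values():
        included |= set(nodes)
    included |= set(linking)
    for node in included:
        classes = sorted(linking.get(node, set()))
        tpn.add_node(node, kind="pathway", pathway=node[0], tissue=node[1],
                     linking=classes if classes else ["relevant-only"])
    for a, b, attrs in net.edges(data=True):
        if a in included and b in included:
            tpn.add_edge(a, b, **{**attrs, "kind": "coexpression"})
    for trait, nodes in relevant.items():
        for node in nodes:
            tpn.add_edge(trait, node, kind="relevance")
    return tpn


def refine(tpn: nx.Graph, *, max_distance_sum: int = 6, iterate: bool = False,
           ) -> nx.Graph:
    """Prune weakly attached pathway nodes from the merged network.

    One pass: drop pathway nodes of total degree <= 1, then, on the
    remaining graph, drop pathway nodes whose two smallest unweighted
    distances to trait nodes sum to more than ``max_distance_sum``
    (unreachable counts as infinite). Trait nodes are never dropped.
    With ``iterate`` the pass repeats until a fixed point.
    """
    g = tpn.copy()
    trait_nodes = [n for n, d in g.nodes(data=True) if d.get("kind") == "trait"]
    while True:
        low = [n for n in g.nodes if g.nodes[n].get("kind") != "trait" and g.degree(n) <= 1]
        g.remove_nodes_from(low)
        dist: dict = {n: [] for n in g.nodes if g.nodes[n].get("kind") != "trait"}
        for t in trait_nodes:
            if t not in g:
                continue
            lengths = nx.single_source_shortest_path_length(g, t)
            for n, d in lengths.items():
                if n in dist:
                    dist[n].append(d)
        far = []
        for n, ds in dist.items():
            ds.sort()
            if len(ds) < 2 or ds[0] + ds[1] > max_distance_sum:
                far.append(n)
        g.remove_nodes_from(far)
        if not iterate or (not low and not far):
            break
    return g
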