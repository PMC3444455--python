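"""Topological and enrichment analytics for the trait-pathway network.

Covers the descriptive statistics used to characterize the network:
log-binned degree distribution, Brandes betweenness centrality, dense
subregion detection in the style of the MCODE molecular-complex
algorithm, and Fisher exact tests (category representation, interaction
enhancement) with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .data import PATHWAY_CATEGORIES, PathwayDB
from .network import Node, candidate_pairs


# ---------------------------------------------------------------- degree

@dataclass
class DegreeHistogram:
    """Counts of nodes per bin of ln(degree); degree-0 nodes excluded."""

    centers: np.ndarray  # bin centers on the ln(degree) axis
    counts: np.ndarray
    edges: np.ndarray

    def to_frame(self, drop_empty: bool = True) -> pd.DataFrame:
        """Report (center, count, ln count); empty bins omitted by default."""
        df = pd.DataFrame({"ln_degree": self.centers, "count": self.counts})
        if drop_empty:
            df = df[df["count"] > 0].copy()
        df["ln_count"] = np.log(df["count"].to_numpy(dtype=float))
        return df.reset_index(drop=True)


def degree_histogram(net: nx.Graph, n_bins: int = 10) -> DegreeHistogram:
    """Evenly spaced bins on natural-log degree between min and max.

    Bins are half-open [lo, hi) with the last bin closed. All-equal
    degrees collapse into a single degenerate bin holding every node.
    """
    degs = np.array([d for _, d in net.degree() if d >= 1], dtype=float)
    if degs.size == 0:
        raise ValueError("network has no node of degree >= 1")
    logd = np.log(degs)
    lo, hi = logd.min(), logd.max()
    if lo == hi:
        return DegreeHistogram(np.array([lo]), np.array([degs.size]),
                               np.array([lo, hi]))
    counts, edges = np.histogram(logd, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    return DegreeHistogram(centers, counts, edges)


# ------------------------------------------------------------ betweenness

def betweenness(net: nx.Graph) -> dict:
    """Unnormalized betweenness centrality (Brandes' accumulation).

    Each unordered source-target pair is counted once, endpoints are
    excluded, and tied shortest paths split the credit fractionally.
    """
    return nx.betweenness_centrality(net, normalized=False)


# ----------------------------------------------------------------- MCODE

def _core_weight(g: nx.Graph, v) -> float:
    """MCODE vertex weight: highest k-core number of the closed
    neighborhood subgraph times the density of that core."""
    nbhd = set(g.neighbors(v)) | {v}
    sub = g.subgraph(nbhd)
    sub = nx.Graph(sub)
    sub.remove_edges_from(nx.selfloop_edges(sub))
    if sub.number_of_edges() == 0:
        return 0.0
    cores = nx.core_number(sub)
    k = max(cores.values())
    core_nodes = [n for n, c in cores.items() if c >= k]
    core = sub.subgraph(core_nodes)
    n = core.number_of_nodes()
    dens = 0.0 if n < 2 else 2.0 * core.number_of_edges() / (n * (n - 1))
    return k * dens


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    return 0.0 if n < 2 else 2.0 * g.number_of_edges() / (n * (n - 1))


def dense_subregions(net: nx.Graph, vwp: float = 0.2, haircut: bool = True,
                     fluff: bool = False, fluff_density: float = 0.2,
                     ) -> list[nx.Graph]:
    """Densely connected subregions (MCODE-style seed-and-grow).

    Vertices are weighted by their core-clustering coefficient (highest
    k-core number of the closed neighborhood times that core's density).
    Complexes grow outward from the highest-weight unused seed, admitting
    neighbors whose weight is at least (1 - vwp) times the seed weight.
    ``haircut`` iteratively strips members with fewer than two
    within-cluster links; ``fluff`` adds back boundary neighbors whose
    closed-neighborhood density exceeds ``fluff_density``. Clusters are
    returned as subgraph copies ranked by score = density x size.
    """
    if net.number_of_nodes() == 0:
        return []
    if not 0.0 <= vwp < 1.0:
        raise ValueError("vwp must lie in [0, 1)")
    weights = {v: _core_weight(net, v) for v in net.nodes}
    order = sorted(net.nodes, key=lambda v: (-weights[v], str(v)))
    used: set = set()
    clusters: list[set] = []
    for seed in order:
        if seed in used or weights[seed] <= 0:
            continue
        cut = (1.0 - vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for u in net.neighbors(v):
                if u in used or u in members:
                    continue
                if weights[u] >= cut:
                    members.add(u)
                    frontier.append(u)
        used |= members
        clusters.append(members)

    out: list[nx.Graph] = []
    for members in clusters:
        sub = nx.Graph(net.subgraph(members))
        if haircut:
            while True:
                weak = [v for v in sub.nodes if sub.degree(v) < 2]
                if not weak:
                    break
                sub.remove_nodes_from(weak)
        if fluff:
            extra = set()
            for v in list(sub.nodes):
                for u in net.neighbors(v):
                    if u in sub or u in extra:
                        continue
                    nbhd = set(net.neighbors(u)) | {u}
                    if _density(nx.Graph(net.subgraph(nbhd))) > fluff_density:
                        extra.add(u)
            sub = nx.Graph(net.subgraph(set(sub.nodes) | extra))
        if sub.number_of_nodes() >= 2 and sub.number_of_edges() >= 1:
            sub.graph["score"] = _density(sub) * sub.number_of_nodes()
            out.append(sub)
    out.sort(key=lambda g: -g.graph["score"])
    return out


# ------------------------------------------------------ Fisher tests, FDR

def fisher_2x2(a: int, b: int, c: int, d: int, side: str = "greater") -> float:
    """Fisher exact p for [[a, b], [c, d]].

    ``side``: 'greater'/'less' are hypergeometric tails on a; 'two-sided'
    sums point probabilities <= the observed one. All-zero table -> 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be nonnegative integers")
    if a + b + c + d == 0:
        return 1.0
    alternative = {"greater": "greater", "less": "less", "two-sided": "two-sided"}[side]
    return float(fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def category_representation(tpn: nx.Graph, pathway_db: PathwayDB,
                            tissues: Sequence[str], *,
                            universe: str = "all") -> pd.DataFrame:
    """Per (category, tissue) over/under-representation in the network.

    The universe is every (pathway, tissue) pair — all curated pathways
    by default, or only the pathways actually scored (``universe='scored'``
    restricts to pathways appearing as network node candidates is not
    knowable here, so 'scored' restricts to pathways present among tpn
    pathway nodes' pathway universe supplied via pathway_db). Each
    cluster (category ∧ tissue) yields a 2x2 of network membership vs
    cluster membership with both one-sided Fisher p-values.
    """
    in_net = {n for n, d in tpn.nodes(data=True) if d.get("kind") == "pathway"}
    uncategorized = {p for p, _ in in_net} - set(pathway_db.categories)
    if uncategorized:
        raise ValueError(f"pathways without a category label: {sorted(uncategorized)}")
    cats = set(pathway_db.categories.values())
    pathways = pathway_db.pathways
    if universe == "scored":
        scored = {p for p, _ in in_net}
        pathways = [p for p in pathways if p in scored] or pathways
    elif universe != "all":
        raise ValueError("universe must be 'all' or 'scored'")
    universe_pairs = [(p, t) for p in pathways for t in tissues]
    n_universe = len(universe_pairs)
    rows = []
    for cat in sorted(cats):
        cat_paths = {p for p in pathways if pathway_db.categories.get(p) == cat}
        for tissue in tissues:
            cluster = {(p, tissue) for p in cat_paths}
            a = len(cluster & in_net)
            b = len(in_net & set(universe_pairs)) - a
            c = len(cluster) - a
            d = n_universe - a - b - c
            rows.append({
                "category": cat,
                "tissue": tissue,
                "in_network": a,
                "cluster_size": len(cluster),
                "over_p": fisher_2x2(a, b, c, d, "greater"),
                "under_p": fisher_2x2(a, b, c, d, "less"),
            })
    return pd.DataFrame(rows).sort_values("over_p").reset_index(drop=True)


def interaction_enhancement(net: nx.Graph, links: set[frozenset[str]],
                            ) -> pd.DataFrame:
    """Per-node degree enhancement over its curated opportunities.

    For node v with realized degree k_v out of O_v candidate pairs, and
    network totals K edges out of O candidates, tests the 2x2
    [[k_v, O_v - k_v], [K - k_v, (O - O_v) - (K - k_v)]] one-sided
    (greater), then controls FDR by Benjamini-Hochberg. Nodes with no
    candidate opportunity are skipped.
    """
    nodes = list(net.nodes)
    pairs = candidate_pairs(nodes, links)
    opp: dict[Node, int] = {n: 0 for n in nodes}
    for a, b in pairs:
        opp[a] += 1
        opp[b] += 1
    o_total = len(pairs)
    k_total = net.number_of_edges()
    rows = []
    for v in nodes:
        o_v = opp[v]
        if o_v == 0:
            continue
        k_v = net.degree(v)
        a, b = k_v, o_v - k_v
        c = k_total - k_v
        d = (o_total - o_v) - c
        rows.append({
            "pathway": v[0], "tissue": v[1], "degree": k_v,
            "opportunities": o_v,
            "p": fisher_2x2(a, b, max(c, 0), max(d, 0), "greater"),
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["FDR"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("p").reset_index(drop=True)
    return df
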