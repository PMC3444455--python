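"""Summary tables over the trait-pathway network.

Two report shapes recur in this kind of study: the distribution of
trait-linking pathways across tissues (one row per trait, one column per
tissue, a row-total column and a per-tissue total row), and per-group
counts of trait-relevant pathways with a column-mean row. The margin
arithmetic is factored out so the same code summarizes both freshly
computed networks and externally supplied count tables.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .network import Node

TOTAL_COL = "Total"
TOTAL_ROW = "Total each tissue"
MEAN_ROW = "Mean"


def add_linking_margins(cells: pd.DataFrame) -> pd.DataFrame:
    """Row totals plus a column-sum row (grand total in the corner)."""
    out = cells.copy()
    out.insert(0, TOTAL_COL, out.sum(axis=1))
    out.loc[TOTAL_ROW] = out.sum(axis=0)
    return out


def add_mean_row(cells: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Arithmetic column means, rounded, appended as a 'Mean' row."""
    out = cells.astype(float).copy()
    out.loc[MEAN_ROW] = out.mean(axis=0).round(decimals)
    return out


def linked_traits(tpn: nx.Graph, node: Node) -> set[str]:
    """Traits a linking pathway node is attached to.

    Own relevance traits union the relevance traits of coexpression
    neighbors — the traits that participate in whichever linking rule
    the node satisfies.
    """
    own = {u for u in tpn.neighbors(node)
           if tpn.nodes[u].get("kind") == "trait"}
    via = set()
    for u in tpn.neighbors(node):
        if tpn.nodes[u].get("kind") != "pathway":
            continue
        via |= {w for w in tpn.neighbors(u) if tpn.nodes[w].get("kind") == "trait"}
    return own | via


def trait_tissue_distribution(tpn: nx.Graph, *, traits: Sequence[str] | None = None,
                              tissues: Sequence[str] | None = None) -> pd.DataFrame:
    """Trait x tissue counts of linking pathways, with margins.

    A cell counts the linking pathway nodes of that tissue attached to
    that trait; the ``Total`` column sums each trait row and the final
    row sums each tissue column.
    """
    trait_nodes = [n for n, d in tpn.nodes(data=True) if d.get("kind") == "trait"]
    if traits is None:
        traits = sorted(trait_nodes)
    pathway_nodes = [n for n, d in tpn.nodes(data=True)
                     if d.get("kind") == "pathway"
                     and set(d.get("linking", [])) & {"direct", "path2", "path3"}]
    if tissues is None:
        tissues = sorted({n[1] for n in pathway_nodes})
    cells = pd.DataFrame(0, index=list(traits), columns=list(tissues))
    for node in pathway_nodes:
        tissue = node[1]
        if tissue not in cells.columns:
            continue
        for trait in linked_traits(tpn, node):
            if trait in cells.index:
                cells.loc[trait, tissue] += 1
    return add_linking_margins(cells)


def group_relevance_counts(per_group: Mapping[str, Mapping[str, set[Node]]],
                           *, traits: Sequence[str] | None = None) -> pd.DataFrame:
    """Trait x group counts of relevant pathways plus a per-group mean row."""
    groups = list(per_group)
    if traits is None:
        seen: dict[str, None] = {}
        for g in groups:
            for t in per_group[g]:
                seen.setdefault(t)
        traits = list(seen)
    cells = pd.DataFrame(
        {g: [len(per_group[g].get(t, set())) for t in traits] for g in groups},
        index=list(traits),
    )
    return add_mean_row(cells)


def linking_class_sizes(tpn: nx.Graph) -> dict[str, int]:
    """Node counts of the direct / path2 / path3 linking classes."""
    sizes = {"direct": 0, "path2": 0, "path3": 0, "relevant-only": 0}
    for _, d in tpn.nodes(data=True):
        if d.get("kind") != "pathway":
            continue
        for cls in d.get("linking", []):
            sizes[cls] += 1
    return sizes


def relevant_pathway_table(relevant: Mapping[str, set[Node]],
                           linking: Mapping[Node, set[str]],
                           descriptions: Mapping[str, str] | None = None,
                           ) -> pd.DataFrame:
    """Long-form per-trait relevant/linking listing (trait, tissue, pathway)."""
    rows = []
    for trait in sorted(relevant):
        for pathway, tissue in sorted(relevant[trait]):
            rows.append({
                "trait": trait,
                "tissue": tissue,
                "pathway": pathway,
                "description": (descriptions or {}).get(pathway, ""),
                "linking": ",".join(sorted(linking.get((pathway, tissue), set()))),
            })
    return pd.DataFrame(rows, columns=["trait", "tissue", "pathway", "description",
                                       "linking"])
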