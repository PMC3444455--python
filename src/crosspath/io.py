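"""Readers and writers for every on-disk format the pipeline touches.

Plain-text formats throughout: GMT for pathway membership, two-column
TSV for curated pathway links, three-column TSV for the weighted gene
network, one genes x animals TSV per tissue for expression, an animals x
traits TSV, YAML for ground truth and run configs, TSV for PCI matrices
("pathway|tissue" row keys), and SIF / GraphML for networks.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .data import CohortDesign, ExpressionMatrix, GeneNetwork, PathwayDB, TraitTable
from .pci import PCIMatrix
from .simulate import GroundTruth

NODE_SEP = "|"


# ------------------------------------------------------------ pathway db

def write_gmt(path, pathway_db: PathwayDB) -> None:
    with open(path, "w") as fh:
        for pid, genes in pathway_db.members.items():
            desc = pathway_db.descriptions.get(pid, pid)
            fh.write("\t".join([pid, desc, *genes]) + "\n")


def read_gmt(path) -> tuple[dict[str, tuple[str, ...]], dict[str, str]]:
    members: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            members[parts[0]] = tuple(parts[2:])
            descriptions[parts[0]] = parts[1]
    return members, descriptions


def write_links(path, links: set[frozenset[str]]) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(l)) for l in links):
            fh.write(f"{a}\t{b}\n")


def read_links(path) -> set[frozenset[str]]:
    links: set[frozenset[str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            a, b = line.split("\t")[:2]
            links.add(frozenset((a, b)))
    return links


def write_categories(path, categories: Mapping[str, str]) -> None:
    pd.Series(dict(categories), name="category").rename_axis("pathway") \
        .to_csv(path, sep="\t")


def read_categories(path) -> dict[str, str]:
    s = pd.read_csv(path, sep="\t", index_col=0)["category"]
    return s.to_dict()


# ---------------------------------------------------------- gene network

def write_gene_network(path, network: GeneNetwork) -> None:
    with open(path, "w") as fh:
        for gi, gj, w in network.edges():
            fh.write(f"{gi}\t{gj}\t{w:.6g}\n")


def read_gene_network(path, genes: Sequence[str] | None = None) -> GeneNetwork:
    edges = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            gi, gj, w = line.split("\t")[:3]
            edges.append((gi, gj, float(w)))
            seen.update((gi, gj))
    return GeneNetwork(genes if genes is not None else sorted(seen), edges)


# ------------------------------------------------- expression and traits

def write_expression(path, expr: ExpressionMatrix) -> None:
    expr.values.rename_axis("gene").to_csv(path, sep="\t", float_format="%.6g")


def read_expression(path, tissue: str,
                    annotations: pd.DataFrame | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, tissue, annotations=annotations)


def write_traits(path, traits: TraitTable) -> None:
    traits.values.rename_axis("animal").to_csv(path, sep="\t", float_format="%.6g")


def read_traits(path) -> TraitTable:
    return TraitTable(pd.read_csv(path, sep="\t", index_col=0))


# ------------------------------------------------------------ PCI matrix

def write_pci(path, pci: PCIMatrix) -> None:
    df = pci.values.copy()
    df.insert(0, "N", pci.sizes)
    df.index = [f"{p}{NODE_SEP}{t}" for p, t in df.index]
    df.rename_axis("node").to_csv(path, sep="\t", float_format="%.8g")


def read_pci(path) -> PCIMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    sizes = df.pop("N")
    idx = pd.MultiIndex.from_tuples(
        [tuple(s.split(NODE_SEP, 1)) for s in df.index], names=["pathway", "tissue"])
    values = pd.DataFrame(df.to_numpy(), index=idx, columns=df.columns)
    return PCIMatrix(values, pd.Series(sizes.to_numpy(), index=idx, name="N"))


# ----------------------------------------------------------- ground truth

def write_ground_truth(path, gt: GroundTruth) -> None:
    doc = {
        "active_pathways": {g: sorted(v) for g, v in gt.active_pathways.items()},
        "trait_effects": {
            t: [[p, ti, float(e)] for p, ti, e in eff]
            for t, eff in gt.trait_effects.items()
        },
        "noise_sd": float(gt.noise_sd),
        "activity_sd": float(gt.activity_sd),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return GroundTruth(
        active_pathways={g: set(v) for g, v in (doc.get("active_pathways") or {}).items()},
        trait_effects={
            t: [(p, ti, float(e)) for p, ti, e in eff]
            for t, eff in (doc.get("trait_effects") or {}).items()
        },
        noise_sd=float(doc.get("noise_sd", 0.2)),
        activity_sd=float(doc.get("activity_sd", 1.0)),
    )


# --------------------------------------------------------------- fixtures

def write_fixture(directory, pathway_db: PathwayDB, gene_network: GeneNetwork,
                  exprs: Mapping[str, ExpressionMatrix], traits: TraitTable,
                  ground_truth: GroundTruth) -> dict[str, str]:
    """Write the complete input bundle; returns path of each artifact."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "gmt": str(d / "pathways.gmt"),
        "links": str(d / "curated_links.tsv"),
        "categories": str(d / "categories.tsv"),
        "gene_network": str(d / "gene_network.tsv"),
        "traits": str(d / "traits.tsv"),
        "ground_truth": str(d / "ground_truth.yaml"),
    }
    write_gmt(paths["gmt"], pathway_db)
    write_links(paths["links"], pathway_db.links)
    write_categories(paths["categories"], pathway_db.categories)
    write_gene_network(paths["gene_network"], gene_network)
    write_traits(paths["traits"], traits)
    write_ground_truth(paths["ground_truth"], ground_truth)
    for tissue, expr in exprs.items():
        p = str(d / f"expression_{tissue}.tsv")
        write_expression(p, expr)
        paths[f"expression:{tissue}"] = p
    return paths


def read_fixture(directory, design: CohortDesign | None = None,
                 ) -> tuple[PathwayDB, GeneNetwork, dict[str, ExpressionMatrix],
                            TraitTable, GroundTruth]:
    """Read a bundle written by :func:`write_fixture`."""
    d = Path(directory)
    members, descriptions = read_gmt(d / "pathways.gmt")
    links = read_links(d / "curated_links.tsv")
    categories = read_categories(d / "categories.tsv")
    network = read_gene_network(d / "gene_network.tsv")
    db = PathwayDB(members=members, categories=categories, links=links,
                   descriptions=descriptions, genes=tuple(network.genes))
    traits = read_traits(d / "traits.tsv")
    gt = read_ground_truth(d / "ground_truth.yaml")
    ann = design.animals() if design is not None else None
    exprs = {}
    for p in sorted(d.glob("expression_*.tsv")):
        tissue = p.stem[len("expression_"):]
        exprs[tissue] = read_expression(p, tissue, annotations=ann)
    return db, network, exprs, traits, gt


# ---------------------------------------------------------------- network

def _node_id(node) -> str:
    if isinstance(node, tuple):
        return NODE_SEP.join(node)
    return str(node)


def write_sif(path, graph: nx.Graph, default_type: str = "coexpression") -> None:
    """SIF export: one line per edge, isolated nodes as single-column lines."""
    with open(path, "w") as fh:
        for a, b, attrs in graph.edges(data=True):
            kind = attrs.get("kind", default_type)
            fh.write(f"{_node_id(a)}\t{kind}\t{_node_id(b)}\n")
        for node in graph.nodes:
            if graph.degree(node) == 0:
                fh.write(f"{_node_id(node)}\n")


def write_graphml(path, graph: nx.Graph) -> None:
    g = nx.relabel_nodes(graph, {n: _node_id(n) for n in graph.nodes}, copy=True)
    for _, data in g.nodes(data=True):
        if isinstance(data.get("linking"), list):
            data["linking"] = ",".join(data["linking"])
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    mapping = {}
    for n in g.nodes:
        if NODE_SEP in n:
            mapping[n] = tuple(n.split(NODE_SEP, 1))
    return nx.relabel_nodes(g, mapping, copy=True)


def export_network(graph: nx.Graph, path, fmt: str = "sif") -> None:
    fmt = fmt.lower()
    if fmt == "sif":
        write_sif(path, graph)
    elif fmt == "graphml":
        write_graphml(path, graph)
    else:
        raise ValueError(f"unknown network format {fmt!r}; use 'sif' or 'graphml'")


# ----------------------------------------------------------------- config

def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "p_cut" in cfg and not (0.0 < float(cfg["p_cut"]) < 1.0):
        raise ValueError("p_cut must lie in (0, 1)")
    return cfg


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
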