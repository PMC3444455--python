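"""Model/Results facade over the whole pipeline.

``TraitPathwayModel`` bundles the four inputs (per-tissue expression,
traits, pathway database, gene network); ``fit`` runs PCI scoring,
permutation calibration, network construction, trait relevance and
linking, assembly and refinement, and returns a ``TraitPathwayResults``
carrying every intermediate plus the topology and reporting methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from . import io as cio
from . import network as cnet
from . import reporting, topology
from . import traits as ctraits
from .data import (
    CohortDesign,
    ExpressionMatrix,
    GeneNetwork,
    PathwayDB,
    TraitTable,
    check_shared_animals,
)
from .pci import PCIMatrix, pci_matrix

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Tunable knobs of one pipeline run."""

    p_cut: float = 0.005
    n_perm: int = 1000
    trait_n_perm: int = 1000
    seed: int = 0
    animals: tuple[str, ...] | None = None  # None = all animals (global network)
    threshold: float | None = None  # fixed |r| cutoff; None = permutation-calibrated
    trait_r_threshold: float | None = None
    include_diagonal: bool = True
    normalize: str = "size"
    max_distance_sum: int = 6
    iterate_refinement: bool = False


class TraitPathwayModel:
    """Cross-tissue trait-pathway network model.

    Parameters
    ----------
    expressions : mapping tissue -> ExpressionMatrix
    traits : TraitTable
    pathway_db : PathwayDB
    gene_network : GeneNetwork
    """

    def __init__(self, expressions: Mapping[str, ExpressionMatrix],
                 traits: TraitTable, pathway_db: PathwayDB,
                 gene_network: GeneNetwork):
        self.expressions = dict(expressions)
        self.traits = traits
        self.pathway_db = pathway_db
        self.gene_network = gene_network
        check_shared_animals(self.expressions)

    @classmethod
    def from_fixture(cls, directory, design: CohortDesign | None = None,
                     ) -> "TraitPathwayModel":
        db, gnet, exprs, traits, _gt = cio.read_fixture(directory, design)
        return cls(exprs, traits, db, gnet)

    @property
    def tissues(self) -> list[str]:
        return sorted(self.expressions)

    def fit(self, *, p_cut: float = 0.005, n_perm: int = 1000,
            trait_n_perm: int | None = None, seed: int = 0,
            animals: Sequence[str] | None = None,
            threshold: float | None = None,
            trait_r_threshold: float | None = None,
            include_diagonal: bool = True, normalize: str = "size",
            max_distance_sum: int = 6, iterate_refinement: bool = False,
            ) -> "TraitPathwayResults":
        """Run the full pipeline and return the fitted results.

        With ``animals`` the run is group-specific: expression is
        re-normalized within the subset before scoring. ``threshold``
        short-circuits the permutation calibration with a fixed |r|
        cutoff (e.g. 0.7 for 5-animal groups, 0.4 for the full cohort).
        """
        cfg = FitConfig(p_cut=p_cut, n_perm=n_perm,
                        trait_n_perm=n_perm if trait_n_perm is None else trait_n_perm,
                        seed=seed,
                        animals=tuple(animals) if animals is not None else None,
                        threshold=threshold, trait_r_threshold=trait_r_threshold,
                        include_diagonal=include_diagonal, normalize=normalize,
                        max_distance_sum=max_distance_sum,
                        iterate_refinement=iterate_refinement)

        pci = pci_matrix(self.expressions, self.pathway_db, self.gene_network,
                         animals=animals, include_diagonal=include_diagonal,
                         normalize=normalize)
        null = None
        if threshold is None:
            null = cnet.permutation_null(
                self.expressions, self.pathway_db, self.gene_network, n_perm,
                animals=animals, seed=seed, include_diagonal=include_diagonal,
                normalize=normalize)
            threshold = cnet.threshold_for_p(null, p_cut)
        net = cnet.build_network(pci, self.pathway_db.links, threshold, null=null)

        trait_table = self.traits
        if animals is not None:
            trait_table = TraitTable(self.traits.values.loc[list(animals)])
        relevant = ctraits.trait_relevant(
            pci, trait_table, p_cut=p_cut, n_perm=cfg.trait_n_perm, seed=seed,
            r_threshold=trait_r_threshold)
        linking = ctraits.classify_linking(relevant, net)
        tpn = ctraits.assemble(relevant, linking, net, trait_table.traits)
        refined = ctraits.refine(tpn, max_distance_sum=max_distance_sum,
                                 iterate=iterate_refinement)
        return TraitPathwayResults(model=self, config=cfg, pci=pci, null=null,
                                   threshold=threshold, network=net,
                                   relevant=relevant, linking=linking,
                                   trait_pathway_network=tpn, refined=refined)


@dataclass
class TraitPathwayResults:
    """Everything a fitted run produced.

    Attributes
    ----------
    pci : PCIMatrix
        (pathway, tissue) x animal activity scores.
    null : NullDistribution or None
        Pooled permutation null behind the correlation threshold.
    threshold : float
        Absolute Spearman cutoff actually applied.
    network : networkx.Graph
        Pathway coordination network (curated-gated coexpression edges).
    relevant : dict trait -> set of (pathway, tissue)
    linking : dict (pathway, tissue) -> set of linking classes
    trait_pathway_network / refined : networkx.Graph
        Merged network before and after refinement.
    """

    model: TraitPathwayModel
    config: FitConfig
    pci: PCIMatrix
    null: cnet.NullDistribution | None
    threshold: float
    network: nx.Graph
    relevant: dict[str, set[cnet.Node]]
    linking: dict[cnet.Node, set[str]]
    trait_pathway_network: nx.Graph
    refined: nx.Graph
    _cache: dict = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------ topology

    def degree_histogram(self, n_bins: int = 10) -> topology.DegreeHistogram:
        return topology.degree_histogram(self.refined, n_bins)

    def betweenness(self) -> pd.Series:
        b = topology.betweenness(self.refined)
        return pd.Series(b).sort_values(ascending=False)

    def dense_subregions(self, **kwargs) -> list[nx.Graph]:
        return topology.dense_subregions(self.refined, **kwargs)

    def category_representation(self, **kwargs) -> pd.DataFrame:
        return topology.category_representation(
            self.refined, self.model.pathway_db, self.model.tissues, **kwargs)

    def interaction_enhancement(self) -> pd.DataFrame:
        return topology.interaction_enhancement(self.network,
                                                self.model.pathway_db.links)

    # ----------------------------------------------------------- reporting

    def trait_tissue_distribution(self) -> pd.DataFrame:
        return reporting.trait_tissue_distribution(
            self.refined, traits=self.model.traits.traits,
            tissues=self.model.tissues)

    def relevant_counts(self) -> pd.Series:
        return pd.Series({t: len(s) for t, s in self.relevant.items()},
                         name="relevant_pathways")

    def export_network(self, path, fmt: str = "sif", *, refined: bool = True) -> None:
        cio.export_network(self.refined if refined else self.trait_pathway_network,
                           path, fmt)

    def plot_degree_distribution(self, ax=None):
        """ln-ln degree distribution plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        hist = self.degree_histogram().to_frame()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(hist["ln_degree"], hist["ln_count"], "o-")
        ax.set_xlabel("ln(degree)")
        ax.set_ylabel("ln(count)")
        return ax

    # ------------------------------------------------------------- summary

    def summary(self) -> str:
        """Human-readable run summary."""
        cls_sizes = reporting.linking_class_sizes(self.refined)
        lines = [
            "Cross-tissue trait-pathway network",
            "==================================",
            f"tissues:               {', '.join(self.model.tissues)}",
            f"animals:               {len(self.pci.animals)}",
            f"(pathway,tissue) rows: {len(self.pci.nodes)}",
            f"|r| threshold:         {self.threshold:.4g}"
            + (f"  (p<{self.config.p_cut}, {self.config.n_perm} permutations)"
               if self.null is not None else "  (fixed)"),
            f"coordination network:  {self.network.number_of_nodes()} nodes, "
            f"{self.network.number_of_edges()} edges",
            f"merged trait-pathway:  {self.trait_pathway_network.number_of_nodes()} nodes, "
            f"{self.trait_pathway_network.number_of_edges()} edges",
            f"refined:               {self.refined.number_of_nodes()} nodes, "
            f"{self.refined.number_of_edges()} edges",
            "",
            "trait-relevant pathways:",
        ]
        for trait, n in self.relevant_counts().items():
            lines.append(f"  {trait:<14} {n}")
        lines.append("")
        lines.append(
            "linking classes (refined): "
            + ", ".join(f"{k}={v}" for k, v in cls_sizes.items()))
        return "\n".join(lines)
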