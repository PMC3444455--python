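"""Core data containers shared across the pipeline.

The pipeline operates on four kinds of input: per-tissue expression
matrices (log10 ratios, genes x animals), a table of quantitative traits
per animal, a pathway membership database with curated pathway-pathway
links, and a weighted gene functional-interaction network whose weights
are probabilities of functional linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse


class ConsistencyError(ValueError):
    """Raised when related inputs disagree (animal sets, gene ids, ...)."""


PATHWAY_CATEGORIES = (
    "Metabolism",
    "Genetic information processing",
    "Environmental information processing",
    "Cellular processes",
    "Human diseases",
)


@dataclass(frozen=True)
class CohortDesign:
    """Factorial animal cohort: strains x obesity x ages x replicates.

    Every animal is profiled in every tissue; the default emulates a
    2 strains x 2 obesity states x 2 ages x 5 replicates design (40
    animals) across six tissues.
    """

    strains: tuple[str, ...] = ("B6", "BTBR")
    obesity: tuple[str, ...] = ("ob", "lean")
    ages: tuple[str, ...] = ("4wk", "10wk")
    replicates: int = 5
    tissues: tuple[str, ...] = (
        "Adipose",
        "Gastrocnemius",
        "Hypothalamus",
        "Islet",
        "Liver",
        "Soleus",
    )

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")
        if not self.tissues:
            raise ValueError("at least one tissue is required")

    @property
    def n_animals(self) -> int:
        return len(self.strains) * len(self.obesity) * len(self.ages) * self.replicates

    @property
    def groups(self) -> list[str]:
        """Group labels in strain-obesity-age form, e.g. ``B6-ob-4wk``."""
        return [
            f"{s}-{o}-{a}"
            for s in self.strains
            for o in self.obesity
            for a in self.ages
        ]

    def animals(self) -> pd.DataFrame:
        """Animal annotation table indexed by animal id."""
        rows = []
        for s in self.strains:
            for o in self.obesity:
                for a in self.ages:
                    for r in range(1, self.replicates + 1):
                        rows.append(
                            {
                                "animal": f"{s}-{o}-{a}-r{r}",
                                "strain": s,
                                "obesity": o,
                                "age": a,
                                "replicate": r,
                                "group": f"{s}-{o}-{a}",
                            }
                        )
        return pd.DataFrame(rows).set_index("animal")

    def group_animals(self, group: str) -> list[str]:
        ann = self.animals()
        ids = ann.index[ann["group"] == group].tolist()
        if not ids:
            raise KeyError(f"unknown group {group!r}")
        return ids


@dataclass
class ExpressionMatrix:
    """Log-ratio expression for one tissue: genes x animals.

    ``values`` is a DataFrame with gene ids as the index and animal ids
    as columns; ``annotations`` (optional) carries strain/obesity/age/
    replicate per animal.
    """

    values: pd.DataFrame
    tissue: str
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ConsistencyError(f"duplicate gene ids in tissue {self.tissue!r}")
        if self.values.shape[1] < 2:
            raise ConsistencyError("need >=2 animals for per-gene variance")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def animals(self) -> pd.Index:
        return self.values.columns

    def subset_animals(self, animals: Sequence[str]) -> "ExpressionMatrix":
        missing = [a for a in animals if a not in self.values.columns]
        if missing:
            raise ConsistencyError(f"animals absent from tissue {self.tissue!r}: {missing}")
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[list(animals)]
        return ExpressionMatrix(self.values[list(animals)], self.tissue, ann)


@dataclass
class PathwayDB:
    """Pathway membership, category labels, and curated pathway links."""

    members: dict[str, tuple[str, ...]]
    categories: dict[str, str]
    links: set[frozenset[str]] = field(default_factory=set)
    descriptions: dict[str, str] = field(default_factory=dict)
    genes: tuple[str, ...] | None = None  # full gene universe, if larger than the union

    def __post_init__(self) -> None:
        for link in self.links:
            if len(link) != 2:
                raise ConsistencyError(f"curated link must join two distinct pathways: {set(link)}")
        unknown = {p for link in self.links for p in link} - set(self.members)
        if unknown:
            raise ConsistencyError(f"curated links reference unknown pathways: {sorted(unknown)}")

    @property
    def pathways(self) -> list[str]:
        return list(self.members)

    @property
    def gene_universe(self) -> tuple[str, ...]:
        if self.genes is not None:
            return self.genes
        seen: dict[str, None] = {}
        for genes in self.members.values():
            for g in genes:
                seen.setdefault(g)
        return tuple(seen)

    def size(self, pathway: str) -> int:
        return len(self.members[pathway])


class GeneNetwork:
    """Symmetric gene-gene functional-linkage probabilities.

    Stored weights are in (0, 1]; an absent pair means probability 0.
    Self-links are never stored: the diagonal is the business of the
    pathway-activity score, which fixes a_ii = 1.
    """

    def __init__(self, genes: Sequence[str], edges: Iterable[tuple[str, str, float]]):
        self._genes = list(genes)
        self._index = {g: i for i, g in enumerate(self._genes)}
        if len(self._index) != len(self._genes):
            raise ConsistencyError("duplicate gene ids in GeneNetwork")
        rows, cols, vals = [], [], []
        for gi, gj, w in edges:
            if gi == gj:
                continue
            try:
                i, j = self._index[gi], self._index[gj]
            except KeyError as exc:
                raise ConsistencyError(f"edge references unknown gene {exc.args[0]!r}") from exc
            if not (0.0 < w <= 1.0):
                raise ValueError(f"link probability must lie in (0,1], got {w} for ({gi},{gj})")
            rows.extend((i, j))
            cols.extend((j, i))
            vals.extend((w, w))
        n = len(self._genes)
        mat = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
        # duplicate entries (e.g. both orientations supplied) collapse to the max
        mat.sum_duplicates()
        self._adj = mat.tocsr()

    @property
    def genes(self) -> list[str]:
        return list(self._genes)

    @property
    def n_edges(self) -> int:
        return self._adj.nnz // 2

    def weight(self, gi: str, gj: str) -> float:
        if gi not in self._index or gj not in self._index:
            return 0.0
        return float(self._adj[self._index[gi], self._index[gj]])

    def subnetwork(self, genes: Sequence[str]) -> np.ndarray:
        """Dense adjacency for ``genes`` (zero diagonal).

        Genes absent from the network get all-zero rows: they will only
        contribute their diagonal term to the pathway score.
        """
        idx = np.array([self._index.get(g, -1) for g in genes])
        k = len(genes)
        out = np.zeros((k, k))
        present = np.flatnonzero(idx >= 0)
        if present.size:
            sub = self._adj[np.ix_(idx[present], idx[present])].toarray()
            out[np.ix_(present, present)] = sub
        return out

    def edges(self) -> list[tuple[str, str, float]]:
        coo = sparse.triu(self._adj, k=1).tocoo()
        return [
            (self._genes[i], self._genes[j], float(v))
            for i, j, v in zip(coo.row, coo.col, coo.data)
        ]


@dataclass
class TraitTable:
    """Quantitative traits per animal (animals x traits); NaN = missing."""

    values: pd.DataFrame

    DEFAULT_TRAITS = (
        "glucose",
        "insulin",
        "islets",
        "weight",
        "TG",
        "adiponectin",
        "PAI1",
        "resistin",
    )

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    @property
    def animals(self) -> pd.Index:
        return self.values.index

    def trait(self, name: str) -> pd.Series:
        return self.values[name]


def check_shared_animals(exprs: Mapping[str, ExpressionMatrix]) -> pd.Index:
    """All tissues must profile the same animal set; returns that set."""
    tissues = list(exprs)
    if not tissues:
        raise ConsistencyError("no expression matrices supplied")
    ref = exprs[tissues[0]].animals
    for t in tissues[1:]:
        if set(exprs[t].animals) != set(ref):
            raise ConsistencyError(f"animal sets differ between tissues {tissues[0]!r} and {t!r}")
    return ref


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
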