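"""Pathway Connectivity Index (PCI).

The PCI scores the activity state of a pathway in one tissue of one
animal by combining every member gene's expression with the topology of
the gene functional-interaction network. Per-gene log-ratio expression
is z-scored across the animals of a tissue, squashed through a centered
sigmoid h = 1/(1+e^(-z)) - 1/2 in (-1/2, 1/2), and summed over gene
pairs:

    PCI = (1/N) * sum_{i<=j in pathway} sgn(h_i + h_j) * sqrt|h_i| * a_ij * sqrt|h_j|

with a_ii = 1 on the diagonal and a_ij the probability of functional
linkage between genes i and j (0 when unlinked). N is the number of
scored member genes. The sign term records whether the pair is jointly
up- or down-regulated; the square-root magnitudes damp extreme values;
hub genes, having more and stronger links, contribute more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ConsistencyError, ExpressionMatrix, GeneNetwork, PathwayDB, check_shared_animals

logger = logging.getLogger(__name__)


def normalize_expression(expr: ExpressionMatrix, ddof: int = 1) -> pd.DataFrame:
    """Z-score each gene across the animals of this tissue.

    Uses the sample (n-1) standard deviation. A zero-variance gene is
    mapped to an all-zero row (it carries no between-animal signal) with
    a logged warning.
    """
    vals = expr.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning(
            "tissue %s: %d zero-variance gene(s) z-scored to all-zero rows",
            expr.tissue,
            int(flat.sum()),
        )
        sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mean) / sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns)


def sigmoid_transform(z: np.ndarray | float) -> np.ndarray | float:
    """Centered logistic squashing: h = expit(z) - 1/2, odd, in (-1/2, 1/2)."""
    return expit(z) - 0.5


@dataclass
class PCIMatrix:
    """PCI values for every (pathway, tissue) node x animal.

    ``values`` is a DataFrame with a 2-level (pathway, tissue) MultiIndex
    and animal columns; ``sizes`` records the number of scored genes N
    per row.
    """

    values: pd.DataFrame
    sizes: pd.Series

    @property
    def nodes(self) -> list[tuple[str, str]]:
        return list(self.values.index)

    @property
    def animals(self) -> pd.Index:
        return self.values.columns

    def row(self, pathway: str, tissue: str) -> pd.Series:
        return self.values.loc[(pathway, tissue)]


def _pairwise_pci(h: np.ndarray, adj: np.ndarray, *, include_diagonal: bool,
                  normalize: str) -> np.ndarray:
    """Vectorized PCI for one pathway across animals.

    h: (N genes, n animals) transformed values; adj: (N, N) symmetric
    link probabilities with zero diagonal. Returns an n-vector.
    """
    n_genes = h.shape[0]
    a = adj.copy()
    if include_diagonal:
        np.fill_diagonal(a, 1.0)
    u = np.sqrt(np.abs(h))  # (N, n)
    sgn = np.sign(h[:, None, :] + h[None, :, :])  # (N, N, n)
    prod = sgn * (u[:, None, :] * u[None, :, :]) * a[:, :, None]
    iu = np.triu_indices(n_genes, k=0 if include_diagonal else 1)
    total = prod[iu].sum(axis=0)
    if normalize == "size":
        denom = n_genes
    elif normalize == "pairs":
        denom = n_genes * (n_genes + 1) / 2 if include_diagonal else max(
            n_genes * (n_genes - 1) / 2, 1
        )
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return total / denom


def compute_pci(h: Mapping[str, float] | pd.Series, members: Sequence[str],
                network: GeneNetwork, *, include_diagonal: bool = True,
                normalize: str = "size") -> float:
    """PCI of one pathway for one animal.

    ``h`` maps gene id -> centered-sigmoid value; members absent from
    ``h`` are dropped and N counts only the scored genes. Genes missing
    from the interaction network contribute only their diagonal term.
    """
    h = pd.Series(h)
    scored = [g for g in members if g in h.index]
    if not scored:
        raise ValueError("pathway has no member with expression data")
    hv = h.loc[scored].to_numpy(dtype=float)[:, None]
    adj = network.subnetwork(scored)
    return float(
        _pairwise_pci(hv, adj, include_diagonal=include_diagonal, normalize=normalize)[0]
    )


def pci_matrix(exprs: Mapping[str, ExpressionMatrix], pathways: PathwayDB,
               network: GeneNetwork, *, animals: Sequence[str] | None = None,
               include_diagonal: bool = True, normalize: str = "size") -> PCIMatrix:
    """PCI of every pathway in every tissue for every animal.

    When ``animals`` is given, expression is re-normalized within that
    subset before scoring, so group-specific networks are self-contained.
    Rows are ordered lexicographically by (pathway, tissue); pathways
    with no expressed member in a tissue are skipped with a warning.
    """
    shared = check_shared_animals(exprs)
    if animals is not None:
        exprs = {t: e.subset_animals(animals) for t, e in exprs.items()}
        shared = exprs[next(iter(exprs))].animals

    # per tissue: transformed matrix + gene index lookup
    transformed: dict[str, tuple[np.ndarray, dict[str, int]]] = {}
    for tissue in sorted(exprs):
        e = exprs[tissue]
        z = normalize_expression(e).to_numpy()
        h = sigmoid_transform(z)
        transformed[tissue] = (h, {g: i for i, g in enumerate(e.genes)})

    rows, sizes, index = [], [], []
    for pathway in sorted(pathways.members):
        members = pathways.members[pathway]
        for tissue in sorted(exprs):
            h_all, gene_idx = transformed[tissue]
            scored = [g for g in members if g in gene_idx]
            if not scored:
                logger.warning("pathway %s has no expressed member in tissue %s; skipped",
                               pathway, tissue)
                continue
            h = h_all[[gene_idx[g] for g in scored], :]
            adj = network.subnetwork(scored)
            rows.append(_pairwise_pci(h, adj, include_diagonal=include_diagonal,
                                      normalize=normalize))
            sizes.append(len(scored))
            index.append((pathway, tissue))

    if not rows:
        raise ConsistencyError("no (pathway, tissue) node could be scored")
    midx = pd.MultiIndex.from_tuples(index, names=["pathway", "tissue"])
    # column order follows the (shared) animal order of the input matrices
    cols = list(shared)
    values = pd.DataFrame(np.vstack(rows), index=midx, columns=cols)
    return PCIMatrix(values, pd.Series(sizes, index=midx, name="N"))


def pci_from_transformed(h_by_tissue: Mapping[str, tuple[np.ndarray, dict[str, int]]],
                         pathways: PathwayDB, animal_ids: Sequence[str], *,
                         include_diagonal: bool = True, normalize: str = "size",
                         network: GeneNetwork | None = None,
                         subnets: Mapping[tuple[str, str], np.ndarray] | None = None,
                         ) -> PCIMatrix:
    """PCI from pre-transformed per-tissue matrices (permutation fast path).

    ``subnets`` may cache the dense per-(pathway, tissue) adjacency so a
    permutation loop does not re-slice the sparse network each round.
    """
    rows, sizes, index = [], [], []
    for pathway in sorted(pathways.members):
        members = pathways.members[pathway]
        for tissue in sorted(h_by_tissue):
            h_all, gene_idx = h_by_tissue[tissue]
            scored = [g for g in members if g in gene_idx]
            if not scored:
                continue
            h = h_all[[gene_idx[g] for g in scored], :]
            if subnets is not None:
                adj = subnets[(pathway, tissue)]
            else:
                assert network is not None
                adj = network.subnetwork(scored)
            rows.append(_pairwise_pci(h, adj, include_diagonal=include_diagonal,
                                      normalize=normalize))
            sizes.append(len(scored))
            index.append((pathway, tissue))
    midx = pd.MultiIndex.from_tuples(index, names=["pathway", "tissue"])
    values = pd.DataFrame(np.vstack(rows), index=midx, columns=list(animal_ids))
    return PCIMatrix(values, pd.Series(sizes, index=midx, name="N"))
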