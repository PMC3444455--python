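"""Synthetic cohort generator.

Emulates the study design the pipeline targets: a 2 strains x 2 obesity
states x 2 ages x 5 replicates mouse cohort (40 animals) profiled in
multiple tissues, log10-ratio expression, a curated pathway database
with pathway-pathway links, a probabilistic gene functional-interaction
network, and quantitative traits. The generator plants known structure
— co-active pathway groups driven by shared latent activity, and traits
that load linearly on the true pathway activity of chosen (pathway,
tissue) nodes — and records it as ground truth so recovery can be
scored.

Scales: the default test scale is 60 pathways / 1200 genes / 3 tissues /
40 animals (minutes-scale pipelines); the full 187-pathway, 6-tissue
scale of the real study is available by passing the corresponding
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    PATHWAY_CATEGORIES,
    CohortDesign,
    ConsistencyError,
    ExpressionMatrix,
    GeneNetwork,
    PathwayDB,
    TraitTable,
)
from .pci import PCIMatrix

DEFAULT_TEST_TISSUES = ("Adipose", "Islet", "Liver")


@dataclass
class GroundTruth:
    """Planted structure: co-active pathway groups and trait loadings.

    ``active_pathways`` maps a group label to the pathways sharing one
    latent activity series (one value per animal, sd ``activity_sd``);
    member genes of those pathways are shifted by that series in every
    tissue, so their PCIs co-vary across animals. ``trait_effects`` maps
    a trait to (pathway, tissue, effect) loadings on true PCI;
    ``noise_sd`` is the baseline expression (and trait) noise scale.
    """

    active_pathways: dict[str, set[str]] = field(default_factory=dict)
    trait_effects: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)
    noise_sd: float = 0.2
    activity_sd: float = 1.0

    def validate(self, pathway_db: PathwayDB) -> None:
        known = set(pathway_db.members)
        for group, paths in self.active_pathways.items():
            missing = set(paths) - known
            if missing:
                raise ConsistencyError(
                    f"group {group!r} references unknown pathways: {sorted(missing)}")
        for trait, effects in self.trait_effects.items():
            for p, _t, _e in effects:
                if p not in known:
                    raise ConsistencyError(
                        f"trait {trait!r} effect references unknown pathway {p!r}")


def generate_pathway_db(n_pathways: int = 60, size_range: tuple[int, int] = (10, 30),
                        n_genes: int = 1200, link_density: float = 0.05,
                        seed: int = 0, overlap_frac: float = 0.0) -> PathwayDB:
    """Pathway membership, category labels, and a curated link set.

    Pathways receive disjoint cores drawn from the gene universe, plus an
    optional ``overlap_frac`` of members re-drawn from genes already used
    elsewhere. Each unordered pathway pair is curated-linked with
    probability ``link_density``; each pathway gets one of five category
    labels.
    """
    if n_pathways < 2:
        raise ValueError("need at least 2 pathways")
    lo, hi = size_range
    if not (2 <= lo <= hi <= n_genes):
        raise ValueError("size_range must satisfy 2 <= lo <= hi <= n_genes")
    if not 0.0 <= link_density <= 1.0:
        raise ValueError("link_density must lie in [0, 1]")
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes - 1))
    genes = tuple(f"g{i:0{width}d}" for i in range(n_genes))
    pool = list(rng.permutation(n_genes))
    members: dict[str, tuple[str, ...]] = {}
    used: list[int] = []
    pw_width = len(str(n_pathways - 1))
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_overlap = int(round(size * overlap_frac)) if used else 0
        core = size - n_overlap
        if core > len(pool):  # universe exhausted: draw the rest from used genes
            n_overlap += core - len(pool)
            core = len(pool)
        chosen = [pool.pop() for _ in range(core)]
        if n_overlap:
            chosen.extend(rng.choice(used, size=n_overlap, replace=False).tolist()
                          if n_overlap <= len(used) else used)
        used.extend(chosen[:core])
        pid = f"pw{k:0{pw_width}d}"
        members[pid] = tuple(sorted(genes[i] for i in set(chosen)))

    categories = {p: PATHWAY_CATEGORIES[int(rng.integers(len(PATHWAY_CATEGORIES)))]
                  for p in members}
    descriptions = {p: f"synthetic pathway {p}" for p in members}
    pids = list(members)
    links: set[frozenset[str]] = set()
    if link_density > 0:
        for i in range(len(pids)):
            draws = rng.random(len(pids) - i - 1)
            for off, u in enumerate(draws):
                if u < link_density:
                    links.add(frozenset((pids[i], pids[i + 1 + off])))
    return PathwayDB(members=members, categories=categories, links=links,
                     descriptions=descriptions, genes=genes)


def generate_gene_network(pathway_db: PathwayDB, within_prob: float = 0.3,
                          cross_prob: float = 0.001, seed: int = 0) -> GeneNetwork:
    """Probabilistic gene-gene links, denser within pathways.

    Same-pathway gene pairs are linked with probability ``within_prob``,
    all other pairs with ``cross_prob``; link weights (probabilities of
    functional linkage) are Uniform(0.1, 1). Symmetric, no self-links.
    """
    for p in (within_prob, cross_prob):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = pathway_db.gene_universe
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    within_pairs: set[tuple[int, int]] = set()
    for mem in pathway_db.members.values():
        idx = sorted(index[g] for g in mem)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                within_pairs.add((idx[a], idx[b]))

    edges: list[tuple[str, str, float]] = []
    for (i, j), u in zip(sorted(within_pairs), rng.random(len(within_pairs))):
        if u < within_prob:
            edges.append((genes[i], genes[j], float(rng.uniform(0.1, 1.0))))

    if cross_prob > 0:
        total_pairs = n * (n - 1) // 2
        n_cross_target = rng.binomial(total_pairs - len(within_pairs), cross_prob)
        seen: set[tuple[int, int]] = set()
        while len(seen) < n_cross_target:
            i, j = int(rng.integers(n)), int(rng.integers(n))
            if i == j:
                continue
            pair = (min(i, j), max(i, j))
            if pair in seen or pair in within_pairs:
                continue
            seen.add(pair)
            edges.append((genes[pair[0]], genes[pair[1]], float(rng.uniform(0.1, 1.0))))
    return GeneNetwork(genes, edges)


def generate_expression(pathway_db: PathwayDB, gene_network: GeneNetwork,
                        design: CohortDesign, ground_truth: GroundTruth,
                        seed: int = 0, tissues: Sequence[str] | None = None,
                        ) -> dict[str, ExpressionMatrix]:
    """Per-tissue log10-ratio matrices with planted co-activity.

    Baseline values are i.i.d. Normal(0, noise_sd). For every planted
    group, one latent series per animal (Normal(0, activity_sd)) is added
    to all member genes of the group's pathways in every tissue, so the
    PCIs of those pathways co-vary across animals, within and across
    tissues.
    """
    ground_truth.validate(pathway_db)
    tissues = tuple(tissues) if tissues is not None else design.tissues
    rng = np.random.default_rng(seed)
    ann = design.animals()
    animals = list(ann.index)
    genes = pathway_db.gene_universe
    index = {g: i for i, g in enumerate(genes)}

    latents = {g: rng.normal(0.0, ground_truth.activity_sd, size=len(animals))
               for g in sorted(ground_truth.active_pathways)}

    out: dict[str, ExpressionMatrix] = {}
    for tissue in tissues:
        x = rng.normal(0.0, ground_truth.noise_sd, size=(len(genes), len(animals)))
        for group in sorted(ground_truth.active_pathways):
            shift = latents[group]
            for pathway in sorted(ground_truth.active_pathways[group]):
                rows = [index[g] for g in pathway_db.members[pathway]]
                x[rows, :] += shift[None, :]
        df = pd.DataFrame(x, index=list(genes), columns=animals)
        out[tissue] = ExpressionMatrix(df, tissue, annotations=ann)
    return out


def generate_traits(design: CohortDesign, pci_truth: PCIMatrix,
                    ground_truth: GroundTruth, seed: int = 0,
                    trait_names: Sequence[str] = TraitTable.DEFAULT_TRAITS,
                    trait_noise_sd: float | None = None) -> TraitTable:
    """Traits as linear loadings on true PCI plus Gaussian noise.

    Each trait is sum_k effect_k * PCI(pathway_k, tissue_k) per animal
    plus Normal(0, trait_noise_sd); the noise defaults to the ground
    truth's ``noise_sd``. Traits with no planted effect are pure noise.
    """
    rng = np.random.default_rng(seed)
    animals = list(design.animals().index)
    if list(pci_truth.animals) != animals:
        raise ConsistencyError("PCI animal columns do not match the design")
    sd = ground_truth.noise_sd if trait_noise_sd is None else trait_noise_sd
    cols = {}
    for trait in trait_names:
        signal = np.zeros(len(animals))
        for pathway, tissue, effect in ground_truth.trait_effects.get(trait, []):
            if (pathway, tissue) not in pci_truth.values.index:
                raise ConsistencyError(
                    f"trait {trait!r} effect references unscored node ({pathway}, {tissue})")
            signal += effect * pci_truth.row(pathway, tissue).to_numpy()
        cols[trait] = signal + rng.normal(0.0, sd, size=len(animals))
    return TraitTable(pd.DataFrame(cols, index=animals))


def make_ground_truth(pathway_db: PathwayDB, *, tissues: Sequence[str],
                      n_coactive_groups: int = 4, group_size: int = 3,
                      trait_names: Sequence[str] = TraitTable.DEFAULT_TRAITS,
                      effect: float = 1.0, noise_sd: float = 0.2,
                      activity_sd: float = 1.0, seed: int = 0) -> GroundTruth:
    """A standard planted scenario.

    The first pathways become co-active groups of ``group_size`` (these
    feed network-edge recovery); the next ``len(trait_names)`` pathways
    each get their own singleton active group plus a loading of size
    ``effect`` from one trait in one tissue, so trait-relevance recovery
    has an unambiguous answer key. Remaining pathways stay unplanted.
    """
    rng = np.random.default_rng(seed)
    pids = pathway_db.pathways
    need = n_coactive_groups * group_size + len(trait_names)
    if need > len(pids):
        raise ValueError(f"need at least {need} pathways for this scenario")
    active: dict[str, set[str]] = {}
    k = 0
    for g in range(n_coactive_groups):
        active[f"grp{g}"] = set(pids[k:k + group_size])
        k += group_size
    effects: dict[str, list[tuple[str, str, float]]] = {}
    for i, trait in enumerate(trait_names):
        p = pids[k]
        k += 1
        active[f"trait-{trait}"] = {p}
        tissue = tissues[int(rng.integers(len(tissues)))]
        effects[trait] = [(p, tissue, effect)]
    return GroundTruth(active_pathways=active, trait_effects=effects,
                       noise_sd=noise_sd, activity_sd=activity_sd)


def null_ground_truth(noise_sd: float = 0.2) -> GroundTruth:
    """No planted structure: pure-noise expression and traits."""
    return GroundTruth(noise_sd=noise_sd)


def write_fixture(directory, pathway_db: PathwayDB, gene_network: GeneNetwork,
                  exprs: Mapping[str, ExpressionMatrix], traits: TraitTable,
                  ground_truth: GroundTruth) -> dict[str, str]:
    """Write every input as plain text (GMT, TSVs, YAML); see crosspath.io."""
    from . import io as cio
    return cio.write_fixture(directory, pathway_db, gene_network, exprs, traits,
                             ground_truth)
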