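"""Trait relevance, linking classification, assembly, refinement."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import crosspath as cp
from crosspath.traits import LINKING_CLASSES, trait_pci_correlations


def brute_classify(relevant, net):
    """Exhaustive enumeration of the three linking rules (test oracle)."""
    traits_of = {}
    for trait, nodes in relevant.items():
        for n in nodes:
            traits_of.setdefault(n, set()).add(trait)
    out = {}
    nodes = set(net.nodes) | set(traits_of)
    traits = sorted(relevant)
    for v in nodes:
        classes = set()
        # rule 1: relevant to two traits simultaneously
        for i, x in enumerate(traits):
            for y in traits[i + 1:]:
                if v in relevant[x] and v in relevant[y]:
                    classes.add("direct")
        # rule 2: relevant to one trait, adjacent to a node relevant to another
        for x in traits:
            if v not in relevant[x]:
                continue
            for u in (net.neighbors(v) if v in net else []):
                for y in traits:
                    if y != x and u in relevant[y] and y not in traits_of.get(v, set()):
                        classes.add("path2")
        # rule 3: adjacent to relevant nodes of two different traits
        for i, x in enumerate(traits):
            for y in traits[i + 1:]:
                hit_x = any(u in relevant[x] for u in (net.neighbors(v) if v in net else []))
                hit_y = any(u in relevant[y] for u in (net.neighbors(v) if v in net else []))
                if hit_x and hit_y:
                    classes.add("path3")
        if classes:
            out[v] = classes
    return out


class TestTraitRelevant:
    def test_noise_free_monotone_trait_detected(self, null_data, small_db):
        _, pci, _, _ = null_data
        node = pci.nodes[5]
        vec = np.exp(pci.values.loc[node].to_numpy())  # monotone in PCI
        table = cp.TraitTable(pd.DataFrame({"t": vec}, index=pci.animals))
        rel = cp.trait_relevant(pci, table, p_cut=0.005, n_perm=50, seed=1)
        assert node in rel["t"]

    def test_all_missing_trait_gives_empty_set(self, null_data):
        _, pci, _, _ = null_data
        table = cp.TraitTable(pd.DataFrame({"t": np.nan}, index=pci.animals))
        with pytest.warns(UserWarning):
            rel = cp.trait_relevant(pci, table, n_perm=10)
        assert rel["t"] == set()

    def test_constant_trait_gives_empty_set(self, null_data):
        _, pci, _, _ = null_data
        table = cp.TraitTable(pd.DataFrame({"t": 1.0}, index=pci.animals))
        with pytest.warns(UserWarning):
            rel = cp.trait_relevant(pci, table, n_perm=10)
        assert rel["t"] == set()

    def test_fixed_r_mode_matches_direct_correlations(self, null_data):
        _, pci, traits, _ = null_data
        rel = cp.trait_relevant(pci, traits, r_threshold=0.4)
        for trait in traits.traits:
            r = trait_pci_correlations(pci, traits.trait(trait))
            want = {tuple(n) for n in r.index[np.abs(r.to_numpy()) >= 0.4]}
            assert rel[trait] == want

    def test_missing_values_dropped_pairwise(self, null_data):
        _, pci, _, _ = null_data
        node = pci.nodes[0]
        vec = pci.values.loc[node].copy()
        vec.iloc[:5] = np.nan
        table = cp.TraitTable(pd.DataFrame({"t": vec}))
        rel = cp.trait_relevant(pci, table, p_cut=0.005, n_perm=50, seed=2)
        assert node in rel["t"]  # perfect rank correlation on the observed 35


class TestClassifyLinking:
    def test_three_rule_toy_graph(self):
        net = nx.Graph()
        net.add_edges_from([("A", "B"), ("C", "A"), ("C", "B")])
        relevant = {"X": {"A"}, "Y": {"B"}}
        got = cp.classify_linking(relevant, net)
        assert got["A"] == {"path2"}  # relevant to X, adjacent to B which is Y-relevant
        assert got["B"] == {"path2"}
        assert got["C"] == {"path3"}  # adjacent to X-relevant A and Y-relevant B

    def test_direct_requires_two_traits(self):
        net = nx.Graph()
        net.add_node("A")
        got = cp.classify_linking({"X": {"A"}, "Y": {"A"}}, net)
        assert got["A"] == {"direct"}

    def test_empty_relevance_gives_no_classes(self):
        net = nx.path_graph(4)
        assert cp.classify_linking({"X": set(), "Y": set()}, net) == {}

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            net = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)))
            traits = ["X", "Y", "Z"]
            relevant = {t: {v for v in net.nodes if rng.random() < 0.3}
                        for t in traits}
            got = cp.classify_linking(relevant, net)
            want = brute_classify(relevant, net)
            assert got == want


class TestAssembleRefine:
    def test_no_relevance_leaves_isolated_trait_nodes(self):
        net = nx.Graph()
        traits = list(cp.TraitTable.DEFAULT_TRAITS)
        tpn = cp.assemble({t: set() for t in traits}, {}, net, traits)
        assert tpn.number_of_nodes() == 8
        assert tpn.number_of_edges() == 0

    def test_node_bookkeeping(self, planted_data, small_db):
        _, pci, traits, _ = planted_data
        rel = cp.trait_relevant(pci, traits, p_cut=0.005, n_perm=50, seed=3)
        net = cp.build_network(pci, small_db.links, threshold=0.5)
        linking = cp.classify_linking(rel, net)
        tpn = cp.assemble(rel, linking, net, traits.traits)
        included = set().union(*rel.values()) | set(linking)
        assert tpn.number_of_nodes() == len(traits.traits) + len(included)

    def test_planted_relevance_edges_attach_right_traits(self, planted_data,
                                                         small_db):
        exprs, pci, traits, gt = planted_data
        rel = cp.trait_relevant(pci, traits, p_cut=0.005, n_perm=100, seed=4)
        net = cp.build_network(pci, small_db.links, threshold=0.5)
        tpn = cp.assemble(rel, cp.classify_linking(rel, net), net, traits.traits)
        for trait, effects in gt.trait_effects.items():
            for pathway, tissue, _e in effects:
                assert tpn.has_edge(trait, (pathway, tissue))

    def test_refine_drops_isolated_and_low_degree(self):
        tpn = nx.Graph()
        tpn.add_node("X", kind="trait")
        tpn.add_node(("p", "T"), kind="pathway")  # degree 0
        tpn.add_node(("q", "T"), kind="pathway")
        tpn.add_edge("X", ("q", "T"), kind="relevance")  # degree 1
        out = cp.refine(tpn)
        assert set(out.nodes) == {"X"}

    def test_refine_keeps_hand_computed_bridge(self):
        # X--A, Y--B, A--B: A at d1+d2 = 1+2 = 3 <= 6 with degree 2
        tpn = nx.Graph()
        tpn.add_node("X", kind="trait")
        tpn.add_node("Y", kind="trait")
        for n in ("A", "B"):
            tpn.add_node((n, "T"), kind="pathway")
        tpn.add_edge("X", ("A", "T"), kind="relevance")
        tpn.add_edge("Y", ("B", "T"), kind="relevance")
        tpn.add_edge(("A", "T"), ("B", "T"), kind="coexpression")
        out = cp.refine(tpn)
        assert set(out.nodes) == {"X", "Y", ("A", "T"), ("B", "T")}

    def test_refine_drops_single_trait_reachable_nodes(self):
        # C hangs off A with no second trait in reach
        tpn = nx.Graph()
        tpn.add_node("X", kind="trait")
        for n in ("A", "B", "C"):
            tpn.add_node((n, "T"), kind="pathway")
        tpn.add_edge("X", ("A", "T"), kind="relevance")
        tpn.add_edge(("A", "T"), ("B", "T"))
        tpn.add_edge(("A", "T"), ("C", "T"))
        tpn.add_edge(("B", "T"), ("C", "T"))
        out = cp.refine(tpn)
        assert set(out.nodes) == {"X"}  # second trait distance is infinite

    def test_refined_nodes_subset_of_input(self, planted_data, small_db):
        _, pci, traits, _ = planted_data
        rel = cp.trait_relevant(pci, traits, p_cut=0.01, n_perm=50, seed=5)
        net = cp.build_network(pci, small_db.links, threshold=0.4)
        tpn = cp.assemble(rel, cp.classify_linking(rel, net), net, traits.traits)
        out = cp.refine(tpn)
        assert set(out.nodes) <= set(tpn.nodes)
        out_iter = cp.refine(tpn, iterate=True)
        assert set(out_iter.nodes) <= set(out.nodes)
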