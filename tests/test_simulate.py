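"""Generator behavior: determinism, boundaries, planted structure."""

import numpy as np
import pandas as pd
import pytest

import crosspath as cp
from crosspath import io as cio
from crosspath.data import ConsistencyError


class TestPathwayDB:
    def test_same_seed_reproduces_identical_db(self):
        a = cp.generate_pathway_db(n_pathways=10, size_range=(4, 8), n_genes=120,
                                   link_density=0.1, seed=5)
        b = cp.generate_pathway_db(n_pathways=10, size_range=(4, 8), n_genes=120,
                                   link_density=0.1, seed=5)
        assert a.members == b.members
        assert a.links == b.links
        assert a.categories == b.categories

    def test_full_study_scale_pathway_count(self):
        db = cp.generate_pathway_db(n_pathways=187, size_range=(10, 30),
                                    n_genes=6000, link_density=0.02, seed=1)
        assert len(db.members) == 187
        assert all(c in cp.data.PATHWAY_CATEGORIES for c in db.categories.values())

    def test_zero_link_density_gives_no_curated_links(self):
        db = cp.generate_pathway_db(n_pathways=5, size_range=(3, 5), n_genes=60,
                                    link_density=0.0, seed=2)
        assert db.links == set()

    @pytest.mark.parametrize("kwargs", [
        dict(n_pathways=1),
        dict(size_range=(1, 5)),
        dict(size_range=(5, 3)),
        dict(size_range=(5, 10_000)),
        dict(link_density=1.5),
        dict(link_density=-0.1),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(n_pathways=5, size_range=(3, 5), n_genes=60,
                    link_density=0.1, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            cp.generate_pathway_db(**base)


class TestGeneNetwork:
    def test_zero_cross_prob_keeps_all_edges_within_pathways(self):
        db = cp.generate_pathway_db(n_pathways=6, size_range=(4, 6), n_genes=80,
                                    link_density=0.0, seed=3)
        net = cp.generate_gene_network(db, within_prob=0.8, cross_prob=0.0, seed=4)
        pathway_of = {}
        for pid, genes in db.members.items():
            for g in genes:
                pathway_of[g] = pid
        for gi, gj, _w in net.edges():
            assert pathway_of[gi] == pathway_of[gj]

    def test_full_within_prob_yields_complete_pathway_graphs(self):
        db = cp.generate_pathway_db(n_pathways=4, size_range=(5, 5), n_genes=40,
                                    link_density=0.0, seed=6)
        net = cp.generate_gene_network(db, within_prob=1.0, cross_prob=0.0, seed=7)
        assert net.n_edges == 4 * (5 * 4 // 2)

    def test_weights_symmetric_and_in_range(self, small_db, small_gnet):
        edges = small_gnet.edges()
        assert edges
        for gi, gj, w in edges[:50]:
            assert 0.0 < w <= 1.0
            assert small_gnet.weight(gi, gj) == small_gnet.weight(gj, gi) == w

    def test_unknown_gene_in_edge_rejected(self):
        with pytest.raises(ConsistencyError):
            cp.GeneNetwork(["a", "b"], [("a", "zz", 0.5)])


class TestExpression:
    def test_same_seed_identical_matrices(self, small_db, small_gnet, design3):
        gt = cp.null_ground_truth()
        e1 = cp.generate_expression(small_db, small_gnet, design3, gt, seed=9)
        e2 = cp.generate_expression(small_db, small_gnet, design3, gt, seed=9)
        for t in e1:
            pd.testing.assert_frame_equal(e1[t].values, e2[t].values)

    def test_null_expression_has_near_zero_gene_correlations(self, null_data,
                                                             small_db):
        exprs, *_ = null_data
        vals = exprs["Adipose"].values
        genes = list(small_db.members[small_db.pathways[0]])[:4]
        corr = np.corrcoef(vals.loc[genes].to_numpy())
        off = corr[np.triu_indices_from(corr, k=1)]
        assert np.all(np.abs(off) < 0.5)  # n=40 noise-only correlations

    def test_planted_pathway_members_strongly_correlated(self):
        """A planted latent shift far above noise couples member genes."""
        design = cp.CohortDesign(replicates=125, tissues=("Adipose",))  # 1000 animals
        db = cp.generate_pathway_db(n_pathways=3, size_range=(5, 6), n_genes=40,
                                    link_density=0.0, seed=20)
        gnet = cp.generate_gene_network(db, seed=21)
        target = db.pathways[0]
        gt = cp.GroundTruth(active_pathways={"g": {target}}, noise_sd=0.1,
                            activity_sd=1.0)
        exprs = cp.generate_expression(db, gnet, design, gt, seed=22)
        genes = list(db.members[target])[:3]
        corr = np.corrcoef(exprs["Adipose"].values.loc[genes].to_numpy())
        assert corr[np.triu_indices_from(corr, k=1)].min() > 0.5

    def test_unknown_pathway_in_truth_rejected(self, small_db, small_gnet, design3):
        gt = cp.GroundTruth(active_pathways={"g": {"nope"}})
        with pytest.raises(ConsistencyError):
            cp.generate_expression(small_db, small_gnet, design3, gt, seed=0)


class TestTraits:
    def test_shape_is_eight_traits_by_forty_animals(self, null_data, design3):
        _, _, traits, _ = null_data
        assert traits.values.shape == (40, 8)
        assert design3.n_animals == 40

    def test_noise_free_single_effect_trait_is_rank_identical_to_pci(
            self, small_db, small_gnet, design3):
        gt = cp.make_ground_truth(small_db, tissues=design3.tissues,
                                  n_coactive_groups=1, group_size=2, seed=30)
        exprs = cp.generate_expression(small_db, small_gnet, design3, gt, seed=31)
        pci = cp.pci_matrix(exprs, small_db, small_gnet)
        traits = cp.generate_traits(design3, pci, gt, seed=32, trait_noise_sd=0.0)
        trait = "glucose"
        (pathway, tissue, effect), = gt.trait_effects[trait]
        r = cp.spearman(traits.trait(trait).to_numpy(),
                        pci.row(pathway, tissue).to_numpy())
        assert r == pytest.approx(np.sign(effect) * 1.0)

    def test_effect_on_missing_pathway_rejected(self, null_data, design3):
        _, pci, _, _ = null_data
        gt = cp.GroundTruth(trait_effects={"glucose": [("pw00", "Mars", 1.0)]})
        with pytest.raises(ConsistencyError):
            cp.generate_traits(design3, pci, gt, seed=0)


class TestFixtureIO:
    def test_round_trip_preserves_every_object(self, tmp_path, small_db,
                                               small_gnet, planted_data, design3):
        exprs, _, traits, gt = planted_data
        cp.simulate.write_fixture(tmp_path, small_db, small_gnet, exprs, traits, gt)
        db2, gnet2, exprs2, traits2, gt2 = cio.read_fixture(tmp_path, design3)

        assert {p: tuple(m) for p, m in db2.members.items()} == dict(small_db.members)
        assert db2.links == small_db.links
        assert db2.categories == small_db.categories
        e1 = {(a, b): w for a, b, w in small_gnet.edges()}
        e2 = {(a, b): w for a, b, w in gnet2.edges()}
        assert e1.keys() == e2.keys()
        assert all(abs(e1[k] - e2[k]) < 1e-5 for k in e1)
        for t in exprs:
            np.testing.assert_allclose(exprs2[t].values.to_numpy(),
                                       exprs[t].values.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(traits2.values.to_numpy(),
                                   traits.values.to_numpy(), atol=1e-5)
        assert gt2.active_pathways == gt.active_pathways
        assert gt2.trait_effects == gt.trait_effects

    def test_gmt_line_count_equals_pathway_count(self, tmp_path, small_db):
        cio.write_gmt(tmp_path / "p.gmt", small_db)
        lines = (tmp_path / "p.gmt").read_text().strip().splitlines()
        assert len(lines) == len(small_db.members)
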