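import math

import dendropy
import numpy as np
import pytest

from famscape.phylo import (BootstrapConfig, DistanceMatrix,
                            ZeroComparableSitesError, bootstrap_support,
                            nj_tree, p_distance, poisson_correct)
from famscape.tree import Node, Tree

from conftest import prot


class TestPDistance:
    def test_pairwise_deletion_ignores_gapped_sites(self):
        dm = p_distance([prot("a", "ACDE"), prot("b", "AC-E")])
        assert dm.pair("a", "b") == 0.0

    def test_hand_counted_quarter(self):
        dm = p_distance([prot("a", "ACDF"), prot("b", "ACDW")])
        assert dm.pair("a", "b") == pytest.approx(0.25)

    def test_self_distance_zero(self):
        dm = p_distance([prot("a", "MKTW"), prot("b", "MKTW")])
        assert dm.pair("a", "b") == 0.0

    def test_zero_comparable_sites_named(self):
        with pytest.raises(ZeroComparableSitesError, match="a.*b"):
            p_distance([prot("a", "A--"), prot("b", "--A")])


class TestPoissonCorrection:
    def test_closed_forms(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]), "p")
        d = poisson_correct(dm)
        assert d.pair("a", "b") == pytest.approx(math.log(2))
        assert d.model == "poisson"
        zero = poisson_correct(DistanceMatrix(["a", "b"], np.zeros((2, 2)), "p"))
        assert zero.pair("a", "b") == 0.0

    def test_monotone_in_p(self, rng):
        ps = np.sort(rng.uniform(0, 0.95, size=30))
        ds = -np.log1p(-ps)
        assert (np.diff(ds) > 0).all()

    def test_saturated_pair_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]), "p")
        with pytest.raises(ValueError, match="infinite"):
            poisson_correct(dm)


def _random_additive_tree(n, rng):
    nodes = [Node(f"t{i}", length=rng.uniform(0.1, 1.0)) for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = Node(children=[nodes[i], nodes[j]], length=rng.uniform(0.1, 1.0))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    return Tree(Node(children=nodes))


class TestNeighborJoining:
    def test_three_taxon_star(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], float), "p")
        tree = nj_tree(dm)
        lengths = {c.label: c.length for c in tree.root.children}
        assert lengths == {"A": 0.0, "B": 2.0, "C": 4.0}

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) => AB=3 AC=5 AD=6 BC=6 BD=7 CD=7
        m = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), m, "p"))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        _, plm = tree.path_length_matrix()
        assert np.allclose(plm, m)

    def test_additive_matrices_reproduced_exactly(self, rng):
        for _ in range(25):
            true = _random_additive_tree(int(rng.integers(5, 9)), rng)
            labels, D = true.path_length_matrix()
            est = nj_tree(DistanceMatrix(labels, D, "p"))
            assert est.bipartitions() == true.bipartitions()
            _, D2 = est.path_length_matrix()
            assert np.allclose(D2, D, atol=1e-9)

    def test_matches_dendropy_nj_topology(self, rng):
        """Independent cross-check: dendropy's NJ on the same additive
        matrix recovers the same unrooted topology."""
        true = _random_additive_tree(8, rng)
        labels, D = true.path_length_matrix()
        csv = "," + ",".join(labels) + "\n"
        for i, lab in enumerate(labels):
            csv += lab + "," + ",".join(f"{x:.8f}" for x in D[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv))
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        anchor = min(labels)
        d_splits = set()
        for edge in dtree.preorder_edge_iter():
            taxa = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
            if 1 < len(taxa) < len(labels) - 1:
                side = frozenset(taxa) if anchor not in taxa \
                    else frozenset(set(labels) - taxa)
                d_splits.add(side)
        mine = nj_tree(DistanceMatrix(labels, D, "p"))
        assert mine.bipartitions() == d_splits

    def test_rejects_tiny_or_invalid_input(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2)), "p"))


class TestNewick:
    def test_round_trip_through_dendropy(self):
        m = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), m, "p"))
        tree.annotate_supports({frozenset({"C", "D"}): 97})
        newick = tree.to_newick()
        back = dendropy.Tree.get(data=newick, schema="newick")
        leaves = sorted(l.taxon.label for l in back.leaf_node_iter())
        assert leaves == list("ABCD")
        supports = [n.label for n in back.preorder_internal_node_iter() if n.label]
        assert supports == ["97"]
        lengths = {l.taxon.label: l.edge.length for l in back.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)


class TestBootstrap:
    def _msa(self):
        rows = [prot(f"s{i}", "MKTWAEDQ" * 6) for i in range(4)]
        rows.append(prot("div", "WWKTAEDQ" * 6))
        return rows

    def test_supports_within_bounds_and_consensus_rule(self):
        msa = self._msa()
        res = bootstrap_support(msa, BootstrapConfig(n_replicates=30, seed=1))
        assert all(0 <= s <= 100 for s in res.support_of_split.values())
        for node in res.consensus.iter_nodes():
            if not node.is_leaf and node.support is not None:
                assert node.support > 50

    def test_identical_rows_plus_divergent_row_support_100(self):
        """Resampling cannot change which pairs are at distance zero, so
        every retained split is found in all replicates."""
        msa = [prot("a", "MKTWAEDQ" * 5), prot("b", "MKTWAEDQ" * 5),
               prot("c", "MKTWAEYR" * 5), prot("d", "MKTWAEYS" * 5)]
        res = bootstrap_support(msa, BootstrapConfig(n_replicates=25, seed=0))
        assert all(s == 100.0 for s in res.support_of_split.values())

    def test_seeded_reproducibility(self):
        msa = self._msa()
        r1 = bootstrap_support(msa, BootstrapConfig(n_replicates=20, seed=9))
        r2 = bootstrap_support(msa, BootstrapConfig(n_replicates=20, seed=9))
        assert r1.support_of_split == r2.support_of_split
        assert r1.tree.to_newick() == r2.tree.to_newick()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BootstrapConfig(n_replicates=0)
        with pytest.raises(ValueError):
            BootstrapConfig(consensus_cutoff=100)
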