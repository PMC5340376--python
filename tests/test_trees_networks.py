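import itertools

import networkx as nx
import numpy as np
import pytest

from mtphylogeo.distances import DistanceMatrix, distance_matrix
from mtphylogeo.haplotypes import collapse_haplotypes
from mtphylogeo.seqio import Alignment
from mtphylogeo.structure import upgma
from mtphylogeo.trees_networks import (bootstrap_support, median_joining_network,
                                       network_from_table, nj_tree, split_support,
                                       tree_bipartitions)


def patristic(tree, a, b):
    return tree.find(a).distance(tree.find(b))


class TestNeighbourJoining:
    def test_three_taxa_closed_form(self):
        # branch lengths solve the three-point equations:
        # a = (dAB + dAC - dBC)/2 etc.
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), d, "raw"))
        assert patristic(tree, "A", "B") == pytest.approx(3)
        assert patristic(tree, "A", "C") == pytest.approx(4)
        assert patristic(tree, "B", "C") == pytest.approx(5)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,C:3,D:4) -> additive distances
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C", "D"), d, "raw"))
        for x, y in itertools.combinations("ABCD", 2):
            i, j = "ABCD".index(x), "ABCD".index(y)
            assert patristic(tree, x, y) == pytest.approx(d[i, j])
        assert tree_bipartitions(tree) == {frozenset({"A", "B"})}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float), "raw"))

    def test_ultrametric_matrix_matches_upgma_topology(self):
        d = np.array([[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float)
        dm = DistanceMatrix(("A", "B", "C", "D"), d, "raw")
        nj_splits = tree_bipartitions(nj_tree(dm))
        assert nj_splits == {frozenset({"A", "B"})}  # == {C,D} side
        newick = upgma(dm)
        assert "(A:1,B:1)" in newick and "(C:2,D:2)" in newick


class TestBootstrap:
    def two_clade_alignment(self):
        # two clades separated by many fixed differences
        left = "A" * 20 + "C" * 10
        right = "T" * 20 + "C" * 10
        seqs = (left, left[:29] + "T", right, right[:29] + "G", left[:28] + "TC")
        return Alignment(("a1", "a2", "b1", "b2", "a3"), seqs)

    def test_strong_split_near_full_support(self):
        aln = self.two_clade_alignment()
        support = bootstrap_support(aln, reps=100, seed=0, metric="raw")
        s = split_support(support, {"a1", "a2", "a3"}, set(aln.ids))
        assert s >= 95.0

    def test_support_values_bounded_and_taxon_order_invariant(self):
        aln = self.two_clade_alignment()
        s1 = bootstrap_support(aln, reps=50, seed=4, metric="raw")
        assert all(0 <= v <= 100 for v in s1.values())
        order = [4, 2, 0, 3, 1]
        shuffled = Alignment(tuple(aln.ids[i] for i in order),
                             tuple(aln.seqs[i] for i in order))
        s2 = bootstrap_support(shuffled, reps=50, seed=4, metric="raw")
        split = frozenset({"a1", "a2", "a3"})
        assert abs(s1.get(split, 0) - s2.get(split, 0)) <= 10


class TestMedianJoining:
    def test_two_haplotypes_single_edge(self):
        net = median_joining_network(["AAAA", "ATTA"])
        assert net.number_of_edges() == 1
        assert list(net.edges(data="weight"))[0][2] == 2

    def test_toy_triplet_adds_median_star(self):
        net = median_joining_network(["AAA", "TTA", "TAT"], ids=["h1", "h2", "h3"])
        medians = [n for n, d in net.nodes(data=True) if d["is_median"]]
        assert len(medians) == 1
        assert net.nodes[medians[0]]["sequence"] == "TAA"
        assert sorted(d for _, d in net.degree()) == [1, 1, 1, 3]
        assert all(w == 1 for _, _, w in net.edges(data="weight"))

    def test_connected_and_integer_weights(self, rng):
        seqs = list({"".join(rng.choice(list("ACGT"), 12)) for _ in range(10)})
        net = median_joining_network(seqs)
        assert nx.is_connected(net)
        assert all(isinstance(w, (int, np.integer)) and w >= 1
                   for _, _, w in net.edges(data="weight"))

    def test_medians_never_duplicate_observed(self, rng):
        seqs = list({"".join(rng.choice(list("AT"), 8)) for _ in range(12)})
        net = median_joining_network(seqs)
        observed = {d["sequence"] for _, d in net.nodes(data=True) if not d["is_median"]}
        medians = {d["sequence"] for _, d in net.nodes(data=True) if d["is_median"]}
        assert not (observed & medians)

    def test_rerun_on_own_vertex_set_is_fixed_point(self):
        net = median_joining_network(["AAA", "TTA", "TAT"])
        all_seqs = [d["sequence"] for _, d in net.nodes(data=True)]
        net2 = median_joining_network(all_seqs)
        assert {d["sequence"] for _, d in net2.nodes(data=True)} == set(all_seqs)
        assert net2.number_of_edges() == net.number_of_edges()

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            median_joining_network(["AAA", "AAA"])


class TestSyntheticNetwork:
    def test_two_lineage_clusters(self, synthetic_default):
        dataset, truth = synthetic_default
        table = collapse_haplotypes(dataset)
        net = network_from_table(table)
        assert nx.is_connected(net)
        # observed vertices carry population breakdowns summing to their frequency
        for name, d in net.nodes(data=True):
            if not d["is_median"]:
                assert sum(d["populations"].values()) == d["frequency"]
        # the two lineages are far apart: some edge path must cross a long gap,
        # i.e. hamming distance between lineage founders is reflected in the network
        hap_lineage = {}
        hap_of = {sid: f"H{idx + 1}" for sid, idx in table.assignments.items()}
        for sid, lab in truth.lineage_of.items():
            hap_lineage[hap_of[sid]] = lab
        cross = [w for a, b, w in net.edges(data="weight")
                 if hap_lineage.get(a) and hap_lineage.get(b)
                 and hap_lineage[a] != hap_lineage[b]]
        within = [w for a, b, w in net.edges(data="weight")
                  if hap_lineage.get(a) and hap_lineage.get(b)
                  and hap_lineage[a] == hap_lineage[b]]
        if cross and within:
            assert min(cross) > max(within)


class TestHaplotypeTreeOnSynthetic:
    def test_nj_separates_the_two_lineages(self, synthetic_default):
        dataset, truth = synthetic_default
        table = collapse_haplotypes(dataset)
        hap_aln = Alignment(tuple(table.counts.index), table.sequences)
        tree = nj_tree(distance_matrix(hap_aln, "k2p"))
        hap_of = {sid: f"H{idx + 1}" for sid, idx in table.assignments.items()}
        a_haps = frozenset(hap_of[sid] for sid, lab in truth.lineage_of.items() if lab == "A")
        all_haps = frozenset(hap_aln.ids)
        splits = tree_bipartitions(tree)
        target = min(a_haps, all_haps - a_haps, key=lambda s: sorted(s))
        assert target in splits
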