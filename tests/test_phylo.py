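"""Distances, phylotype clustering, neighbor joining, bootstrap, Newick I/O."""

import math

import numpy as np
import pytest

from mnox import simulate
from mnox.phylo import (
    Alignment,
    DistMatrix,
    bipartitions,
    bootstrap_support,
    branch_supports,
    cluster_phylotypes,
    dist_matrix,
    k2p_distance,
    neighbor_joining,
    p_distance,
    read_newick,
    write_newick,
)


def mutate(seq, sites, alphabet="ACGT"):
    out = list(seq)
    for site in sites:
        out[site] = alphabet[(alphabet.index(out[site]) + 1) % 4]
    return "".join(out)


class TestPDistance:
    def test_identical(self):
        assert p_distance("A" * 100, "A" * 100) == 0.0

    def test_direct_count(self):
        a = "A" * 100
        assert p_distance(a, mutate(a, range(5))) == pytest.approx(0.05)

    def test_gap_sites_excluded_pairwise(self):
        assert p_distance("AC-G", "ACTG") == 0.0
        assert p_distance("ACNG", "ACTG") == 0.0

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError):
            p_distance("----", "AAAA")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            p_distance("ACGT", "ACG")


class TestK2P:
    def test_identical(self):
        assert k2p_distance("ACGT" * 25, "ACGT" * 25) == 0.0

    def test_closed_form(self):
        # 10 transitions (A->G), 5 transversions (A->C) over 100 sites
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        expected = -0.5 * math.log(1 - 2 * 0.1 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_saturation_flagged_as_nan(self):
        # Q = 0.5 makes 1 - 2Q = 0: undefined
        a = "A" * 50 + "G" * 50
        b = "C" * 50 + "G" * 50
        assert math.isnan(k2p_distance(a, b))

    def test_expands_p_distance(self, rng):
        base = "".join(rng.choice(list("ACGT"), 300))
        for _ in range(20):
            sites = rng.choice(300, size=int(rng.integers(1, 60)), replace=False)
            other = mutate(base, sites)
            k2p = k2p_distance(base, other)
            if not math.isnan(k2p):
                assert k2p >= p_distance(base, other) - 1e-12


class TestPhylotypes:
    def test_identical_sequences_single_phylotype(self):
        aln = Alignment(("a", "b", "c"), ("ACGT" * 25,) * 3)
        assert cluster_phylotypes(aln).n_phylotypes == 1

    def test_pair_beyond_threshold_split(self):
        a = "A" * 100
        aln = Alignment(("a", "b"), (a, mutate(a, range(5))))  # p = 0.05 >= 0.03
        assert cluster_phylotypes(aln).n_phylotypes == 2

    def test_pair_below_threshold_grouped(self):
        a = "A" * 100
        aln = Alignment(("a", "b"), (a, mutate(a, [0, 1])))  # p = 0.02 < 0.03
        assert cluster_phylotypes(aln).n_phylotypes == 1

    def test_complete_linkage_guarantee(self):
        # d(a,b)=0.02, d(a,c)=0.02, d(b,c)=0.04: complete linkage refuses the
        # merge that would put a 0.04 pair in one phylotype; single accepts it.
        base = "A" * 100
        aln = Alignment(
            ("a", "b", "c"), (base, mutate(base, [0, 1]), mutate(base, [2, 3]))
        )
        complete = cluster_phylotypes(aln, linkage="complete")
        single = cluster_phylotypes(aln, linkage="single")
        assert complete.n_phylotypes == 2
        assert single.n_phylotypes == 1
        # every within-phylotype pair is strictly below the threshold
        for members in complete.members().values():
            rows = {name: aln.rows[aln.ids.index(name)] for name in members}
            for x in members:
                for y in members:
                    assert p_distance(rows[x], rows[y]) < complete.threshold

    def test_order_invariance(self, rng):
        tree = simulate.simulate_tree(10, seed=3)
        aln = simulate.simulate_alignment(tree, 500, seed=4)
        perm = rng.permutation(10)
        shuffled = Alignment(
            tuple(aln.ids[i] for i in perm), tuple(aln.rows[i] for i in perm)
        )

        def partition(assignment):
            return {frozenset(v) for v in assignment.members().values()}

        assert partition(cluster_phylotypes(aln)) == partition(cluster_phylotypes(shuffled))


class TestNeighborJoining:
    def additive_matrix(self, tree):
        """Leaf-to-leaf path-length matrix (independent of the NJ code)."""
        pdm = tree.phylogenetic_distance_matrix()
        labels = sorted(t.label for t in tree.taxon_namespace)
        taxa = {t.label: t for t in tree.taxon_namespace}
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        return DistMatrix(ids=tuple(labels), values=d)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> path-sum distances
        ids = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        tree = neighbor_joining(DistMatrix(ids, d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}  # AB|CD split
        leaf_lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert leaf_lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0})
        internal = [
            node.edge.length
            for node in tree.preorder_node_iter()
            if node is not tree.seed_node and not node.is_leaf()
        ]
        assert internal == pytest.approx([1.0])

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistMatrix(("a", "b", "c"), d))
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_recovers_random_additive_topologies(self):
        for seed in range(20):
            tree = simulate.simulate_tree(6, seed=seed, mean_branch_length=0.3)
            dm = self.additive_matrix(tree)
            rebuilt = neighbor_joining(dm)
            assert bipartitions(rebuilt) == bipartitions(tree)

    def test_agrees_with_scikit_bio(self):
        import io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import TreeNode, nj as skbio_nj

        tree = simulate.simulate_tree(7, seed=11, mean_branch_length=0.2)
        dm = self.additive_matrix(tree)
        mine = neighbor_joining(dm)
        other = skbio_nj(SkbioDM(dm.values, ids=list(dm.ids)))

        def skbio_bipartitions(t):
            labels = {tip.name for tip in t.tips()}
            ref = min(labels)
            out = set()
            for node in t.non_tips(include_self=False):
                side = frozenset(tip.name for tip in node.tips())
                if ref in side:
                    side = frozenset(labels - side)
                if 2 <= len(side) <= len(labels) - 2:
                    out.add(side)
            return out

        assert bipartitions(mine) == skbio_bipartitions(other)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistMatrix(("a", "b"), np.zeros((2, 2))))

    def test_undefined_entries_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            neighbor_joining(DistMatrix(("a", "b", "c"), d))

    def test_clamp_negative_option(self):
        d = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0.2]], float)
        tree = neighbor_joining(DistMatrix(("a", "b", "c", "d"), d), clamp_negative=True)
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                assert node.edge.length >= 0


class TestBootstrap:
    def test_single_replicate_supports_are_all_or_nothing(self):
        tree = simulate.simulate_tree(5, seed=2)
        aln = simulate.simulate_alignment(tree, 300, seed=2)
        boot = bootstrap_support(aln, replicates=1, seed=0)
        assert set(branch_supports(boot).values()) <= {0, 100}

    def test_deterministic_given_seed(self):
        tree = simulate.simulate_tree(5, seed=6)
        aln = simulate.simulate_alignment(tree, 400, seed=6)
        a = branch_supports(bootstrap_support(aln, replicates=25, seed=9))
        b = branch_supports(bootstrap_support(aln, replicates=25, seed=9))
        assert a == b

    def test_supports_bounded(self):
        tree = simulate.simulate_tree(6, seed=7)
        aln = simulate.simulate_alignment(tree, 500, seed=7)
        boot = bootstrap_support(aln, replicates=20, seed=1)
        supports = branch_supports(boot)
        assert supports  # at least one internal branch
        assert all(0 <= s <= 100 for s in supports.values())
        assert boot.bootstrap_replicates_used + boot.bootstrap_skipped == 20


class TestNewick:
    def test_round_trip_topology_lengths_supports(self):
        tree = simulate.simulate_tree(8, seed=5)
        aln = simulate.simulate_alignment(tree, 600, seed=5)
        boot = bootstrap_support(aln, replicates=10, seed=3)
        text = write_newick(boot)
        back = read_newick(text)
        assert bipartitions(back) == bipartitions(boot)
        assert branch_supports(back) == branch_supports(boot)
        orig = sorted(
            round(n.edge.length, 6)
            for n in boot.preorder_node_iter()
            if n is not boot.seed_node
        )
        rt = sorted(
            round(n.edge.length, 6)
            for n in back.preorder_node_iter()
            if n is not back.seed_node
        )
        assert rt == pytest.approx(orig, abs=1e-6)

    def test_two_leaf_tree(self):
        tree = read_newick("(A:1,B:2);")
        leaves = list(tree.leaf_node_iter())
        assert {leaf.taxon.label for leaf in leaves} == {"A", "B"}

    def test_malformed_text_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            read_newick("((A:1,B:2;")


def test_dist_matrix_symmetry_and_undefined_flagging():
    aln = Alignment(
        ("a", "b", "c"),
        ("A" * 50 + "G" * 50, "A" * 100, "C" * 50 + "G" * 50),
    )
    dm = dist_matrix(aln, metric="k2p")
    assert np.array_equal(np.isnan(dm.values), np.isnan(dm.values.T))
    assert ("a", "c") in dm.undefined_pairs or ("b", "c") in dm.undefined_pairs


def test_alignment_validation():
    with pytest.raises(ValueError):
        Alignment(("a", "a"), ("ACGT", "ACGT"))
    with pytest.raises(ValueError):
        Alignment(("a", "b"), ("ACGT", "ACG"))
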