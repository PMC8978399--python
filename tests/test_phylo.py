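"""Distances (protein p-distance, Tamura 1992), neighbor joining and
nearest-reference clade assignment."""

import itertools
import math

import numpy as np
import pytest

from cactascan.phylo import (CladeAssignment, DistanceMatrix, assign_clade,
                             distance_matrix, nj_tree, p_distance_protein,
                             t92_distance)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(AA[i] for i in rng.integers(0, 20, size=n))


def _random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _evolve(seq, n_subs, seed):
    rng = np.random.default_rng(seed)
    s = list(seq)
    for _ in range(n_subs):
        i = int(rng.integers(0, len(s)))
        s[i] = "ACGT"[(("ACGT".index(s[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(s)


class TestPDistanceProtein:
    def test_identical_is_zero(self):
        assert p_distance_protein("MKVL", "MKVL") == 0.0

    def test_one_of_two_sites(self):
        assert p_distance_protein("AC", "AD") == 0.5

    def test_gap_columns_excluded_pairwise(self):
        assert p_distance_protein("M-KV", "MAKL") == pytest.approx(1 / 3)

    def test_all_gap_raises(self):
        with pytest.raises(ValueError):
            p_distance_protein("--", "AA")

    @pytest.mark.parametrize("seed", range(5))
    def test_random_pair_matches_site_tally(self, seed):
        a = _random_protein(100, seed)
        b = _random_protein(100, seed + 50)
        expect = sum(x != y for x, y in zip(a, b)) / 100
        assert p_distance_protein(a, b) == pytest.approx(expect)


class TestT92Distance:
    def test_identical_is_zero(self):
        s = _random_dna(300, 1)
        assert t92_distance(s, s) == 0.0

    def test_gc_half_equals_kimura_two_parameter(self):
        # build an alignment with overall GC exactly 0.5 and known P, Q
        a = "A" * 50 + "C" * 50 + "G" * 50 + "T" * 50
        b = ("G" * 10 + "A" * 40      # 10 A->G transitions
             + "T" * 5 + "C" * 45     # 5 C->T transitions
             + "C" * 6 + "G" * 44     # 6 G->C transversions
             + "T" * 50)
        P = 15 / 200
        Q = 6 / 200
        k2p = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        got = t92_distance(a, b)
        # GC over both sequences: a has 100/200, b has (10+45+6+44)/200
        gc = (100 + 105) / 400
        h = 2 * gc * (1 - gc)
        expect = -h * math.log(1 - P / h - Q) \
            - 0.5 * (1 - h) * math.log(1 - 2 * Q)
        assert got == pytest.approx(expect)
        # with theta near 0.5, h is near the K2P limit
        assert got == pytest.approx(k2p, rel=0.02)

    def test_closed_form_on_counted_proportions(self):
        """Independent evaluation: count P, Q, theta in the test and plug
        into the Tamura (1992) closed form."""
        a = _random_dna(600, 3)
        b = _evolve(a, 60, 4)
        n = len(a)
        P = sum((x in "AG") == (y in "AG") and x != y
                for x, y in zip(a, b)) / n
        Q = sum((x in "AG") != (y in "AG") for x, y in zip(a, b)) / n
        theta = (sum(c in "GC" for c in a)
                 + sum(c in "GC" for c in b)) / (2 * n)
        h = 2 * theta * (1 - theta)
        expect = -h * math.log(1 - P / h - Q) \
            - 0.5 * (1 - h) * math.log(1 - 2 * Q)
        assert t92_distance(a, b) == pytest.approx(expect)

    def test_gamma_variant_exceeds_uncorrected(self):
        a = _random_dna(600, 7)
        b = _evolve(a, 120, 8)
        assert t92_distance(a, b, gamma_shape=0.5) > t92_distance(a, b)

    def test_saturation_flagged_as_inf(self):
        a = "A" * 100 + "C" * 100
        b = "C" * 100 + "A" * 100  # all transversions, Q = 1
        assert t92_distance(a, b) == math.inf

    @pytest.mark.parametrize("seed", range(5))
    def test_t92_at_least_p_distance(self, seed):
        a = _random_dna(500, seed + 20)
        b = _evolve(a, 50, seed + 70)
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        d = t92_distance(a, b)
        assert math.isfinite(d) and d >= p - 1e-12

    def test_ragged_raises(self):
        with pytest.raises(ValueError):
            t92_distance("ACGT", "ACG")


class TestDistanceMatrix:
    def test_identical_pair_zero_matrix(self):
        dm = distance_matrix([("a", "ACGT"), ("b", "ACGT")], "t92")
        assert np.allclose(dm.d, 0.0)

    def test_three_sequences_match_pairwise_calls(self):
        seqs = [("a", _random_dna(200, 1)), ("b", _random_dna(200, 2)),
                ("c", _random_dna(200, 3))]
        dm = distance_matrix(seqs, "p_protein")
        for i, j in itertools.combinations(range(3), 2):
            assert dm.d[i, j] == pytest.approx(
                p_distance_protein(seqs[i][1], seqs[j][1]))

    def test_symmetric_zero_diagonal(self):
        seqs = [(f"s{i}", _random_dna(300, i)) for i in range(10)]
        dm = distance_matrix(seqs, "t92")
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0.0)

    def test_ragged_alignment_raises(self):
        with pytest.raises(ValueError):
            distance_matrix([("a", "ACGT"), ("b", "ACG")], "t92")


def _tip_distances(newick):
    from skbio import TreeNode
    import io

    tree = TreeNode.read(io.StringIO(newick))
    dm = tree.tip_tip_distances()
    return {frozenset((a, b)): dm[a, b]
            for a, b in itertools.combinations(dm.ids, 2)}


def _additive_matrix_from_tree(topology_pairs, internal, leaves):
    """Distances on an unrooted 4-taxon tree ((A,B),(C,D)) with leaf
    branch lengths and one internal branch."""
    A, B, C, D = leaves
    d = np.zeros((4, 4))
    L = dict(zip("ABCD", topology_pairs))
    def dist(x, y):
        same_side = {x, y} in ({0, 1}, {2, 3})
        extra = 0 if same_side else internal
        return topology_pairs[x] + topology_pairs[y] + extra
    for i in range(4):
        for j in range(i + 1, 4):
            d[i, j] = d[j, i] = dist(i, j)
    return d


class TestNjTree:
    def test_four_taxon_additive_topology_recovered(self):
        d = _additive_matrix_from_tree([2.0, 3.0, 4.0, 1.0], 5.0, "ABCD")
        dm = DistanceMatrix(labels=list("ABCD"), d=d)
        newick = nj_tree(dm)
        tips = _tip_distances(newick)
        # exact recovery on an additive matrix: all path lengths match
        for i, j in itertools.combinations(range(4), 2):
            assert tips[frozenset(("ABCD"[i], "ABCD"[j]))] \
                == pytest.approx(d[i, j])
        # AB are neighbors: their path avoids the internal branch
        assert tips[frozenset(("A", "B"))] == pytest.approx(5.0)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 4.0, 6.0], [4.0, 0, 8.0], [6.0, 8.0, 0]])
        dm = DistanceMatrix(labels=list("ABC"), d=d)
        tips = _tip_distances(nj_tree(dm))
        assert tips[frozenset(("A", "B"))] == pytest.approx(4.0)
        assert tips[frozenset(("A", "C"))] == pytest.approx(6.0)
        assert tips[frozenset(("B", "C"))] == pytest.approx(8.0)

    def test_fewer_than_three_taxa_raises(self):
        dm = DistanceMatrix(labels=["a", "b"],
                            d=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_saturated_taxon_excluded_with_warning(self):
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 0.3
        d[0, 2] = d[2, 0] = 0.4
        d[1, 2] = d[2, 1] = 0.5
        d[0, 3] = d[3, 0] = math.inf
        d[1, 3] = d[3, 1] = math.inf
        d[2, 3] = d[3, 2] = math.inf
        dm = DistanceMatrix(labels=list("ABCX"), d=d)
        with pytest.warns(UserWarning, match="saturated"):
            newick = nj_tree(dm)
        assert "X" not in newick

    @pytest.mark.parametrize("seed", range(100))
    def test_random_additive_trees_recovered_exactly(self, seed):
        """NJ reproduces every pairwise distance of additive matrices
        from random positive-branch-length 4- and 5-taxon trees."""
        rng = np.random.default_rng(seed)
        n = 4 + seed % 2
        import io
        from skbio import TreeNode

        # random binary tree via random joins, with random branch lengths
        labels = [chr(65 + i) for i in range(n)]
        if n == 4:
            newick_in = ("((A:{:.3f},B:{:.3f}):{:.3f},C:{:.3f},D:{:.3f});"
                         .format(*rng.uniform(0.5, 5.0, 5)))
        else:
            newick_in = ("((A:{:.3f},B:{:.3f}):{:.3f},(C:{:.3f},D:{:.3f})"
                         ":{:.3f},E:{:.3f});"
                         .format(*rng.uniform(0.5, 5.0, 7)))
        tree = TreeNode.read(io.StringIO(newick_in))
        tdm = tree.tip_tip_distances()
        order = list(tdm.ids)
        d = np.array([[tdm[a, b] for b in order] for a in order])
        dm = DistanceMatrix(labels=order, d=d)
        tips = _tip_distances(nj_tree(dm))
        for i, j in itertools.combinations(range(n), 2):
            assert tips[frozenset((order[i], order[j]))] \
                == pytest.approx(d[i, j], abs=1e-9)


def _two_families(n_refs=3, n_queries=10, seed=0):
    """Two sequence families with between-family divergence far above
    within-family divergence (published clade structure at desk scale)."""
    rng = np.random.default_rng(seed)
    rootI = _random_dna(600, seed + 1)
    rootII = _evolve(rootI, 360, seed + 2)  # ~0.5 divergence
    refs = []
    for k in range(n_refs):
        refs.append((f"I{k}", "cladeI", _evolve(rootI, 25, seed + 10 + k)))
        refs.append((f"II{k}", "cladeII",
                     _evolve(rootII, 25, seed + 40 + k)))
    queries = []
    for k in range(n_queries):
        if k % 2 == 0:
            queries.append((f"qI{k}", "cladeI",
                            _evolve(rootI, 30, seed + 100 + k)))
        else:
            queries.append((f"qII{k}", "cladeII",
                            _evolve(rootII, 30, seed + 200 + k)))
    return refs, queries


class TestAssignClade:
    def test_identical_to_reference(self):
        refs = [("r1", "cladeI", "ACGTACGT"), ("r2", "cladeII", "TGCATGCA")]
        got = assign_clade(("q", "ACGTACGT"), refs, "t92", cutoff=0.5)
        assert got == CladeAssignment("q", "cladeI", "r1", 0.0)

    def test_beyond_cutoff_unassigned(self):
        refs = [("r1", "cladeI", "A" * 100 + "C" * 100),
                ("r2", "cladeII", "C" * 100 + "A" * 100)]
        q = ("q", "G" * 200)
        got = assign_clade(q, refs, "p_protein", cutoff=0.1)
        assert got.clade == "unassigned"

    def test_single_clade_references_rejected(self):
        with pytest.raises(ValueError):
            assign_clade(("q", "ACGT"), [("r", "cladeI", "ACGT")], "t92",
                         cutoff=1.0)

    def test_two_family_assignment_perfect(self):
        """100 seeded queries against two families separated by ~10x the
        within-family divergence all assign correctly."""
        correct = 0
        total = 0
        for seed in range(10):
            refs, queries = _two_families(seed=seed)
            for label, truth, seq in queries:
                got = assign_clade((label, seq), refs, "t92", cutoff=0.3)
                total += 1
                correct += got.clade == truth
        assert total == 100
        assert correct == total
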