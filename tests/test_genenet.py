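"""genenet: homology edges, MCL families, hypergeometric sharing, Ward.D2."""

import itertools
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from baconscope import genenet, synth
from baconscope.genenet import (
    ScoringScheme,
    filter_contigs,
    mcl,
    pairwise_scores,
    shared_content,
    ward_cluster,
)


def hypergeom_upper_tail_enumeration(N, n_i, n_j, k):
    """Oracle: exhaustive enumeration over all C(N, n_j) draws.

    Families 0..N-1; contig i holds families 0..n_i-1. Count draws of size
    n_j whose overlap with contig i is >= k.
    """
    hits = total = 0
    for draw in itertools.combinations(range(N), n_j):
        total += 1
        if sum(1 for f in draw if f < n_i) >= k:
            hits += 1
    return hits / total


class TestFilterContigs:
    def test_boundary_exactly_min_is_dropped(self):
        data = {"a": list(range(10)), "b": list(range(11))}
        kept = filter_contigs(data, 10)
        assert set(kept) == {"b"}

    def test_empty_dataset(self):
        assert filter_contigs({}, 10) == {}

    def test_negative_min_rejected(self):
        with pytest.raises(ValueError):
            filter_contigs({}, -1)


class TestPairwiseScores:
    def test_bit_conversion_matches_karlin_altschul(self):
        scheme = ScoringScheme()
        # raw 100 at lambda=0.267, K=0.041: (26.7 - ln 0.041)/ln 2
        expected = (0.267 * 100 - math.log(0.041)) / math.log(2)
        assert scheme.bits(100) == pytest.approx(expected)
        assert scheme.bits(100) == pytest.approx(43.1, abs=0.05)
        assert scheme.bits(100) < 50  # dropped at the default threshold

    def test_identical_proteins_far_above_threshold(self):
        rng = np.random.default_rng(0)
        p = synth.random_protein(rng, 100)
        edges = pairwise_scores({"a": p, "b": p}, prefilter=None)
        assert ("a", "b") in edges
        assert edges[("a", "b")] > 100

    def test_unrelated_random_proteins_have_no_edge(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pair = {"a": synth.random_protein(rng, 50), "b": synth.random_protein(rng, 50)}
            assert pairwise_scores(pair, prefilter=None) == {}

    def test_prefilter_preserves_family_edges(self):
        rng = np.random.default_rng(2)
        anc = synth.random_protein(rng, 90)
        prots = {f"m{i}": synth.mutate_protein(anc, 0.05, rng) for i in range(5)}
        exact = pairwise_scores(prots, prefilter=None)
        fast = pairwise_scores(prots)
        assert exact == fast

    def test_needs_two_proteins(self):
        with pytest.raises(ValueError):
            pairwise_scores({"a": "MKW"})


class TestMCL:
    def test_two_cliques_two_families(self):
        nodes = list("abcdef")
        edges = {}
        for x, y in itertools.combinations("abc", 2):
            edges[(x, y)] = 100.0
        for x, y in itertools.combinations("def", 2):
            edges[(x, y)] = 100.0
        graph = mcl(nodes, edges)
        fams = sorted(tuple(m) for m in graph.families.values())
        assert fams == [("a", "b", "c"), ("d", "e", "f")]

    def test_path_graph_single_family(self):
        graph = mcl(["a", "b", "c"], {("a", "b"): 1.0, ("b", "c"): 1.0}, inflation=2.0)
        assert list(graph.families.values()) == [["a", "b", "c"]]

    def test_empty_edges_singletons(self):
        graph = mcl(list("abcde"), {})
        assert sorted(len(m) for m in graph.families.values()) == [1] * 5

    def test_node_order_invariance(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(12)]
        edges = {}
        for i in range(12):
            for j in range(i + 1, 12):
                if (i // 4) == (j // 4) or rng.random() < 0.05:
                    edges[(nodes[i], nodes[j])] = float(rng.integers(50, 150))
        ref = sorted(tuple(m) for m in mcl(nodes, edges).families.values())
        for _ in range(8):
            perm = list(nodes)
            rng.shuffle(perm)
            shuffled_edges = {}
            for (a, b), w in edges.items():
                key = (a, b) if a < b else (b, a)
                shuffled_edges[key] = w
            got = sorted(tuple(m) for m in mcl(perm, shuffled_edges).families.values())
            assert got == ref

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl(["a"], {}, inflation=1.0)

    def test_partition_covers_all_nodes(self, small_dataset):
        _, _, truth = small_dataset
        proteins = {o.orf_id: o.protein for o in truth.orfs[:120]}
        edges = pairwise_scores(proteins)
        graph = mcl(proteins, edges)
        members = [m for fam in graph.families.values() for m in fam]
        assert sorted(members) == sorted(proteins)


class TestSharedContent:
    def test_enumeration_example(self):
        # N=10, n_i=4, n_j=5, k=3 -> 66/252
        oracle = hypergeom_upper_tail_enumeration(10, 4, 5, 3)
        assert oracle == pytest.approx(66 / 252)
        m = shared_content({"i": set(range(4)), "j": {0, 1, 2, 9}, "pad": set(range(10))})
        # direct check of the scipy path against the enumeration value
        assert float(hypergeom.sf(2, 10, 4, 5)) == pytest.approx(oracle, rel=1e-12)

    def test_matches_enumeration_exhaustively(self):
        """Upper-tail p equals exhaustive draw enumeration for small N."""
        for N in (5, 8, 12):
            for n_i in range(0, N + 1, 2):
                for n_j in range(0, N + 1, 3):
                    for k in range(0, min(n_i, n_j) + 1):
                        oracle = hypergeom_upper_tail_enumeration(N, n_i, n_j, k)
                        got = float(hypergeom.sf(k - 1, N, n_i, n_j))
                        assert got == pytest.approx(oracle, abs=1e-12)

    def test_k_zero_gives_one(self):
        assert float(hypergeom.sf(-1, 10, 4, 5)) == 1.0

    def test_forced_full_overlap(self):
        # n_i = N forces k = n_j and p = 1
        m = shared_content({"i": set(range(6)), "j": {1, 3}})
        i, j = m.contig_ids.index("i"), m.contig_ids.index("j")
        assert m.shared[i, j] == 2
        assert m.p_values[i, j] == pytest.approx(1.0)

    def test_monotone_in_k(self):
        N, n_i, n_j = 12, 6, 5
        ps = [float(hypergeom.sf(k - 1, N, n_i, n_j)) for k in range(0, 6)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            shared_content({"a": set()})

    def test_matrix_symmetric(self, small_dataset):
        _, _, truth = small_dataset
        fams = {}
        for o in truth.orfs:
            fams.setdefault(o.contig_id, set()).add(o.family_id)
        m = shared_content(fams)
        np.testing.assert_array_equal(m.p_values, m.p_values.T)
        assert (m.shared <= np.minimum.outer(m.n_families, m.n_families)).all()


def lance_williams_ward2(D):
    """Independent Ward.D2 agglomeration via the explicit recurrence.

    d(ij,k)^2 = ((n_i+n_k) d(i,k)^2 + (n_j+n_k) d(j,k)^2 - n_k d(i,j)^2)
                / (n_i+n_j+n_k); returns merge heights in order.
    """
    D2 = D.astype(float) ** 2
    active = {i: 1 for i in range(len(D))}
    heights = []
    D2 = D2.copy()
    while len(active) > 1:
        pairs = [(D2[i, j], i, j) for i in active for j in active if i < j]
        d2, i, j = min(pairs)
        heights.append(math.sqrt(d2))
        ni, nj = active[i], active[j]
        for k in active:
            if k in (i, j):
                continue
            nk = active[k]
            new = ((ni + nk) * D2[i, k] + (nj + nk) * D2[j, k] - nk * d2) / (ni + nj + nk)
            D2[i, k] = D2[k, i] = new
        active[i] = ni + nj
        del active[j]
    return heights


class TestWardCluster:
    def test_merge_heights_match_lance_williams(self):
        """scipy 'ward' equals the hand-applied Ward.D2 recurrence."""
        pts = np.array([[0.0], [1.0], [10.0], [11.5]])
        D = np.abs(pts - pts.T)
        expected = lance_williams_ward2(D)
        Z = linkage(squareform(D, checks=False), method="ward")
        np.testing.assert_allclose(sorted(Z[:, 2]), sorted(expected), rtol=1e-12)

    def test_two_separated_groups(self):
        from baconscope.genenet import SharedContentMatrix
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.05, (4, 2)), rng.normal(5, 0.05, (4, 2))])
        ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        D = squareform(pdist(pts))
        m = SharedContentMatrix(ids, np.ones(8), np.zeros((8, 8)), 1, np.ones((8, 8)), D)
        assign = ward_cluster(m, range(2, 6))
        assert assign.chosen_k == 2
        groups = {}
        for c, l in assign.labels.items():
            groups.setdefault(l, set()).add(c[0])
        assert sorted(map(tuple, groups.values())) == [("a",), ("b",)]
        assert all(s > 0.5 for s in assign.silhouettes.values())

    def test_dendrogram_heights_non_decreasing(self, small_dataset):
        _, _, truth = small_dataset
        fams = {}
        for o in truth.orfs:
            fams.setdefault(o.contig_id, set()).add(o.family_id)
        m = shared_content(fams)
        assign = ward_cluster(m)
        heights = assign.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_needs_three_contigs(self):
        m = shared_content({"a": {1}, "b": {2}})
        with pytest.raises(ValueError):
            ward_cluster(m)
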