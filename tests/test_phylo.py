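"""phylo: alignment, trimming, distances, NJ/bootstrap, clades, duplication mode."""

import itertools

import numpy as np
import pytest
from skbio import TreeNode

from baconscope import phylo, synth
from baconscope.phylo import (
    align,
    bootstrap,
    concat,
    distance_matrix,
    duplication_mode,
    kimura_distance,
    nj_tree,
    position_clades,
    trim,
)


class TestAlign:
    def test_identical_pair_gap_free(self):
        msa = align({"a": "MKWNQ", "b": "MKWNQ"})
        assert msa == {"a": "MKWNQ", "b": "MKWNQ"}

    def test_single_deletion_matches_hand_nw(self):
        # MKW vs MW: best affine alignment deletes K -> M-W under BLOSUM62
        # (S(M,M)+S(W,W)-open = 5+11-11 = 5 beats any substitution path)
        msa = align({"a": "MKW", "b": "MW"})
        assert msa["a"] == "MKW"
        assert msa["b"] in ("M-W", "-MW")
        assert msa["b"] == "M-W"

    def test_input_order_invariance(self):
        rng = np.random.default_rng(0)
        seqs = {f"s{i}": synth.random_protein(rng, 30) for i in range(5)}
        a = align(dict(sorted(seqs.items())))
        b = align(dict(sorted(seqs.items(), reverse=True)))
        assert a == b

    def test_conserved_residues_align_in_single_columns(self, seed_profile):
        """Planted invariant residues across diverged domains share columns."""
        cfg, ancestor, _, _ = seed_profile
        rng = np.random.default_rng(1)
        seqs = {
            f"d{i}": synth.mutate_protein(ancestor, 0.25, rng, cfg.conserved_positions)
            for i in range(8)
        }
        msa = align(seqs)
        cols = list(zip(*msa.values()))
        for res in cfg.conserved_residues:
            assert any(all(c == res for c in col) for col in cols)

    def test_single_sequence_trivial(self):
        assert align({"only": "MKW"}) == {"only": "MKW"}


class TestTrim:
    def test_gappy_column_removed_at_005(self):
        rows = {f"s{i}": ("A-" if i else "AW") for i in range(25)}  # 4% non-gap col 1
        trimmed, removed = trim(rows, 0.05)
        assert removed == [1]
        assert all(len(v) == 1 for v in trimmed.values())

    def test_gap_free_column_always_kept(self):
        rows = {"a": "W", "b": "W"}
        for gt in (0.0, 0.5, 1.0):
            trimmed, removed = trim(rows, gt)
            assert removed == []

    def test_manual_count_at_04(self):
        # column non-gap fractions: 1.0, 0.5, 0.25, 0.75 with gt=0.4 keep 0,1,3
        rows = {
            "a": "WAC-",
            "b": "WA-D",
            "c": "W--E",
            "d": "W-GF",
        }
        # fractions: col0=1.0, col1=0.5, col2=0.5, col3=0.75 -> recompute carefully
        trimmed, removed = trim(rows, 0.6)
        assert removed == [1, 2]
        assert trimmed["a"] == "W-"

    def test_identity_and_idempotence(self):
        rows = {"a": "MK-W", "b": "M-AW", "c": "MKAW"}
        same, removed = trim(rows, 0.0)
        assert same == rows and removed == []
        once, _ = trim(rows, 0.5)
        twice, removed2 = trim(once, 0.5)
        assert once == twice and removed2 == []

    def test_all_removed_errors(self):
        with pytest.raises(ValueError, match="every column"):
            trim({"a": "-", "b": "-"}, 0.5)


class TestConcat:
    def test_column_count_sums(self):
        a = {"x": "AAAAA", "y": "CCCCC"}
        b = {"x": "DDDDD", "y": "EEEEE"}
        msa, spans = concat([a, b])
        assert len(msa["x"]) == 10
        assert spans == [(0, 5), (5, 10)]

    def test_missing_id_padded(self):
        a = {"x": "AAA", "y": "CCC"}
        b = {"x": "DD"}
        msa, _ = concat([a, b])
        assert msa["y"] == "CCC--"

    def test_disjoint_ids_error(self):
        with pytest.raises(ValueError, match="share no ids"):
            concat([{"x": "A"}, {"y": "C"}])


class TestDistances:
    def test_identical_rows_zero(self):
        ids, D, flags = distance_matrix({"a": "MKWNQARGHE", "b": "MKWNQARGHE", "c": "MKWNQARGHE"})
        np.testing.assert_allclose(D, 0.0)

    def test_formula_value(self):
        # p=0.1: -ln(1 - 0.1 - 0.002)
        assert kimura_distance(0.1) == pytest.approx(-np.log(0.898), rel=1e-12)
        assert kimura_distance(0.1) == pytest.approx(0.1076, abs=2e-4)

    def test_saturation_capped(self):
        assert kimura_distance(0.95) == phylo.SATURATION_CAP

    def test_low_coverage_flagged(self):
        msa = {"a": "MKWNQ----", "b": "----QARGH", "c": "MKWNQARGH"}
        ids, D, flags = distance_matrix(msa, min_shared=10)
        i, j = ids.index("a"), ids.index("b")
        assert flags[i, j]

    def test_monotone_in_divergence(self, seed_profile):
        """Kimura distance increases with simulated substitution load."""
        cfg, ancestor, _, _ = seed_profile
        rng = np.random.default_rng(3)
        seqs = {"anc": ancestor}
        rates = [0.05, 0.15, 0.3, 0.45, 0.6]
        for r in rates:
            seqs[f"r{int(r*100):02d}"] = synth.mutate_protein(ancestor, r, rng, ())
        msa = align(seqs)
        ids, D, _ = distance_matrix(msa, min_shared=5)
        a = ids.index("anc")
        ds = [D[a, ids.index(f"r{int(r*100):02d}")] for r in rates]
        assert all(x < y for x, y in zip(ds, ds[1:]))


def random_additive_matrix(rng, n):
    """Build a random binary tree, return its leaf names, patristic matrix, splits."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    for nd in nodes:
        nd.length = float(rng.uniform(0.1, 1.0))
    pool = list(nodes)
    while len(pool) > 2:
        i, j = sorted(rng.choice(len(pool), 2, replace=False))
        parent = TreeNode(children=[pool[i], pool[j]])
        parent.length = float(rng.uniform(0.1, 1.0))
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [parent]
    root = TreeNode(children=pool)
    names = [f"t{i}" for i in range(n)]
    D = np.zeros((n, n))
    tip = {t.name: t for t in root.tips()}
    for a, b in itertools.combinations(range(n), 2):
        d = tip[names[a]].distance(tip[names[b]])
        D[a, b] = D[b, a] = d
    return names, D, phylo._splits(root, frozenset(names))


class TestNJ:
    def test_four_taxon_additive_exact(self):
        # ((A:1,B:1):2.5,(C:1.5,D:0.5)); pairwise path lengths
        D = np.array(
            [
                [0.0, 2.0, 5.0, 4.0],
                [2.0, 0.0, 5.0, 4.0],
                [5.0, 5.0, 0.0, 2.0],
                [4.0, 4.0, 2.0, 0.0],
            ]
        )
        tree = nj_tree(list("ABCD"), D)
        splits = phylo._splits(tree, frozenset("ABCD"))
        assert splits == {frozenset("CD")} or splits == {frozenset("AB")}
        # patristic distances reproduce the input exactly
        tip = {t.name: t for t in tree.tips()}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert tip[a].distance(tip[b]) == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = nj_tree(["a", "b", "c"], D)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": pytest.approx(1.0), "b": pytest.approx(2.0), "c": pytest.approx(3.0)}

    def test_recovers_additive_topologies_up_to_12(self):
        """NJ is exact on noiseless additive matrices (4..12 taxa)."""
        rng = np.random.default_rng(7)
        for n in range(4, 13):
            names, D, true_splits = random_additive_matrix(rng, n)
            tree = nj_tree(names, D)
            assert phylo._splits(tree, frozenset(names)) == true_splits

    def test_non_finite_rejected(self):
        D = np.zeros((4, 4))
        D[0, 1] = D[1, 0] = np.inf
        with pytest.raises(ValueError):
            nj_tree(list("ABCD"), D)


class TestBootstrap:
    def test_clean_clades_high_support(self, seed_profile):
        cfg, ancestor, _, _ = seed_profile
        rng = np.random.default_rng(5)
        # two well-separated families of sequences
        other = synth.random_protein(rng, len(ancestor))
        seqs = {}
        for i in range(4):
            seqs[f"a{i}"] = synth.mutate_protein(ancestor, 0.05, rng, ())
            seqs[f"b{i}"] = synth.mutate_protein(other, 0.05, rng, ())
        msa = align(seqs)
        tree = bootstrap(msa, B=50, seed=9)
        taxa = frozenset(seqs)
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if side in ({f"a{i}" for i in range(4)}, {f"b{i}" for i in range(4)}):
                assert float(node.name) > 90


class TestPositionClades:
    def test_perfect_partition(self):
        nwk = "(((a1:1,a2:1):1,(b1:1,b2:1):1):1,((c1:1,x:1):1,c2:1):1);"
        tree = TreeNode.read([nwk])
        labels = {"a1": 1, "a2": 1, "b1": 2, "b2": 2, "c1": 3, "c2": 3}
        rep = position_clades(tree, labels)
        assert rep["n_monophyletic"] == 3
        assert all(r["purity"] == 1.0 for r in rep["classes"].values())
        assert rep["candidate_ancestral_position"] == 3  # x sits inside clade 3's LCA

    def test_star_tree_nothing_monophyletic(self):
        tree = TreeNode.read(["(a1:1,a2:1,b1:1,b2:1);"])
        rep = position_clades(tree, {"a1": 1, "b1": 1, "a2": 2, "b2": 2})
        assert rep["n_monophyletic"] == 0

    def test_missing_label_errors(self):
        tree = TreeNode.read(["(a:1,b:1,c:1);"])
        with pytest.raises(ValueError, match="missing"):
            position_clades(tree, {"zz": 1})

    def test_synthetic_low_divergence_arrays(self, seed_profile):
        """Array-position classes form clades when arrays evolve vertically."""
        cfg, ancestor, _, _ = seed_profile
        rng = np.random.default_rng(6)
        events = synth.sample_history(8, "single", rng)
        base, _ = synth.replay_history(ancestor, events, 0.05, 77)
        base = [synth.mutate_protein(d, 0.1, rng, cfg.conserved_positions) for d in base]
        seqs, labels = {}, {}
        for li in range(6):
            for pos in range(8):
                name = f"l{li}p{pos + 1}"
                seqs[name] = synth.mutate_protein(base[pos], 0.015, rng, cfg.conserved_positions)
                labels[name] = pos + 1
        msa = align(seqs)
        trimmed, _ = trim(msa, 0.4)
        ids, D, _ = distance_matrix(trimmed)
        tree = nj_tree(ids, D)
        rep = position_clades(tree, labels)
        assert rep["n_monophyletic"] >= 7


class TestDuplicationMode:
    def test_identical_domains_single(self):
        dm = duplication_mode(["MKWNQARGHEWNRQCDEFGH"] * 5)
        assert dm.classification == "single-domain"

    def test_block_two_detected(self, seed_profile):
        cfg, ancestor, _, _ = seed_profile
        rng = np.random.default_rng(8)
        d1 = ancestor
        d2 = synth.mutate_protein(ancestor, 0.4, rng, cfg.conserved_positions)
        # [d1 d2] -> [d1 d2 d1 d2 d1 d2] then diverge each copy independently
        arr = [synth.mutate_protein(d, 0.1, rng, cfg.conserved_positions) for d in [d1, d2] * 3]
        dm = duplication_mode(arr)
        assert dm.classification == "block:2"
        assert dm.offset_profile[1] > dm.offset_profile[0]

    def test_too_few_domains(self):
        with pytest.raises(ValueError, match="at least 3"):
            duplication_mode(["AAA", "AAA"])

    def test_classifier_accuracy_small(self, seed_profile):
        """Spot accuracy on 10 single + 10 block simulated histories."""
        cfg, ancestor, _, _ = seed_profile
        rng = np.random.default_rng(9)
        correct = 0
        for i in range(10):
            ev = synth.sample_history(8, "single", rng)
            arr, _ = synth.replay_history(ancestor, ev, 0.05, 300 + i)
            correct += duplication_mode(arr).classification == "single-domain"
            ev = synth.sample_history(6, "block:2", rng)
            arr, _ = synth.replay_history(ancestor, ev, 0.05, 400 + i)
            correct += duplication_mode(arr).classification.startswith("block")
        assert correct >= 18
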