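import numpy as np
import pytest

import barcodegap as bg
from barcodegap.errors import NewickParseError, TreeError
from barcodegap.njtree import _nj_agglomerate

from conftest import random_additive_tree


def dm(ids, values):
    values = np.asarray(values, dtype=float)
    return bg.PairwiseDistanceMatrix(
        tuple(ids), values, "k2p", np.ones_like(values, dtype=np.int64)
    )


class TestNeighborJoining:
    def test_recovers_four_taxon_additive_tree(self):
        # Unrooted tree: A-u=1, B-u=2, u-v=1, C-v=3, D-v=4
        D = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        tree = bg.neighbor_joining(dm("ABCD", D))
        assert set(tree.bipartitions()) == {frozenset("CD")}
        assert np.allclose(tree.path_distance_matrix(tuple("ABCD")), D, atol=1e-9)

    def test_three_taxa_closed_form(self):
        tree = bg.neighbor_joining(dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
        # pendant lengths (dAB+dAC-dBC)/2 etc: 1, 2, 3
        assert np.allclose(
            tree.path_distance_matrix(tuple("ABC")),
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            atol=1e-12,
        )

    @pytest.mark.parametrize("n_taxa", [5, 8, 12])
    def test_exact_recovery_on_random_additive_matrices(self, n_taxa):
        for seed in range(5):
            rng = np.random.default_rng(1000 * n_taxa + seed)
            newick, labels = random_additive_tree(n_taxa, rng)
            truth = bg.parse_newick(newick)
            D = truth.path_distance_matrix(tuple(labels))
            tree = bg.neighbor_joining(dm(labels, D))
            assert set(tree.bipartitions()) == set(truth.bipartitions())
            assert np.allclose(tree.path_distance_matrix(tuple(labels)), D, atol=1e-9)

    def test_agrees_with_skbio_on_noisy_matrices(self):
        skbio = pytest.importorskip("skbio")
        for seed in range(5):
            rng = np.random.default_rng(seed)
            newick, labels = random_additive_tree(8, rng)
            D = bg.parse_newick(newick).path_distance_matrix(tuple(labels))
            D = D + rng.uniform(0, 0.05, size=D.shape)
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            mine = bg.neighbor_joining(dm(labels, D))
            other = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
            theirs = set()
            n = len(labels)
            ref = min(labels)
            for node in other.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = frozenset(labels) - side
                if 2 <= len(side) <= n - 2:
                    theirs.add(side)
            assert set(mine.bipartitions()) == theirs

    def test_binary_tree_has_n_minus_3_internal_splits(self):
        for n in (4, 7, 11):
            rng = np.random.default_rng(n)
            newick, labels = random_additive_tree(n, rng)
            D = bg.parse_newick(newick).path_distance_matrix(tuple(labels))
            tree = bg.neighbor_joining(dm(labels, D))
            assert len(tree.bipartitions()) == n - 3

    def test_too_few_or_nonfinite_rejected(self):
        with pytest.raises(TreeError):
            bg.neighbor_joining(dm("AB", [[0, 1], [1, 0]]))
        with pytest.raises(TreeError):
            bg.neighbor_joining(dm("ABC", [[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]]))

    def test_negative_branch_clamped(self):
        # A matrix violating the four-point condition yields a negative NJ
        # branch estimate; output lengths must still be >= 0.
        D = [[0, 2, 2, 2.2], [2, 0, 2.2, 2], [2, 2.2, 0, 0.1], [2.2, 2, 0.1, 0]]
        children, root_children, _ = _nj_agglomerate(np.array(D))
        lengths = [l for pair in children.values() for _, l in pair]
        lengths += [l for _, l in root_children]
        assert all(l >= 0 for l in lengths)


class TestNewickIO:
    def test_roundtrip_preserves_everything(self, tmp_path):
        text = "(A:1,B:2,(C:3,D:4)95:1.5);"
        tree = bg.parse_newick(text)
        assert set(tree.bipartitions()) == {frozenset("CD")}
        assert tree.bipartitions()[frozenset("CD")] == 95.0
        p = tmp_path / "t.nwk"
        bg.write_newick(tree, p)
        back = bg.read_newick(p)
        assert back.bipartitions() == tree.bipartitions()
        assert np.allclose(
            back.path_distance_matrix(tuple("ABCD")),
            tree.path_distance_matrix(tuple("ABCD")),
            rtol=1e-10,
        )

    def test_branch_lengths_to_ten_significant_digits(self, tmp_path):
        tree = bg.parse_newick("(A:0.1234567891234,B:2,(C:3,D:4):1);")
        p = tmp_path / "t.nwk"
        bg.write_newick(tree, p)
        assert "0.1234567891" in p.read_text()

    @pytest.mark.parametrize("bad", ["(A:1,B:2", "(A:1,(),B:2);", "();"])
    def test_malformed_or_unlabeled_rejected(self, bad):
        with pytest.raises(NewickParseError):
            bg.parse_newick(bad)


def two_cluster_alignment(per=2, L=600, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=L)
    other = base.copy()
    sub = rng.choice(L, size=L // 3, replace=False)
    other[sub] = [{"A": "G", "G": "A", "C": "T", "T": "C"}[b] for b in other[sub]]
    rows = {}
    species = {}
    for k in range(per):
        ra, rb = base.copy(), other.copy()
        ra[rng.integers(L)] = "A"
        rb[rng.integers(L)] = "C"
        rows[f"a{k}"] = "".join(ra)
        rows[f"b{k}"] = "".join(rb)
        species[f"a{k}"] = "spA"
        species[f"b{k}"] = "spB"
    return bg.MarkerAlignment("m", list(rows), species, rows)


class TestBootstrapSupports:
    def test_clear_split_gets_high_support(self):
        aln = two_cluster_alignment()
        tree = bg.bootstrap_supports(aln, "k2p", n_replicates=100, seed=5)
        assert all(v >= 95 for v in tree.supports.values())

    def test_single_replicate_supports_are_zero_or_hundred(self):
        aln = two_cluster_alignment(per=3)
        tree = bg.bootstrap_supports(aln, "k2p", n_replicates=1, seed=2)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_same_seed_bit_identical(self):
        aln = two_cluster_alignment(per=3)
        t1 = bg.bootstrap_supports(aln, "k2p", 50, seed=9)
        t2 = bg.bootstrap_supports(aln, "k2p", 50, seed=9)
        assert t1.as_newick() == t2.as_newick()
        assert t1.supports == t2.supports

    def test_supports_invariant_to_tip_order(self):
        # Distinct per-tip substitution counts keep pairwise distances free of
        # exact ties, so NJ is permutation-equivariant and supports must match.
        rng = np.random.default_rng(21)
        L = 800
        base = rng.choice(list("ACGT"), size=L)
        rows, species = {}, {}
        for k in range(6):
            r = base.copy()
            pos = rng.choice(L, size=11 + 17 * k, replace=False)
            r[pos] = [{"A": "G", "G": "C", "C": "T", "T": "A"}[b] for b in r[pos]]
            rows[f"s{k}"] = "".join(r)
            species[f"s{k}"] = f"sp{k % 2}"
        aln = bg.MarkerAlignment("m", list(rows), species, rows)
        perm = list(aln.sample_ids)[::-1]
        aln2 = bg.MarkerAlignment(
            "m", perm, dict(aln.species_of), {s: aln.rows[s] for s in perm}
        )
        t1 = bg.bootstrap_supports(aln, "k2p", 50, seed=11)
        t2 = bg.bootstrap_supports(aln2, "k2p", 50, seed=11)
        assert t1.supports == t2.supports
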