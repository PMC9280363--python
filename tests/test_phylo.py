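import itertools

import numpy as np
import pytest

from guarmir.phylo import (
    DistanceMatrix, TreeNode, bipartitions, bootstrap_supports, nj_tree,
    p_distance, pairwise_align, progressive_msa,
)


def oracle_best_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> float:
    """Enumerate every global alignment recursively; return the best score."""
    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = -1e9
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def random_tree_matrix(rng, n_taxa):
    """A random additive matrix built from a random binary tree by
    summing branch lengths along leaf-to-leaf paths (independent of NJ)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = {l: TreeNode(label=l) for l in labels}
    # leaf -> accumulated path lengths to every leaf below it
    below = {l: {l: 0.0} for l in labels}
    active = list(labels)
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.integers(1, 9, size=2).astype(float)
        parent = f"({a},{b})"
        nodes[parent] = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        below[parent] = {
            **{leaf: d + la for leaf, d in below[a].items()},
            **{leaf: d + lb for leaf, d in below[b].items()},
        }
        active = [x for k, x in enumerate(active) if k not in (i, j)]
        active.append(parent)
    la, lb, lc = rng.integers(1, 9, size=3).astype(float)
    a, b, c = active
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    d = np.zeros((n_taxa, n_taxa))

    def leaf_depths(node, depth, acc):
        if node.is_leaf:
            acc[node.label] = depth
            return
        for ch, ln in node.children:
            leaf_depths(ch, depth + ln, acc)

    def fill(node):
        for ch, ln in node.children:
            fill(ch)
        # distances between leaves in different child subtrees of node
        groups = []
        for ch, ln in node.children:
            acc = {}
            leaf_depths(ch, ln, acc)
            groups.append(acc)
        for g1, g2 in itertools.combinations(groups, 2):
            for l1, d1 in g1.items():
                for l2, d2 in g2.items():
                    i1, i2 = labels.index(l1), labels.index(l2)
                    d[i1, i2] = d[i2, i1] = d1 + d2

    fill(root)
    return DistanceMatrix(tuple(labels), d), root


def bip_set(tree):
    return set(bipartitions(tree).keys())


class TestPairwiseAlign:
    def test_identity(self):
        aa, bb, score = pairwise_align("ACGU", "ACGU")
        assert (aa, bb, score) == ("ACGU", "ACGU", 4.0)

    def test_single_gap(self):
        aa, bb, score = pairwise_align("ACGU", "AGU")
        assert score == 1.0
        assert (aa, bb) == ("ACGU", "A-GU")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("", "ACGT")

    def test_matches_enumeration_oracle_all_short_pairs(self):
        alphabet = "AC"
        seqs = ["".join(t) for n in (1, 2, 3)
                for t in itertools.product(alphabet, repeat=n)]
        for a in seqs:
            for b in seqs:
                _, _, score = pairwise_align(a, b)
                assert score == oracle_best_score(a, b), (a, b)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_oracle_random_longer_pairs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGU"), size=rng.integers(1, 7)))
            b = "".join(rng.choice(list("ACGU"), size=rng.integers(1, 7)))
            assert pairwise_align(a, b)[2] == oracle_best_score(a, b)

    def test_alignment_score_is_consistent(self, rng):
        a = "".join(rng.choice(list("ACGU"), size=30))
        b = "".join(rng.choice(list("ACGU"), size=25))
        aa, bb, score = pairwise_align(a, b)
        recomputed = sum(
            -2 if "-" in (x, y) else (1 if x == y else -1)
            for x, y in zip(aa, bb)
        )
        assert recomputed == score
        assert aa.replace("-", "") == a and bb.replace("-", "") == b


class TestPDistance:
    def test_identical(self):
        assert p_distance("ACGU", "ACGU") == 0.0

    def test_one_in_four(self):
        assert p_distance("AAAA", "AAAU") == 0.25

    def test_gap_sites_excluded(self):
        assert p_distance("A-CG", "AUCG") == 0.0

    def test_gap_only_overlap_is_zero(self):
        assert p_distance("A---", "---A") == 0.0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(DistanceMatrix(("a", "b", "c"), d))
        lengths = {ch.label: ln for ch, ln in tree.children}
        assert lengths == {"a": 2.0, "b": 3.0, "c": 7.0}

    def test_fewer_than_three_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), d))

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_recovers_random_additive_trees(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            dm, true_tree = random_tree_matrix(rng, n_taxa)
            est = nj_tree(dm)
            assert bip_set(est) == bip_set(true_tree)
            # branch lengths: re-derive the leaf-to-leaf path metric
            def paths(tree, labels):
                out = np.zeros((len(labels), len(labels)))
                idx = {l: i for i, l in enumerate(labels)}

                def depths(node, d0, acc):
                    if node.is_leaf:
                        acc[node.label] = d0
                    for ch, ln in node.children:
                        depths(ch, d0 + ln, acc)

                def fill(node):
                    accs = []
                    for ch, ln in node.children:
                        acc = {}
                        depths(ch, ln, acc)
                        accs.append(acc)
                        fill(ch)
                    for g1, g2 in itertools.combinations(accs, 2):
                        for l1, v1 in g1.items():
                            for l2, v2 in g2.items():
                                out[idx[l1], idx[l2]] = v1 + v2
                                out[idx[l2], idx[l1]] = v1 + v2
                fill(tree)
                return out

            assert np.allclose(paths(est, dm.labels), dm.d)

    def test_label_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(42)
        dm, _ = random_tree_matrix(rng, 6)
        perm = rng.permutation(len(dm.labels))
        dm2 = DistanceMatrix(
            tuple(dm.labels[i] for i in perm), dm.d[np.ix_(perm, perm)])
        assert bip_set(nj_tree(dm)) == bip_set(nj_tree(dm2))

    def test_agrees_with_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        rng = np.random.default_rng(7)
        dm, _ = random_tree_matrix(rng, 6)
        sk_tree = sk_nj(SkDM(dm.d, ids=list(dm.labels)))
        ours = bip_set(nj_tree(dm))
        ref = min(dm.labels)
        theirs = set()
        all_leaves = frozenset(dm.labels)
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(all_leaves) - 2:
                theirs.add(side if ref not in side else all_leaves - side)
        assert ours == theirs


class TestProgressiveMsaAndBootstrap:
    LABELS = ["s1", "s2", "s3", "s4", "s5"]

    def test_msa_preserves_sequences(self):
        seqs = ["ACGUACGU", "ACGACGU", "ACGUACG", "AGGUACGU", "ACGUUCGU"]
        msa = progressive_msa(self.LABELS, seqs)
        assert len({len(r) for r in msa}) == 1
        for row, seq in zip(msa, seqs):
            assert row.replace("-", "") == seq

    def test_congruent_signal_gives_all_supports_100(self):
        # every column carries the identical split: replicates cannot differ
        seqs = ["AAAAAAAA", "AAAAAAAA", "CCCCCCCC", "CCCCCCCC", "GGGGGGGG"]
        msa = progressive_msa(self.LABELS, seqs)
        _, supports = bootstrap_supports(self.LABELS, msa, n_reps=100, seed=0)
        assert supports  # at least one internal edge
        assert all(v == 100.0 for v in supports.values())

    def test_fixed_seed_reproducible(self):
        seqs = ["ACGUACGUAC", "ACGUACGUCC", "ACGGACGUAA", "CCGGACGUAA",
                "CCGGACGGAA"]
        msa = progressive_msa(self.LABELS, seqs)
        r1 = bootstrap_supports(self.LABELS, msa, n_reps=150, seed=3)[1]
        r2 = bootstrap_supports(self.LABELS, msa, n_reps=150, seed=3)[1]
        assert r1 == r2

    def test_supports_match_independent_resampler(self):
        # independently coded resampling loop with python's RNG
        import random as pyrandom
        seqs = ["ACGUACGUACGUACG", "ACGUACGUACGUCCG", "ACGGACGUACGAACG",
                "CCGGACGUUCGAACG", "CCGGACGGUCGAACG"]
        msa = progressive_msa(self.LABELS, seqs)
        ref_tree = nj_tree(DistanceMatrix.from_alignment(self.LABELS, msa))
        ref_bips = set(bipartitions(ref_tree))
        prng = pyrandom.Random(99)
        ncol = len(msa[0])
        counts = {b: 0 for b in ref_bips}
        n_reps = 200
        for _ in range(n_reps):
            idx = [prng.randrange(ncol) for _ in range(ncol)]
            rows = ["".join(r[c] for c in idx) for r in msa]
            rep = set(bipartitions(
                nj_tree(DistanceMatrix.from_alignment(self.LABELS, rows))))
            for b in counts:
                counts[b] += b in rep
        independent = {b: 100.0 * c / n_reps for b, c in counts.items()}
        _, ours = bootstrap_supports(self.LABELS, msa, n_reps=200, seed=1)
        assert set(ours) == set(independent)
        for b in ours:
            p = independent[b] / 100.0
            sigma = 100.0 * np.sqrt(max(p * (1 - p), 0.002) / n_reps)
            assert abs(ours[b] - independent[b]) <= 4 * sigma + 2.0

    def test_supports_in_range_and_invariant_to_leaf_order(self):
        seqs = ["ACGUACGUAC", "ACGUACGUCC", "ACGGACGUAA", "CCGGACGUAA",
                "CCGGACGGAA"]
        msa = progressive_msa(self.LABELS, seqs)
        _, sup = bootstrap_supports(self.LABELS, msa, n_reps=100, seed=2)
        assert all(0.0 <= v <= 100.0 for v in sup.values())
        perm = [3, 1, 4, 0, 2]
        labels_p = [self.LABELS[i] for i in perm]
        msa_p = [msa[i] for i in perm]
        _, sup_p = bootstrap_supports(labels_p, msa_p, n_reps=100, seed=2)
        assert set(sup_p) == set(sup)
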