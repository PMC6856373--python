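"""Distances, NJ correctness on additive matrices, bootstrap support, Newick."""

import numpy as np
import pytest

import dendropy

from naddkit import fixtures as fx
from naddkit import phylogeny as ph
from naddkit.coevolution import Alignment


def _additive_quartet(rng):
    """Random additive 4-taxon tree: ((A,B),(C,D)) with positive branches.

    Returns (ids, distance matrix, internal branch, leaf branches)."""
    ids = ["A", "B", "C", "D"]
    a, b, c, d = rng.uniform(0.1, 5.0, 4)
    m = rng.uniform(0.1, 5.0)  # internal edge
    dmat = np.array(
        [
            [0, a + b, a + m + c, a + m + d],
            [a + b, 0, b + m + c, b + m + d],
            [a + m + c, b + m + c, 0, c + d],
            [a + m + d, b + m + d, c + d, 0],
        ],
        float,
    )
    return ids, dmat, m, (a, b, c, d)


def _path_lengths(tree):
    """Leaf-to-leaf patristic distances keyed by frozenset of labels."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


class TestDistances:
    def test_identical_sequences_zero(self):
        aln = Alignment(["a", "b", "c"], ["ACDE", "ACDE", "ACDE"])
        dm = ph.p_distance(aln)
        assert np.allclose(dm.matrix, 0.0)

    def test_single_mismatch_quarter(self):
        aln = Alignment(["a", "b", "c"], ["AAAA", "AAAT", "AAAA"])
        dm = ph.p_distance(aln)
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_matches_brute_force(self):
        rng = np.random.default_rng(41)
        alpha = list("ACDEFGHIKL-")
        rows = ["".join(rng.choice(alpha, 60)) for _ in range(5)]
        aln = Alignment([f"t{i}" for i in range(5)], rows)
        dm = ph.p_distance(aln)
        for i in range(5):
            for j in range(i + 1, 5):
                pairs = [
                    (x, y)
                    for x, y in zip(rows[i], rows[j])
                    if x != "-" and y != "-"
                ]
                brute = sum(x != y for x, y in pairs) / len(pairs)
                assert dm.matrix[i, j] == pytest.approx(brute)

    def test_no_comparable_sites_errors(self):
        aln = Alignment(["a", "b", "c"], ["A-A", "-C-", "ACA"])
        with pytest.raises(ValueError):
            ph.p_distance(aln)

    def test_poisson_correction(self):
        ids = ["a", "b", "c"]
        p = np.zeros((3, 3))
        p[0, 1] = p[1, 0] = 0.25
        dm = ph.poisson_correct(ph.DistanceMatrix(ids, p))
        assert dm.matrix[0, 1] == pytest.approx(0.2877, abs=1e-4)
        assert dm.matrix[0, 2] == 0.0

    def test_poisson_saturated_errors(self):
        p = np.array([[0, 1.0, 0.5], [1.0, 0, 0.5], [0.5, 0.5, 0]])
        with pytest.raises(ValueError):
            ph.poisson_correct(ph.DistanceMatrix(["a", "b", "c"], p))

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            ph.DistanceMatrix(["a", "b"], m)


class TestNeighborJoining:
    def test_spec_quartet_recovered_exactly(self):
        # additive distances from tree ((A:1,B:2):1,(C:3,D:4))
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = ph.neighbor_joining(ph.DistanceMatrix(ids, d))
        assert ph.bipartitions(tree) == {frozenset({"C", "D"})}
        paths = _path_lengths(tree)
        for pair, expect in [
            (("A", "B"), 3), (("A", "C"), 5), (("A", "D"), 6),
            (("B", "C"), 6), (("B", "D"), 7), (("C", "D"), 7),
        ]:
            assert paths[frozenset(pair)] == pytest.approx(expect)

    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = ph.neighbor_joining(ph.DistanceMatrix(ids, d))
        paths = _path_lengths(tree)
        assert paths[frozenset(("a", "b"))] == pytest.approx(2)
        assert paths[frozenset(("a", "c"))] == pytest.approx(3)
        assert paths[frozenset(("b", "c"))] == pytest.approx(5)

    def test_additive_matrices_reproduced(self):
        rng = np.random.default_rng(47)
        for _ in range(25):
            ids, dmat, _, _ = _additive_quartet(rng)
            tree = ph.neighbor_joining(ph.DistanceMatrix(ids, dmat))
            assert ph.bipartitions(tree) == {frozenset({"C", "D"})}
            paths = _path_lengths(tree)
            for i in range(4):
                for j in range(i + 1, 4):
                    assert paths[frozenset((ids[i], ids[j]))] == pytest.approx(
                        dmat[i, j]
                    )

    def test_agrees_with_skbio_on_random_metric(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(53)
        for _ in range(5):
            ids, dmat, _, _ = _additive_quartet(rng)
            ours = ph.bipartitions(
                ph.neighbor_joining(ph.DistanceMatrix(ids, dmat))
            )
            sk_tree = skbio_nj(SkbioDM(dmat, ids))
            sk_newick = sk_tree.__str__()
            theirs = ph.bipartitions(ph.read_newick(sk_newick))
            assert ours == theirs

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            ph.neighbor_joining(
                ph.DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
            )


class TestBootstrap:
    def test_two_clade_fixture_high_support(self):
        aln = fx.make_clade_msa(5, 200, seed=61)
        res = ph.bootstrap_support(aln, n_replicates=100, seed=2)
        clade_b = frozenset(f"B{i}" for i in range(1, 6))
        assert res.support[clade_b] >= 99.0

    def test_single_replicate_support_binary(self):
        aln = fx.make_clade_msa(4, 120, seed=63)
        res = ph.bootstrap_support(aln, n_replicates=1, seed=5)
        assert set(res.support.values()) <= {0.0, 100.0}

    def test_clade_support_invariant_to_taxon_order(self):
        # weakly supported splits may differ under permutation when p-distances
        # tie exactly (index-based tie-breaking); the clade split may not
        aln = fx.make_clade_msa(4, 150, seed=67)
        perm = np.random.default_rng(0).permutation(aln.n_seqs)
        shuffled = Alignment(
            [aln.ids[i] for i in perm], [aln.rows[i] for i in perm]
        )
        clade_b = frozenset(f"B{i}" for i in range(1, 5))
        r1 = ph.bootstrap_support(aln, n_replicates=30, seed=9)
        r2 = ph.bootstrap_support(shuffled, n_replicates=30, seed=9)
        assert clade_b in r1.support and clade_b in r2.support
        assert r1.support[clade_b] == r2.support[clade_b]

    def test_seeded_reproducibility(self):
        aln = fx.make_clade_msa(4, 100, seed=71)
        r1 = ph.bootstrap_support(aln, n_replicates=20, seed=13)
        r2 = ph.bootstrap_support(aln, n_replicates=20, seed=13)
        assert r1.support == r2.support


class TestNewick:
    def test_three_leaf_shape(self):
        ids = ["A", "B", "C"]
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        text = ph.write_newick(ph.neighbor_joining(ph.DistanceMatrix(ids, d)))
        assert text.startswith("(") and text.rstrip().endswith(";")
        assert all(leaf in text for leaf in ids)

    def test_roundtrip_stable(self):
        rng = np.random.default_rng(73)
        ids, dmat, _, _ = _additive_quartet(rng)
        tree = ph.neighbor_joining(ph.DistanceMatrix(ids, dmat))
        text1 = ph.write_newick(tree)
        text2 = ph.write_newick(ph.read_newick(text1))
        assert text1 == text2

    def test_supports_serialized(self):
        aln = fx.make_clade_msa(4, 150, seed=79)
        res = ph.bootstrap_support(aln, n_replicates=20, seed=3)
        text = ph.write_newick(res.tree)
        reparsed = ph.read_newick(text)
        labels = [
            nd.label
            for nd in reparsed.preorder_node_iter()
            if not nd.is_leaf() and nd.label
        ]
        assert labels, "expected internal support labels in newick"
        assert all(0.0 <= float(l) <= 100.0 for l in labels)
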