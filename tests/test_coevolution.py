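"""Sequence weighting, KL conservation, MI z-scores, cMI/pMI and edge tiers."""

import numpy as np
import pandas as pd
import pytest

from naddkit import coevolution as cv
from naddkit import fixtures as fx


def _aln(rows, ids=None, **kw):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return cv.Alignment(ids, rows, **kw)


class TestAlignment:
    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            _aln(["ACD", "AC"])

    def test_reference_numbering_skips_gaps(self):
        aln = _aln(["A-CD", "AACD"], ids=["ref", "other"], reference_id="ref")
        assert list(aln.column_to_ref()) == [1, 0, 2, 3]


class TestWeights:
    def test_identical_pair_shares_one_cluster(self):
        aln = _aln(["ACDEFG", "ACDEFG"])
        w = cv.sequence_weights(aln, 0.62)
        assert np.allclose(w, [0.5, 0.5])

    def test_distinct_sequences_weight_one(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list(cv.STANDARD_AA), 40)) for _ in range(10)]
        w = cv.sequence_weights(_aln(rows), 0.62)
        assert np.allclose(w, 1.0)

    def test_unweighted_frequencies_match_tally(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list(cv.STANDARD_AA), 25)) for _ in range(12)]
        aln = _aln(rows)
        freqs, flagged, w = cv.weighted_frequencies(aln, pseudocount=0.0)
        assert np.allclose(w, 1.0)
        enc = cv.encode(aln)
        for c in range(aln.n_cols):
            tally = np.bincount(enc[:, c], minlength=20) / aln.n_seqs
            assert np.allclose(freqs[c], tally)
        assert not flagged.any()

    def test_all_gap_column_flagged(self):
        aln = _aln(["A-C", "A-C", "G-C", "T-C".replace("T", "W")])
        _, flagged, _ = cv.weighted_frequencies(aln)
        assert list(flagged) == [False, True, False]


class TestKL:
    def test_column_at_background_scores_zero(self):
        q = cv.BLOSUM62_BACKGROUND
        kl = cv.kl_conservation(q[None, :])
        assert abs(kl[0]) < 1e-12

    def test_uniform_vs_uniform_zero(self):
        p = np.full((1, 20), 0.05)
        assert abs(cv.kl_conservation(p, np.full(20, 0.05))[0]) < 1e-12

    def test_invariant_column_maximal(self):
        rng = np.random.default_rng(3)
        rows = ["C" + "".join(rng.choice(list(cv.STANDARD_AA), 14)) for _ in range(30)]
        aln = _aln(rows)
        freqs, flagged, _ = cv.weighted_frequencies(aln)
        kl = cv.kl_conservation(freqs, flagged=flagged)
        assert np.argmax(kl) == 0


class TestMI:
    def test_self_information_equals_entropy(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("AVSTLK"), 12)) for _ in range(24)]
        aln = _aln(rows)
        ones = np.ones(24)
        mi = cv.mutual_information(aln, pseudocount=0.0, weights=ones)
        h = cv.column_entropy(aln, weights=ones)
        assert np.nanmax(np.abs(np.diag(mi) - h)) < 1e-9

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        rows = ["".join(rng.choice(list(cv.STANDARD_AA), 15)) for _ in range(20)]
        mi = cv.mutual_information(_aln(rows), pseudocount=0.0)
        assert np.nanmax(np.abs(mi - mi.T)) < 1e-12

    def test_duplicated_column_attains_entropy(self):
        rng = np.random.default_rng(7)
        col = rng.choice(list("AVST"), 32)
        other = rng.choice(list(cv.STANDARD_AA), 32)
        rows = ["".join([col[i], col[i], other[i]]) for i in range(32)]
        aln = _aln(rows)
        ones = np.ones(32)
        mi = cv.mutual_information(aln, pseudocount=0.0, weights=ones)
        h = cv.column_entropy(aln, weights=ones)
        assert abs(mi[0, 1] - h[0]) < 1e-9

    def test_covarying_pair_has_top_zscore(self):
        aln = fx.make_covarying_msa(64, 30, planted_pairs=((4, 21),), seed=11)
        z = cv.mi_zscores(aln, n_shuffles=50, seed=2)
        iu, ju = np.triu_indices(30, 1)
        top = np.nanargmax(z[iu, ju])
        assert (iu[top], ju[top]) == (4, 21)

    def test_iid_columns_mean_z_small(self):
        rng = np.random.default_rng(13)
        rows = ["".join(rng.choice(list(cv.STANDARD_AA), 12)) for _ in range(40)]
        z = cv.mi_zscores(_aln(rows), n_shuffles=100, seed=3)
        iu, ju = np.triu_indices(12, 1)
        assert abs(np.nanmean(z[iu, ju])) < 0.5

    def test_seeded_pipeline_reproducible(self):
        aln = fx.make_covarying_msa(32, 12, seed=4)
        z1 = cv.mi_zscores(aln, n_shuffles=25, seed=9)
        z2 = cv.mi_zscores(aln, n_shuffles=25, seed=9)
        assert np.array_equal(np.nan_to_num(z1), np.nan_to_num(z2))

    def test_sequence_order_invariance(self):
        aln = fx.make_covarying_msa(24, 10, seed=8)
        perm = np.random.default_rng(1).permutation(24)
        shuffled = cv.Alignment(
            [aln.ids[i] for i in perm], [aln.rows[i] for i in perm]
        )
        mi1 = cv.mutual_information(aln, pseudocount=0.0)
        mi2 = cv.mutual_information(shuffled, pseudocount=0.0)
        assert np.allclose(np.nan_to_num(mi1), np.nan_to_num(mi2))


class TestCMI:
    def test_all_below_threshold(self):
        z = np.full((4, 4), 2.0)
        np.fill_diagonal(z, np.nan)
        assert np.allclose(cv.cumulative_mi(z, 6.5), 0.0)

    def test_single_passing_pair(self):
        z = np.full((4, 4), 0.0)
        z[1, 2] = z[2, 1] = 10.0
        np.fill_diagonal(z, np.nan)
        cmi = cv.cumulative_mi(z, 6.5)
        assert list(cmi) == [0.0, 10.0, 10.0, 0.0]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(21)
        z = rng.normal(5, 3, (10, 10))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        cmi = cv.cumulative_mi(z, 6.5)
        for i in range(10):
            brute = sum(
                z[i, j] for j in range(10) if j != i and z[i, j] > 6.5
            )
            assert abs(cmi[i] - brute) < 1e-12


class TestPMI:
    def test_chain_contacts(self):
        contacts = pd.DataFrame({"res_i": [1, 2], "res_j": [2, 3]})
        pmi = cv.proximity_mi(np.array([0.0, 10.0, 0.0]), contacts)
        assert list(pmi) == [10.0, 0.0, 10.0]

    def test_no_contacts_gives_nan(self):
        pmi = cv.proximity_mi(np.array([1.0, 2.0]), pd.DataFrame({"res_i": [], "res_j": []}))
        assert np.isnan(pmi).all()

    def test_dense_contacts_mean_of_others(self):
        cmi = np.array([1.0, 5.0, 9.0, 3.0])
        rows = [(i + 1, j + 1) for i in range(4) for j in range(i + 1, 4)]
        contacts = pd.DataFrame(rows, columns=["res_i", "res_j"])
        pmi = cv.proximity_mi(cmi, contacts)
        for i in range(4):
            assert abs(pmi[i] - np.mean(np.delete(cmi, i))) < 1e-12

    def test_out_of_range_contact_errors(self):
        with pytest.raises(ValueError):
            cv.proximity_mi(
                np.array([1.0]), pd.DataFrame({"res_i": [1], "res_j": [5]})
            )

    def test_radius_filtering(self):
        contacts = pd.DataFrame(
            {"res_i": [1, 1], "res_j": [2, 3], "distance": [4.0, 12.0]}
        )
        pmi = cv.proximity_mi(np.array([0.0, 7.0, 3.0]), contacts, radius=8.0)
        assert pmi[0] == 7.0 and np.isnan(pmi[2])


class TestTiers:
    def test_hundred_distinct_edges(self):
        z = np.full((200, 200), np.nan)
        vals = np.linspace(7.0, 20.0, 100)
        k = 0
        for i in range(100):
            z[2 * i, 2 * i + 1] = z[2 * i + 1, 2 * i] = vals[k]
            k += 1
        edges = cv.tier_edges(z, 6.5)
        assert len(edges) == 100
        assert (edges["tier"] == "top5").sum() == 5
        assert (edges["tier"] == "mid").sum() == 25
        assert (edges["tier"] == "low").sum() == 70
        assert edges["z"].is_monotonic_decreasing

    def test_single_edge_is_top(self):
        z = np.full((3, 3), np.nan)
        z[0, 1] = z[1, 0] = 8.0
        edges = cv.tier_edges(z, 6.5)
        assert list(edges["tier"]) == ["top5"]

    def test_no_edges_empty(self):
        z = np.zeros((4, 4))
        assert cv.tier_edges(z, 6.5).empty

    def test_random_edges_match_percentile_partition(self):
        rng = np.random.default_rng(31)
        n = 37
        z = np.full((2 * n, 2 * n), np.nan)
        vals = rng.uniform(6.6, 30, n)
        for i, v in enumerate(vals):
            z[2 * i, 2 * i + 1] = z[2 * i + 1, 2 * i] = v
        edges = cv.tier_edges(z, 6.5)
        n_top = int(np.ceil(0.05 * n))
        n_mid = int(np.ceil(0.30 * n)) - n_top
        assert (edges["tier"] == "top5").sum() == n_top
        assert (edges["tier"] == "mid").sum() == n_mid


def test_full_analysis_pipeline():
    aln = fx.make_covarying_msa(48, 16, planted_pairs=((2, 9),), seed=19)
    net = cv.analyze(aln, n_shuffles=30, seed=5)
    assert net.kl.shape == (16,)
    assert net.cmi.shape == (16,)
    assert not net.edges.empty
    top = net.edges.iloc[0]
    assert {int(top["col_i"]), int(top["col_j"])} == {2, 9}
    table = cv.per_column_table(net)
    assert list(table.columns) == ["column", "ref_residue", "kl", "cmi", "pmi"]
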