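import numpy as np
import pandas as pd
import pytest

import hlcbench as hb
from hlcbench import ValidationError

from conftest import make_metadata, make_normalized


# ---------------------------------------------------------------------------
# Euclidean distances
# ---------------------------------------------------------------------------


class TestDistanceMatrix:
    def test_self_distance_zero(self):
        m = make_normalized([[1.0, 2.0], [3.0, 4.0]])
        d = hb.distance_matrix(m)
        assert np.allclose(np.diag(d.distances), 0.0)

    def test_single_gene_difference(self):
        m = make_normalized([[1.0, 4.0], [2.0, 2.0]])
        d = hb.distance_matrix(m)
        assert np.isclose(d.distances.iloc[0, 1], 3.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 5))
        m = make_normalized(vals)
        d = hb.distance_matrix(m).distances.to_numpy()
        for i in range(5):
            for j in range(5):
                expected = np.sqrt(((vals[:, i] - vals[:, j]) ** 2).sum())
                assert np.isclose(d[i, j], expected)

    def test_gene_set_restriction_and_count(self):
        m = make_normalized([[0.0, 3.0], [0.0, 4.0], [0.0, 100.0]],
                            genes=["a", "b", "c"])
        gs = hb.GeneSet(name="pair", gene_ids=frozenset({"a", "b"}))
        d = hb.distance_matrix(m, gs)
        assert d.n_genes_matched == 2
        assert np.isclose(d.distances.iloc[0, 1], 5.0)

    def test_too_few_matched_genes_names_the_set(self):
        m = make_normalized([[0.0, 1.0]], genes=["a"])
        gs = hb.GeneSet(name="lonely", gene_ids=frozenset({"a"}))
        with pytest.raises(ValidationError, match="lonely"):
            hb.distance_matrix(m, gs)


# ---------------------------------------------------------------------------
# distance-based similarity
# ---------------------------------------------------------------------------


def toy_dbs():
    """One PHH control at 0; samples at distances 0, 2, 4 along one gene."""
    m = make_normalized(
        [[0.0, 0.0, 2.0, 4.0], [0.0, 0.0, 0.0, 0.0]],
        samples=["phh", "near", "mid", "far"],
    )
    meta = make_metadata(
        {"phh": "PHH/Liver", "near": "Hep-HLC", "mid": "Fib", "far": "Fib"}
    )
    return hb.dbs_scores(hb.distance_matrix(m), meta)


class TestDbsScores:
    def test_zero_distance_sample_scores_one(self):
        res = toy_dbs()
        assert res.median_dbs["near"] == 1.0

    def test_maximally_distant_sample_scores_zero(self):
        res = toy_dbs()
        assert res.median_dbs["far"] == 0.0

    def test_hand_distances_give_1_half_0(self):
        res = toy_dbs()
        assert res.max_phh == 4.0
        assert [res.median_dbs[s] for s in ("near", "mid", "far")] == [1.0, 0.5, 0.0]

    def test_scores_bounded_and_monotone(self, normalized_sim):
        normalized, _, metadata, _ = normalized_sim
        res = hb.dbs_scores(hb.distance_matrix(normalized), metadata)
        pw = res.pairwise
        assert ((pw["dbs"] >= 0) & (pw["dbs"] <= 1)).all()
        order = pw.sort_values("dist_phh")
        assert (order["dbs"].diff().dropna() <= 1e-12).all()

    def test_invariant_to_gene_and_sample_order(self, normalized_sim):
        normalized, _, metadata, _ = normalized_sim
        rng = np.random.default_rng(1)
        shuffled = hb.NormalizedMatrix(
            normalized.data.iloc[
                rng.permutation(normalized.data.shape[0]),
                rng.permutation(normalized.data.shape[1]),
            ],
            ["shuffled"],
        )
        a = hb.dbs_scores(hb.distance_matrix(normalized), metadata)
        b = hb.dbs_scores(hb.distance_matrix(shuffled), metadata)
        pd.testing.assert_series_equal(
            a.median_dbs.sort_index(), b.median_dbs.sort_index()
        )

    def test_outlier_raises_everyones_scores(self):
        base = toy_dbs()
        m = make_normalized(
            [[0.0, 0.0, 2.0, 4.0, 40.0], [0.0] * 5],
            samples=["phh", "near", "mid", "far", "outlier"],
        )
        meta = make_metadata(
            {
                "phh": "PHH/Liver",
                "near": "Hep-HLC",
                "mid": "Fib",
                "far": "Fib",
                "outlier": "PSC",
            }
        )
        bigger = hb.dbs_scores(hb.distance_matrix(m), meta)
        assert bigger.max_phh > base.max_phh
        for s in ("near", "mid", "far"):
            assert bigger.median_dbs[s] >= base.median_dbs[s]

    def test_phh_controls_scored_with_exclude_self(self):
        m = make_normalized(
            [[0.0, 1.0, 5.0]], samples=["phh1", "phh2", "q"],
            genes=["g0"],
        )
        # need >= 2 genes for distance over a set; use all genes (1 gene fine)
        meta = make_metadata({"phh1": "PHH/Liver", "phh2": "PHH/Liver", "q": "Fib"})
        res = hb.dbs_scores(hb.distance_matrix(m), meta)
        pw = res.pairwise
        assert not ((pw["sample_id"] == pw["control_id"])).any()
        assert {"phh1", "phh2"} <= set(res.median_dbs.index)

    def test_no_controls_is_an_error(self):
        m = make_normalized([[0.0, 1.0]])
        meta = make_metadata({"s0": "Fib", "s1": "Fib"})
        with pytest.raises(ValidationError, match="PHH"):
            hb.dbs_scores(hb.distance_matrix(m), meta)

    def test_all_identical_scores_one_with_warning(self):
        m = make_normalized([[1.0, 1.0], [2.0, 2.0]], samples=["phh", "q"])
        meta = make_metadata({"phh": "PHH/Liver", "q": "Fib"})
        with pytest.warns(UserWarning, match="identical"):
            res = hb.dbs_scores(hb.distance_matrix(m), meta)
        assert (res.pairwise["dbs"] == 1.0).all()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPca:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=10)
        m = make_normalized(
            np.column_stack([col, col, rng.normal(size=10), rng.normal(size=10)])
        )
        res = hb.pca_top_variance(m, n_top=10)
        assert np.allclose(
            res.coordinates.iloc[0].to_numpy(), res.coordinates.iloc[1].to_numpy()
        )

    def test_collinear_samples_are_rank_one(self):
        direction = np.arange(1.0, 11.0)
        m = make_normalized(np.column_stack([t * direction for t in (0, 1, 2, 5)]))
        res = hb.pca_top_variance(m, n_top=10)
        assert abs(res.variance_fraction[0] - 1.0) < 1e-10

    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(50, 6))
        m = make_normalized(vals)
        res = hb.pca_top_variance(m, n_top=50)
        centered = (vals - vals.mean(axis=1, keepdims=True)).T  # samples x genes
        cov = centered @ centered.T
        w, v = np.linalg.eigh(cov)
        idx = np.argsort(w)[::-1]
        w, v = w[idx], v[:, idx]
        for k in range(5):
            got = res.coordinates.iloc[:, k].to_numpy()
            expected = v[:, k] * np.sqrt(w[k])
            assert np.allclose(np.abs(got), np.abs(expected), atol=1e-8)

    def test_variance_fractions_valid(self, normalized_sim):
        normalized, _, _, _ = normalized_sim
        res = hb.pca_top_variance(normalized)
        vf = res.variance_fraction
        assert ((vf >= 0) & (vf <= 1)).all()
        assert (np.diff(vf) <= 1e-12).all()
        assert vf.sum() <= 1 + 1e-9

    def test_full_rank_reproduces_distances(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(30, 8))
        m = make_normalized(vals)
        res = hb.pca_top_variance(m, n_top=30)
        centered = vals - vals.mean(axis=1, keepdims=True)
        coords = res.coordinates.to_numpy()
        for i in range(8):
            for j in range(8):
                d_orig = np.sqrt(((centered[:, i] - centered[:, j]) ** 2).sum())
                d_pca = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
                assert abs(d_orig - d_pca) < 1e-8

    def test_constant_matrix_rejected(self):
        m = make_normalized(np.full((5, 3), 2.0))
        with pytest.raises(ValidationError, match="variance"):
            hb.pca_top_variance(m, n_top=5)

    def test_samples_group_by_source_not_study(self, normalized_sim):
        normalized, _, metadata, _ = normalized_sim
        res = hb.pca_top_variance(normalized)
        xy = res.coordinates[["PC1", "PC2"]].to_numpy()
        src = metadata.table.loc[res.coordinates.index, "cell_source"].to_numpy()
        d = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d, np.inf)
        same = (src[d.argmin(axis=1)] == src).mean()
        assert same >= 0.9


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


class TestClustering:
    def test_separated_pairs_merge_first(self):
        m = make_normalized(
            [[0.0, 0.1, 10.0, 10.1]], genes=["g0"],
            samples=["a1", "a2", "b1", "b2"],
        )
        nwk = hb.hierarchical_cluster(m)
        assert nwk.count("(") == 3
        import re

        # each tight pair forms an innermost clade
        clades = re.findall(r"\(([^()]*)\)", nwk)
        leaves = [sorted(re.findall(r"[ab]\d", c)) for c in clades]
        assert ["a1", "a2"] in leaves and ["b1", "b2"] in leaves

    def test_complete_linkage_hand_trace(self):
        # 1-D points 0, 1, 10, 14: complete linkage merges (a,b)@1, (c,d)@4,
        # then everything at max distance 14
        m = make_normalized(
            [[0.0, 1.0, 10.0, 14.0]], genes=["g0"], samples=["a", "b", "c", "d"]
        )
        nwk = hb.hierarchical_cluster(m)
        import re

        clades = re.findall(r"\(([^()]*)\)", nwk)
        leaves = [sorted(re.findall(r"[abcd]", c)) for c in clades]
        assert ["a", "b"] in leaves and ["c", "d"] in leaves
        # merge heights 1 and 4, root at 14 -> internal branch lengths 13, 10
        assert ":13" in nwk and ":10" in nwk

    def test_topology_invariant_to_sample_order(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(20, 6))
        m1 = make_normalized(vals, samples=list("abcdef"))
        perm = [3, 0, 5, 1, 4, 2]
        m2 = make_normalized(vals[:, perm], samples=[list("abcdef")[i] for i in perm])
        assert hb.hierarchical_cluster(m1) == hb.hierarchical_cluster(m2)


# ---------------------------------------------------------------------------
# row centering & percent of control
# ---------------------------------------------------------------------------


class TestCenteringAndPercent:
    def test_constant_row_becomes_zero(self):
        m = make_normalized([[3.0, 3.0, 3.0]])
        assert (hb.center_rows_log2fc(m).to_numpy() == 0).all()

    def test_two_sample_row(self):
        m = make_normalized([[1.0, 3.0]])
        assert np.allclose(hb.center_rows_log2fc(m).to_numpy(), [[-1.0, 1.0]])

    def test_row_means_vanish(self):
        rng = np.random.default_rng(6)
        m = make_normalized(rng.normal(size=(40, 7)))
        centered = hb.center_rows_log2fc(m)
        assert np.abs(centered.mean(axis=1)).max() < 1e-12
        assert centered.attrs["label"] == "Log2FC RNA Expression"

    def test_percent_of_control(self):
        assert hb.percent_of_control(8.0, 8.0) == 100.0
        assert hb.percent_of_control(0.0, 8.0) == 0.0
        assert np.allclose(hb.percent_of_control([2.0, 4.0], 8.0), [25.0, 50.0])
        with pytest.raises(ValidationError):
            hb.percent_of_control([1.0], 0.0)
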