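import itertools

import numpy as np
import pandas as pd
import pytest

from ivscape import spatial


def brute_morans_i(y, W):
    n = len(y)
    z = y - y.mean()
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / W.sum()) * num / np.sum(z**2)


def brute_semivariance(v, pairs):
    return np.mean([(v[a] - v[b]) ** 2 for a, b in pairs])


class TestBuildNeighborPairs:
    def make(self, coords, species, plots=None):
        return pd.DataFrame(
            {
                "x": [c[0] for c in coords],
                "y": [c[1] for c in coords],
                "species": species,
                "plot": plots if plots is not None else 0,
            }
        )

    def test_single_conspecific_pair(self):
        t = self.make([(0, 0), (50, 0)], ["a", "a"])
        pairs = spatial.build_neighbor_pairs(t, 100.0, focal_species="a")
        assert len(pairs) == 1
        assert pairs.loc[0, "pair_class"] == "conspecific"

    def test_distance_cutoff(self):
        t = self.make([(0, 0), (150, 0)], ["a", "a"])
        assert len(spatial.build_neighbor_pairs(t, 100.0)) == 0

    def test_same_plot_constraint(self):
        t = self.make([(0, 0), (10, 0)], ["a", "a"], plots=[0, 1])
        assert len(spatial.build_neighbor_pairs(t, 100.0)) == 0

    def test_four_trees_two_species(self):
        t = self.make([(0, 0), (1, 0), (0, 1), (1, 1)], ["a", "a", "b", "b"])
        allp = spatial.build_neighbor_pairs(t, 10.0)
        assert len(allp) == 6
        focal = spatial.build_neighbor_pairs(t, 10.0, focal_species="a")
        counts = focal["pair_class"].value_counts()
        assert counts["conspecific"] == 1 and counts["heterospecific"] == 4


class TestMoransI:
    def test_hand_computed_two_clusters(self):
        """Two tight clusters of equal values 9 cells apart give I = 1."""
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0  # x = 0 and 1
        W[2, 3] = W[3, 2] = 1.0  # x = 10 and 11
        res = spatial.morans_i(np.array([0.0, 0.0, 1.0, 1.0]), W)
        assert res.I == pytest.approx(1.0)
        assert res.expected == pytest.approx(-1 / 3)

    def test_null_expectation(self):
        rng = np.random.default_rng(0)
        n = 25
        W = rng.random((n, n)) < 0.3
        W = np.triu(W, 1).astype(float)
        W = W + W.T
        res = spatial.morans_i(rng.standard_normal(n), W)
        assert res.expected == pytest.approx(-1 / (n - 1))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            W = rng.random((n, n)) * (rng.random((n, n)) < 0.4)
            np.fill_diagonal(W, 0.0)
            if W.sum() == 0:
                continue
            y = rng.standard_normal(n)
            res = spatial.morans_i(y, W)
            assert res.I == pytest.approx(brute_morans_i(y, W), abs=1e-12)

    def test_type_one_error_calibrated(self):
        """One-tailed rejection rate under i.i.d. values stays near alpha."""
        rng = np.random.default_rng(2)
        n, reps, rej = 40, 500, 0
        pts = rng.uniform(0, 250, (n, 2))
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        W = ((d <= 100) & (d > 0)).astype(float)
        for _ in range(reps):
            rej += spatial.morans_i(rng.standard_normal(n), W).p_value < 0.05
        assert 0.02 <= rej / reps <= 0.09

    def test_errors(self):
        W = np.zeros((3, 3))
        with pytest.raises(ValueError):
            spatial.morans_i(np.array([1.0, 2.0, 3.0]), W)
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError):
            spatial.morans_i(np.full(3, 2.0), W)
        with pytest.raises(ValueError):
            spatial.morans_i(np.array([1.0, 2.0]), W)


class TestPairwiseSemivariance:
    def test_enumerated_example(self):
        pairs = pd.DataFrame({"a": [0, 0, 1], "b": [1, 2, 2]})
        assert spatial.pairwise_semivariance(np.array([0.0, 1.0, 2.0]), pairs) == pytest.approx(2.0)

    def test_identical_values(self):
        pairs = pd.DataFrame({"a": [0], "b": [1]})
        assert spatial.pairwise_semivariance(np.array([3.0, 3.0]), pairs) == 0.0

    def test_translation_invariance_and_classic_factor(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(12)
        pairs = pd.DataFrame(list(itertools.combinations(range(12), 2)), columns=["a", "b"])
        base = spatial.pairwise_semivariance(v, pairs)
        assert spatial.pairwise_semivariance(v + 5.0, pairs) == pytest.approx(base)
        assert spatial.pairwise_semivariance(v, pairs, classic=True) == pytest.approx(base / 2)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            spatial.pairwise_semivariance(np.array([1.0]), pd.DataFrame(columns=["a", "b"]))


class TestSemivariogram:
    def test_single_bin_matches_pairwise(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(15)
        pts = rng.uniform(0, 10, (15, 2))
        curve = spatial.empirical_semivariogram(v, pts, np.array([0.0, 100.0]))
        pairs = pd.DataFrame(list(itertools.combinations(range(15), 2)), columns=["a", "b"])
        assert curve.loc[0, "semivariance"] == pytest.approx(
            spatial.pairwise_semivariance(v, pairs)
        )

    def test_iid_curve_flat_at_twice_variance(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(400)
        pts = rng.uniform(0, 100, (400, 2))
        curve = spatial.empirical_semivariogram(v, pts, np.linspace(0, 60, 7))
        expect = 2 * v.var()
        assert np.nanmax(np.abs(curve["semivariance"] - expect)) < 0.35 * expect

    def test_empty_bin_reported(self):
        v = np.array([1.0, 2.0])
        pts = np.array([[0.0, 0.0], [50.0, 0.0]])
        curve = spatial.empirical_semivariogram(v, pts, np.array([0.0, 10.0, 60.0]))
        assert curve.loc[0, "n_pairs"] == 0 and np.isnan(curve.loc[0, "semivariance"])
        assert curve.loc[1, "n_pairs"] == 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            spatial.empirical_semivariogram(np.array([1.0]), np.array([[0, 0]]), np.array([0, 1]))
        with pytest.raises(ValueError):
            spatial.empirical_semivariogram(
                np.array([1.0, 2.0]), np.zeros((2, 2)), np.array([1.0, 0.5])
            )


class TestScreen:
    def make_table(self, n, rng, n_species=3, side=200.0):
        return pd.DataFrame(
            {
                "tree_id": np.arange(n),
                "species": [f"s{i % n_species}" for i in range(n)],
                "plot": 0,
                "x": rng.uniform(0, side, n),
                "y": rng.uniform(0, side, n),
                "mean_growth": rng.standard_normal(n),
            }
        )

    def test_rare_species_ineligible(self):
        rng = np.random.default_rng(6)
        t = self.make_table(60, rng)
        t.loc[t.index[:57], "species"] = "common"
        t.loc[t.index[57:], "species"] = "rare"  # 3 individuals
        res, summary = spatial.species_autocorrelation_screen(t, radius=100.0)
        assert not res.set_index("species").loc["rare", "eligible"]
        assert summary["n_species_total"] == 2

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        t = self.make_table(400, rng)
        r1, s1 = spatial.species_autocorrelation_screen(t, max_sample=100, seed=3)
        r2, s2 = spatial.species_autocorrelation_screen(t, max_sample=100, seed=3)
        pd.testing.assert_frame_equal(r1, r2)
        assert s1 == s2


class TestCompareIntraInter:
    def test_constructed_clusters_classified_intra_below_inter(self):
        """Conspecifics tightly clustered in value, heterospecifics
        divergent: the focal species is classified intra<inter."""
        rng = np.random.default_rng(8)
        n_f, n_o = 25, 50
        t = pd.DataFrame(
            {
                "tree_id": np.arange(n_f + n_o),
                "species": ["focal"] * n_f + ["other"] * n_o,
                "plot": 0,
                "x": rng.uniform(0, 80, n_f + n_o),
                "y": rng.uniform(0, 80, n_f + n_o),
                "mean_growth": np.r_[rng.normal(0, 0.05, n_f), rng.normal(0, 3.0, n_o)],
            }
        )
        res, _ = spatial.compare_intra_inter(t, radius=100.0, seed=1)
        row = res.set_index("species").loc["focal"]
        assert row["classification"] == "intra<inter"
        assert row["intra_semivariance"] < row["inter_semivariance"]

    def test_exchangeable_pool_mostly_ns(self):
        """With all values from one exchangeable pool the permutation test
        rejects at ~alpha."""
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 40
        for r in range(reps):
            n = 60
            t = pd.DataFrame(
                {
                    "tree_id": np.arange(n),
                    "species": ["f"] * 20 + ["o"] * 40,
                    "plot": 0,
                    "x": rng.uniform(0, 100, n),
                    "y": rng.uniform(0, 100, n),
                    "mean_growth": np.exp(rng.standard_normal(n)),
                }
            )
            res, _ = spatial.compare_intra_inter(t, radius=100.0, n_perm=99, seed=r)
            rejections += res.set_index("species").loc["f", "classification"] != "ns"
        assert rejections <= 6  # binomial(40, 0.05) upper tail

    def test_ineligible_species_not_tested(self):
        t = pd.DataFrame(
            {
                "tree_id": range(8),
                "species": ["a"] * 4 + ["b"] * 4,
                "plot": 0,
                "x": np.linspace(0, 10, 8),
                "y": 0.0,
                "mean_growth": np.arange(8.0),
            }
        )
        res, _ = spatial.compare_intra_inter(t)
        assert (res["classification"] == "not_tested").all()

    def test_abundance_control_subsamples(self):
        rng = np.random.default_rng(10)
        n = 120
        t = pd.DataFrame(
            {
                "tree_id": np.arange(n),
                "species": ["a"] * 60 + ["b"] * 60,
                "plot": 0,
                "x": rng.uniform(0, 50, n),
                "y": rng.uniform(0, 50, n),
                "mean_growth": rng.standard_normal(n),
            }
        )
        res, _ = spatial.compare_intra_inter(t, max_per_species=10, seed=2)
        assert (res["n_individuals"] <= 10).all()

    def test_naive_mannwhitney_available(self):
        rng = np.random.default_rng(11)
        n = 40
        t = pd.DataFrame(
            {
                "tree_id": np.arange(n),
                "species": ["a"] * 20 + ["b"] * 20,
                "plot": 0,
                "x": rng.uniform(0, 50, n),
                "y": rng.uniform(0, 50, n),
                "mean_growth": rng.standard_normal(n),
            }
        )
        res, _ = spatial.compare_intra_inter(t, method="mannwhitney", seed=2)
        assert res["p_value"].notna().all()
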