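import numpy as np
import pandas as pd
import pytest

from ivscape import hier


class TestPartitionVariance:
    def test_clonal_trial_partition(self):
        """Partition of the published clonal-trial variance components."""
        part = hier.partition_variance(
            {"individual": 0.23, "block": 0.06, "genetic": 0.13, "temporal": 1.3, "residual": 0.51}
        )
        assert part.percent == {
            "individual": 10.31, "block": 2.69, "genetic": 5.83,
            "temporal": 58.30, "residual": 22.87,
        }

    @pytest.mark.parametrize(
        "comps, expected",
        [
            ((0.52, 0.55, 0.75), (28.57, 30.22, 41.21)),   # Paracou
            ((0.37, 0.66, 0.59), (22.84, 40.74, 36.42)),   # Uppangala
            ((0.67, 0.41, 0.81), (35.45, 21.69, 42.86)),   # BCI
        ],
    )
    def test_forest_partitions(self, comps, expected):
        part = hier.partition_variance(dict(zip(("species", "individual", "residual"), comps)))
        assert tuple(part.percent.values()) == expected

    def test_single_component(self):
        assert hier.partition_variance({"A": 1.0}).percent == {"A": 100.00}

    def test_sums_to_hundred_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        comps = {f"c{i}": float(v) for i, v in enumerate(rng.uniform(0.01, 5, 6))}
        part = hier.partition_variance(comps)
        assert sum(part.percent.values()) == pytest.approx(100.0, abs=0.02)
        shuffled = dict(reversed(list(comps.items())))
        part2 = hier.partition_variance(shuffled)
        for k in comps:
            assert part.percent[k] == part2.percent[k]

    @pytest.mark.parametrize("comps", [{}, {"a": 0.0, "b": 0.0}, {"a": -1.0}])
    def test_invalid_components(self, comps):
        with pytest.raises(ValueError):
            hier.partition_variance(comps)


class TestGibbsSampler:
    def test_random_intercept_recovery(self, mcmc_test_config):
        rng = np.random.default_rng(3)
        groups = np.repeat(np.arange(80), 6)
        u = rng.normal(0, np.sqrt(0.5), 80)
        x = rng.standard_normal(480)
        y = 0.8 + 0.4 * x + u[groups] + rng.normal(0, 0.5, 480)
        fit = hier.gibbs_lmm(
            y, np.column_stack([np.ones(480), x]), {"individual": groups},
            mcmc_test_config, fixed_names=["intercept", "slope"],
        )
        summ = fit.summary()
        for name, truth in [("beta_intercept", 0.8), ("beta_slope", 0.4),
                            ("sigma2_individual", 0.5), ("sigma2_resid", 0.25)]:
            assert abs(summ.loc[name, "mean"] - truth) < 3 * summ.loc[name, "sd"] + 0.05

    def test_credible_interval_coverage(self):
        """95% intervals for the slope cover the truth at >= 85% over
        replicated simulations from the model's own generative form."""
        rng = np.random.default_rng(9)
        cfg = hier.McmcConfig(n_chains=2, n_iter=800, n_warmup=400, thin=1, seed=0)
        hits = 0
        reps = 20
        for r in range(reps):
            groups = np.repeat(np.arange(40), 4)
            u = rng.normal(0, 0.6, 40)
            x = rng.standard_normal(160)
            y = 0.5 + 0.7 * x + u[groups] + rng.normal(0, 0.4, 160)
            cfg_r = hier.McmcConfig(n_chains=2, n_iter=800, n_warmup=400, thin=1, seed=r)
            fit = hier.gibbs_lmm(y, np.column_stack([np.ones(160), x]),
                                 {"individual": groups}, cfg_r)
            lo, hi = np.quantile(fit.stacked("beta")[:, 1], [0.025, 0.975])
            hits += lo <= 0.7 <= hi
        assert hits / reps >= 0.85


class TestImperfectModel:
    def test_nonpositive_inputs_rejected(self, mcmc_test_config):
        df = pd.DataFrame({"i": [0, 0], "j": [0, 0], "Y": [1.0, -1.0], "X1": [1.0, 1.0]})
        with pytest.raises(ValueError):
            hier.fit_imperfect_model(df, mcmc_test_config)

    def test_perfect_knowledge_limit(self, small_virtual_data, mcmc_test_config):
        """When every environmental dimension is observed, the individual
        effect and residual variances collapse toward zero."""
        _, _, _, data = small_virtual_data
        covs = tuple(f"X{n}" for n in range(1, 6))
        imperfect = hier.fit_imperfect_model(data, mcmc_test_config)
        perfect = hier.fit_imperfect_model(data, mcmc_test_config, covariates=covs)
        for j in perfect.species_fits:
            assert perfect.vbj()[j] < 0.05 * imperfect.vbj()[j]
            assert perfect.vj()[j] < 1e-6

    def test_imperfect_vbj_large(self, small_virtual_data, mcmc_test_config):
        _, _, _, data = small_virtual_data
        fit = hier.fit_imperfect_model(data, mcmc_test_config)
        for j, f in fit.species_fits.items():
            draws = f.stacked("sigma2_individual")
            assert np.quantile(draws, 0.05) > 0.01


class TestForestModel:
    def test_single_species_rejected(self, mcmc_test_config):
        g = pd.DataFrame(
            {"tree_id": [1, 1, 2, 2], "species": "only", "G": [1.0, 2.0, 1.5, 2.5],
             "dbh_start": [120.0] * 4}
        )
        with pytest.raises(ValueError):
            hier.fit_forest_growth_model(g, mcmc_test_config)

    def test_singleton_species_warns(self, mcmc_test_config):
        rng = np.random.default_rng(1)
        g = pd.DataFrame(
            {
                "tree_id": np.r_[np.repeat(np.arange(10), 2), [99, 99]],
                "species": ["a"] * 10 + ["b"] * 10 + ["c"] * 2,
                "G": rng.uniform(0.5, 5, 22),
                "dbh_start": rng.uniform(110, 300, 22),
            }
        )
        with pytest.warns(UserWarning, match="single individual"):
            hier.fit_forest_growth_model(g, mcmc_test_config)

    def test_equal_variances_recovered_in_ratio(self, mcmc_test_config):
        """Generated with equal species and individual variances, the
        posterior ratio is near 1."""
        rng = np.random.default_rng(8)
        n_sp, n_per, n_obs = 20, 12, 4
        sp = np.repeat(np.arange(n_sp), n_per * n_obs)
        tree = np.repeat(np.arange(n_sp * n_per), n_obs)
        bj = rng.normal(0, np.sqrt(0.4), n_sp)
        bi = rng.normal(0, np.sqrt(0.4), n_sp * n_per)
        dbh = rng.uniform(110, 400, n_sp * n_per)[tree]
        eta = 1.2 + bj[sp] + bi[tree] + 0.2 * (np.log(dbh) - 5.0) + rng.normal(0, 0.5, sp.size)
        g = pd.DataFrame(
            {"tree_id": tree, "species": sp, "G": np.exp(eta) - 2.0, "dbh_start": dbh}
        )
        fit = hier.fit_forest_growth_model(g, mcmc_test_config)
        vc = fit.variance_components()
        assert 0.5 < vc["individual"] / vc["species"] < 2.0


class TestConvergence:
    def test_stationary_chains_pass(self):
        rng = np.random.default_rng(2)
        draws = {
            "beta": rng.standard_normal((4, 500, 1)),
            "sigma2_resid": rng.gamma(2.0, 1.0, (4, 500)),
        }
        fit = hier.GibbsLMMFit(
            draws=draws, fixed_names=["intercept"], factor_names=[],
            level_labels={}, config=hier.McmcConfig.test_mode(),
        )
        assert hier.check_convergence(fit).passed

    def test_shifted_chains_fail(self):
        rng = np.random.default_rng(2)
        b = rng.standard_normal((2, 500, 1))
        b[1] += 10.0
        fit = hier.GibbsLMMFit(
            draws={"beta": b, "sigma2_resid": rng.gamma(2.0, 1.0, (2, 500))},
            fixed_names=["intercept"], factor_names=[],
            level_labels={}, config=hier.McmcConfig.test_mode(),
        )
        rep = hier.check_convergence(fit)
        assert not rep.passed
        assert rep.table.loc["beta_intercept", "rhat"] > 1.5

    def test_constant_chains_flagged(self):
        fit = hier.GibbsLMMFit(
            draws={"beta": np.ones((2, 200, 1)), "sigma2_resid": np.ones((2, 200))},
            fixed_names=["intercept"], factor_names=[],
            level_labels={}, config=hier.McmcConfig.test_mode(),
        )
        assert not hier.check_convergence(fit).passed

    def test_single_chain_rejected(self):
        fit = hier.GibbsLMMFit(
            draws={"beta": np.ones((1, 200, 1)), "sigma2_resid": np.ones((1, 200))},
            fixed_names=["intercept"], factor_names=[],
            level_labels={}, config=hier.McmcConfig.test_mode(),
        )
        with pytest.raises(ValueError):
            hier.check_convergence(fit)


class TestPredictiveEnvelope:
    def _degenerate_fit(self, vb, ve):
        draws = {
            "beta": np.tile(np.array([1.0, 0.5]), (2, 300, 1)),
            "sigma2_individual": np.full((2, 300), vb),
            "sigma2_resid": np.full((2, 300), ve),
        }
        f = hier.GibbsLMMFit(
            draws=draws, fixed_names=["intercept", "lnX1"],
            factor_names=["individual"], level_labels={},
            config=hier.McmcConfig.test_mode(),
        )
        return hier.ImperfectFit(species_fits={0: f})

    def test_band_collapses_without_variance(self):
        env = hier.predictive_envelope(self._degenerate_fit(0.0, 0.0), np.array([0.5, 1, 2]))
        band = env[0]
        np.testing.assert_allclose(band["lo"], band["mean"], atol=1e-12)
        np.testing.assert_allclose(band["hi"], band["mean"], atol=1e-12)

    def test_band_widens_with_individual_variance(self):
        narrow = hier.predictive_envelope(self._degenerate_fit(0.5, 0.0), np.array([1.0, 2.0]), seed=3)[0]
        wide = hier.predictive_envelope(self._degenerate_fit(1.0, 0.0), np.array([1.0, 2.0]), seed=3)[0]
        assert ((wide["hi"] - wide["lo"]) > (narrow["hi"] - narrow["lo"])).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            hier.predictive_envelope(self._degenerate_fit(0.1, 0.1), np.array([]))

    def test_envelope_covers_observations(self, small_virtual_data, mcmc_test_config):
        """~95% of simulated individuals fall inside the 95% band."""
        _, _, _, data = small_virtual_data
        fit = hier.fit_imperfect_model(data, mcmc_test_config)
        covered = total = 0
        for j, sub in data.groupby("j"):
            grid = np.sort(sub["X1"].unique())
            band = hier.predictive_envelope(fit, grid, seed=1)[j]
            lo = np.interp(sub["X1"], band["x1"], band["lo"])
            hi = np.interp(sub["X1"], band["x1"], band["hi"])
            lnY = np.log(sub["Y"])
            covered += ((lnY >= lo) & (lnY <= hi)).sum()
            total += len(sub)
        assert covered / total >= 0.88
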