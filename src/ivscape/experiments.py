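"""Reproduction drivers: canned experiments measuring the package's
headline behaviours on synthetic data.

Each driver generates its own data, runs the relevant analyses and returns
a flat dict of metrics; they are what ``scripts/acceptance.py`` and the
acceptance-level tests execute.  Problem sizes are desk-scale versions of
the study designs (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hier, io_utils, landscape, spatial, synth

__all__ = [
    "virtual_experiment_metrics",
    "clonal_recovery_metrics",
    "inventory_detection_metrics",
    "moran_null_calibration",
    "comparison_null_calibration",
    "reference_partitions",
]

#: Variance components printed for the clonal-trial growth model and the
#: three forest-inventory fits, used as worked-example inputs.
REFERENCE_COMPONENTS = {
    "clonal": {"individual": 0.23, "block": 0.06, "genetic": 0.13,
               "temporal": 1.3, "residual": 0.51},
    "paracou": {"species": 0.52, "individual": 0.55, "residual": 0.75},
    "uppangala": {"species": 0.37, "individual": 0.66, "residual": 0.59},
    "bci": {"species": 0.67, "individual": 0.41, "residual": 0.81},
}


def reference_partitions() -> dict[str, dict[str, float]]:
    """Variance partitions of the published component estimates."""
    return {
        name: hier.partition_variance(comps).percent
        for name, comps in REFERENCE_COMPONENTS.items()
    }


def virtual_experiment_metrics(
    seed: int,
    C: int = 100,
    I: int = 100,
    J: int = 2,
    N: int = 10,
    T: int = 2,
    autocorr_range: float = 10.0,
    coef_scale: float = 0.3,
    moran_radius: float = 20.0,
) -> dict:
    """One realisation of the virtual experiment at desk scale.

    Simulates the deterministic attribute over a high-dimensional
    landscape, fits the single-covariate individual-effects model and its
    fully observed benchmark, and measures: the posterior of the
    individual-effect variance V_bj, the ratio of the fully observed to
    the single-covariate V_bj, Moran's I of mean attribute per species,
    and pooled vs within-species semivariance at lags below the range.
    """
    env = landscape.generate_environment(C, N, T, autocorr_range, seed=seed)
    placements = landscape.place_individuals(I, J, C, seed=seed + 1)
    responses = landscape.draw_species_responses(J, N, coef_scale, seed=seed + 2)
    data = landscape.simulate_attribute(env, placements, responses)

    cfg = hier.McmcConfig.test_mode(seed=seed + 3)
    imperfect = hier.fit_imperfect_model(data, cfg)
    all_covs = tuple(f"X{n}" for n in range(1, N + 1))
    perfect = hier.fit_imperfect_model(data, cfg, covariates=all_covs)

    out: dict = {"seed": seed, "n_obs": len(data)}
    for j, f in imperfect.species_fits.items():
        draws = f.stacked("sigma2_individual")
        out[f"vbj_mean_{j}"] = float(draws.mean())
        out[f"vbj_q05_{j}"] = float(np.quantile(draws, 0.05))
        out[f"vbj_ratio_perfect_{j}"] = float(
            perfect.vbj()[j] / imperfect.vbj()[j]
        )

    mean_y = data.groupby(["i", "j", "x", "y"], as_index=False)["Y"].mean()
    edges = np.linspace(0.0, C / 2, 11)
    short = edges[1:] <= autocorr_range  # bins entirely below the range
    pooled = spatial.empirical_semivariogram(
        mean_y["Y"], mean_y[["x", "y"]], edges
    )
    tot = np.zeros(edges.size - 1)
    cnt = np.zeros(edges.size - 1)
    for j, sub in mean_y.groupby("j"):
        c = spatial.empirical_semivariogram(sub["Y"], sub[["x", "y"]], edges)
        tot += np.nan_to_num(c["semivariance"] * c["n_pairs"])
        cnt += c["n_pairs"].to_numpy()
        subr = sub.reset_index(drop=True).assign(plot=0)
        pairs = spatial.build_neighbor_pairs(subr, moran_radius)
        W = np.zeros((len(subr), len(subr)))
        W[pairs["a"], pairs["b"]] = 1.0
        W[pairs["b"], pairs["a"]] = 1.0
        res = spatial.morans_i(subr["Y"].to_numpy(), W)
        out[f"moran_I_{j}"] = res.I
        out[f"moran_p_{j}"] = res.p_value

    pw = pooled["n_pairs"].to_numpy()[short]
    out["pooled_semivar_short"] = float(
        np.nansum(pooled["semivariance"].to_numpy()[short] * pw) / pw.sum()
    )
    out["within_semivar_short"] = float(tot[short].sum() / cnt[short].sum())
    return out


def clonal_recovery_metrics(
    seed: int,
    n_blocks: int = 3,
    n_genotypes: int = 5,
    trees_per_plot: int = 25,
    n_censuses: int = 4,
) -> dict:
    """Fit the clonal growth model to a trial generated from its own form
    with the individual variance set to twice the genotype variance, and
    report recovery diagnostics per component (posterior mean, median, sd,
    truth, z-score) on the response scale."""
    from . import growth as gp

    cfg = synth.ClonalTrialConfig(
        n_blocks=n_blocks,
        n_genotypes=n_genotypes,
        trees_per_plot=trees_per_plot,
        n_censuses=n_censuses,
        sigma2_individual=0.26,
        sigma2_genotype=0.13,
        seed=seed,
    )
    census, truth = synth.generate_clonal_trial(cfg)
    growth = gp.annualized_growth(census)
    growth = gp.competition_index(
        growth, group_cols=("block", "date_start"), dbh_col="dbh_start"
    )
    mcfg = hier.McmcConfig(n_chains=2, n_iter=4000, n_warmup=2000, thin=2, seed=seed + 1)
    fit = hier.fit_clonal_growth_model(growth, mcfg)
    s2 = fit.response_scaler.sd**2
    out: dict = {"seed": seed, "n_obs": len(growth)}
    for k, tr in truth["components"].items():
        d = fit.stacked(f"sigma2_{k}") * s2
        out[f"{k}_truth"] = tr
        out[f"{k}_mean"] = float(d.mean())
        out[f"{k}_median"] = float(np.median(d))
        out[f"{k}_sd"] = float(d.std(ddof=1))
        out[f"{k}_z"] = float((d.mean() - tr) / d.std(ddof=1))
    out["vi_vg_median_ratio"] = out["individual_median"] / out["genotype_median"]
    return out


def inventory_detection_metrics(seed: int, iv_mode: str) -> dict:
    """Full pipeline on a synthetic inventory: generate, prepare mean
    growth, run the Moran screen and the intra-vs-inter comparison, and
    report the summary rates."""
    cfg = synth.ForestInventoryConfig(iv_mode=iv_mode, seed=seed)
    census, _ = synth.generate_forest_inventory(cfg)
    mean_growth, _ = io_utils.prepare_mean_growth(census)
    _, screen = spatial.species_autocorrelation_screen(mean_growth, seed=seed + 1)
    _, comp = spatial.compare_intra_inter(mean_growth, seed=seed + 2)
    return {
        "seed": seed,
        "iv_mode": iv_mode,
        "n_trees": len(mean_growth),
        "n_species_eligible_moran": screen["n_species_eligible"],
        "pct_species_moran_significant": screen["pct_species_significant"],
        "pct_individuals_moran_significant": screen["pct_individuals_significant"],
        "n_species_eligible_compare": comp["n_species_eligible"],
        "pct_species_intra_lt_inter": comp["pct_species_intra<inter"],
        "pct_species_intra_gt_inter": comp["pct_species_intra>inter"],
        "pct_species_ns": comp["pct_species_ns"],
    }


def moran_null_calibration(
    seed: int, n_reps: int = 1000, n: int = 60, side: float = 500.0,
    radius: float = 100.0, alpha: float = 0.05,
) -> dict:
    """Type-I error of the one-tailed Moran test on i.i.d. values at random
    positions (same weights as the screen)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        pts = rng.uniform(0, side, (n, 2))
        d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
        W = ((d <= radius) & (d > 0)).astype(float)
        res = spatial.morans_i(
            rng.standard_normal(n), W, seed=int(rng.integers(2**31 - 1))
        )
        rejections += res.p_value < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}


def comparison_null_calibration(
    seed: int, n_reps: int = 1000, n_focal: int = 20, n_other: int = 40,
    side: float = 100.0, alpha: float = 0.05, n_perm: int = 199,
) -> dict:
    """Rejection rate of the intra-vs-inter comparison when all values come
    from one exchangeable (lognormal) pool."""
    rng = np.random.default_rng(seed)
    n = n_focal + n_other
    rejections = 0
    for r in range(n_reps):
        t = pd.DataFrame(
            {
                "tree_id": np.arange(n),
                "species": ["focal"] * n_focal + ["other"] * n_other,
                "plot": 0,
                "x": rng.uniform(0, side, n),
                "y": rng.uniform(0, side, n),
                "mean_growth": np.exp(rng.standard_normal(n)),
            }
        )
        res, _ = spatial.compare_intra_inter(
            t, alpha=alpha, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        row = res.set_index("species").loc["focal"]
        rejections += row["classification"] not in ("ns", "not_tested")
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}
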