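"""Synthetic census datasets with known generative truth.

Two generators mirror the data structures the analyses consume:

- :func:`generate_clonal_trial` — a fully crossed clonal trial (blocks x
  genotypes, square planting plots at fixed spacing, repeated censuses)
  whose log-growth follows exactly the clonal mixed model, with all random
  effects and the residuals drawn once and stored in a truth record;
- :func:`generate_forest_inventory` — a multi-species inventory in which
  species respond, through species-specific coefficient vectors, to latent
  spatially autocorrelated environmental fields (``iv_mode=
  "environmental"``), or receive i.i.d. individual effects of *matched
  marginal variance* (``iv_mode="unstructured"``), so that detection
  differences between the two modes are attributable to spatial structure
  and not to effect magnitude.

Both return a standard census table (``tree_id, species, plot, x, y, date,
dbh_mm`` plus design columns) and a truth dict sufficient to recompute
every generated response exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .growth import competition_index
from .landscape import _exponential_grf

__all__ = [
    "ClonalTrialConfig",
    "ForestInventoryConfig",
    "generate_clonal_trial",
    "generate_forest_inventory",
]


@dataclass
class ClonalTrialConfig:
    """Design and generative parameters of the clonal trial.

    Defaults reproduce the reference trial's shape — 10 blocks x 14
    genotypes, plots of 100 trees (10 x 10) at 1,666 trees/ha (6 m^2 per
    tree, ~2.45 m spacing), 5 censuses over 6 years — and variance
    components of realistic relative magnitude (temporal >> individual >
    genotype > block).  Variances apply on the ln(G + 1) scale.
    """

    n_blocks: int = 10
    n_genotypes: int = 14
    trees_per_plot: int = 100
    n_censuses: int = 5
    duration_years: float = 6.0
    spacing_m: float = 2.449

    beta0: float = 1.0
    beta_diam: float = 0.55
    beta_comp: float = -0.27
    # reference constants standardizing the covariates inside the generator
    # (the fit re-standardizes empirically; variance components are unaffected)
    lnD_center: float = 4.5
    lnD_scale: float = 0.5
    lnC_center: float = 10.0
    lnC_scale: float = 1.0

    sigma2_block: float = 0.06
    sigma2_genotype: float = 0.13
    sigma2_date: float = 1.3
    sigma2_individual: float = 0.23
    sigma2_resid: float = 0.51

    init_dbh_mean: float = 50.0
    init_dbh_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_block", "sigma2_genotype", "sigma2_date",
                     "sigma2_individual", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        side = int(round(np.sqrt(self.trees_per_plot)))
        if side * side != self.trees_per_plot:
            raise ValueError("trees_per_plot must be a perfect square")


def generate_clonal_trial(config: ClonalTrialConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the clonal trial.

    DBH trajectories are built so that annualized growth between
    consecutive censuses satisfies exactly

        ln(G + 1) = beta0 + b_block + b_genotype + b_date + b_tree
                    + beta_diam * z(ln D) + beta_comp * z(ln(C + 1)) + eps

    with z() using the fixed reference constants of the config, D the
    start-of-interval DBH and C the Moore-neighbourhood competition index
    at interval start.  The truth record stores every drawn effect, every
    residual, and the growth of every interval.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    side = int(round(np.sqrt(cfg.trees_per_plot)))
    n_intervals = cfg.n_censuses - 1
    dt = cfg.duration_years / max(n_intervals, 1)

    b_block = rng.normal(0, np.sqrt(cfg.sigma2_block), cfg.n_blocks)
    b_geno = rng.normal(0, np.sqrt(cfg.sigma2_genotype), cfg.n_genotypes)
    b_date = rng.normal(0, np.sqrt(cfg.sigma2_date), n_intervals)

    # layout: genotype plots tiled on a grid inside each block; blocks offset
    plots_per_row = int(np.ceil(np.sqrt(cfg.n_genotypes)))
    rows, cols, blocks, genos = [], [], [], []
    for blk in range(cfg.n_blocks):
        for g in range(cfg.n_genotypes):
            pr, pc = divmod(g, plots_per_row)
            for k in range(cfg.trees_per_plot):
                tr, tc = divmod(k, side)
                rows.append(pr * side + tr)
                cols.append(pc * side + tc)
                blocks.append(blk)
                genos.append(g)
    trees = pd.DataFrame(
        {
            "tree_id": np.arange(len(rows)),
            "block": blocks,
            "genotype": genos,
            "row": rows,
            "col": cols,
        }
    )
    n_trees = len(trees)
    b_tree = rng.normal(0, np.sqrt(cfg.sigma2_individual), n_trees)
    # block offset keeps blocks spatially disjoint
    block_extent = plots_per_row * side * cfg.spacing_m + 50.0
    trees["x"] = trees["col"] * cfg.spacing_m + trees["block"] * block_extent
    trees["y"] = trees["row"] * cfg.spacing_m
    # per-block global grid: rows/cols are already unique within a block

    dbh = np.maximum(
        rng.normal(cfg.init_dbh_mean, cfg.init_dbh_sd, n_trees), 1.0
    )
    blk_idx = trees["block"].to_numpy()
    gen_idx = trees["genotype"].to_numpy()

    records = []
    eps_store = np.empty((n_intervals, n_trees))
    growth_store = np.empty((n_intervals, n_trees))
    comp_store = np.empty((n_intervals, n_trees))
    dbh_store = np.empty((cfg.n_censuses, n_trees))
    for c in range(cfg.n_censuses):
        dbh_store[c] = dbh
        date = 1.0 + c * dt  # plantation age in years at census
        records.append(
            pd.DataFrame(
                {
                    "tree_id": trees["tree_id"],
                    "species": "eucalyptus",
                    "genotype": gen_idx,
                    "block": blk_idx,
                    "plot": blk_idx,
                    "row": trees["row"],
                    "col": trees["col"],
                    "x": trees["x"],
                    "y": trees["y"],
                    "date": date,
                    "dbh_mm": dbh.copy(),
                }
            )
        )
        if c == cfg.n_censuses - 1:
            break
        snap = trees.assign(dbh_mm=dbh)
        comp = competition_index(snap, group_cols=("block",))["comp_index"].to_numpy()
        eps = rng.normal(0, np.sqrt(cfg.sigma2_resid), n_trees)
        eta = (
            cfg.beta0
            + b_block[blk_idx]
            + b_geno[gen_idx]
            + b_date[c]
            + b_tree
            + cfg.beta_diam * (np.log(dbh) - cfg.lnD_center) / cfg.lnD_scale
            + cfg.beta_comp * (np.log(comp + 1.0) - cfg.lnC_center) / cfg.lnC_scale
            + eps
        )
        G = np.exp(eta) - 1.0  # mm/year; ln(G+1) = eta exactly
        eps_store[c], growth_store[c], comp_store[c] = eps, G, comp
        dbh = dbh + G * dt

    census = pd.concat(records, ignore_index=True)
    truth = {
        "config": asdict(cfg),
        "effects": {
            "block": b_block,
            "genotype": b_geno,
            "date": b_date,
            "individual": b_tree,
        },
        "components": {
            "block": cfg.sigma2_block,
            "genotype": cfg.sigma2_genotype,
            "date": cfg.sigma2_date,
            "individual": cfg.sigma2_individual,
            "resid": cfg.sigma2_resid,
        },
        "eps": eps_store,
        "growth": growth_store,
        "comp_index": comp_store,
        "dbh": dbh_store,
    }
    return census, truth


@dataclass
class ForestInventoryConfig:
    """Generative parameters of the multi-species forest inventory.

    Species abundances follow a log-series rank-abundance curve
    (``logseries_x``; ``abundance="uniform"`` for equal expected counts).
    Expected ln(G + 2) for a tree is

        beta0 + b_species + e_i + beta_diam * z(ln D) + eps_it

    where e_i is the environmental response
    sum_n beta_jn * X_n(x_i, y_i) of the tree's species at its location
    (``iv_mode="environmental"``) or an i.i.d. draw with the identical
    species-specific variance sum_n beta_jn^2 (``iv_mode="unstructured"``).
    By default species differ only through their response coefficients, not
    through baseline offsets (``species_effect_sd = 0``), so the
    unstructured mode is a true exchangeable null for local intra- vs
    inter-specific comparisons.
    """

    n_species: int = 15
    n_trees: int = 2700
    n_plots: int = 6
    plot_size_m: float = 100.0
    n_censuses: int = 6
    periodicity_years: float = 2.0

    n_fields: int = 10
    # autocorrelation ranges of the latent fields; None = log-spaced between
    # env_range_min_m and env_range_max_m, emulating environmental variation
    # from fine-scale (soil) to broad (topographic) structure
    env_ranges_m: tuple[float, ...] | None = None
    env_range_min_m: float = 30.0
    env_range_max_m: float = 150.0
    field_cell_m: float = 5.0
    response_sd: float = 0.265  # per-field scale; total env response var = n_fields * sd^2
    species_effect_sd: float = 0.0
    iv_mode: str = "environmental"

    beta0: float = 1.8
    beta_diam: float = 0.2
    lnD_center: float = 5.0
    lnD_scale: float = 0.5
    sigma2_resid: float = 0.2

    min_dbh_mm: float = 100.0
    init_dbh_scale: float = 80.0  # exponential tail above the observation floor
    abundance: str = "logseries"
    logseries_x: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iv_mode not in ("environmental", "unstructured"):
            raise ValueError("iv_mode must be 'environmental' or 'unstructured'")
        if self.abundance not in ("logseries", "uniform"):
            raise ValueError("abundance must be 'logseries' or 'uniform'")


def generate_forest_inventory(config: ForestInventoryConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the forest inventory; see :class:`ForestInventoryConfig`.

    Latent fields are unit-variance exponential-covariance Gaussian fields
    sampled on a ``field_cell_m`` grid per plot and looked up at the
    nearest cell.  DBH accumulates growth between censuses; records below
    the observation floor are censored from the output table (as a real
    inventory would not measure them).  Two conspecific trees in the same
    cell receive identical environmental responses.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    if cfg.abundance == "logseries":
        ranks = np.arange(1, cfg.n_species + 1)
        w = cfg.logseries_x**ranks / ranks
    else:
        w = np.ones(cfg.n_species)
    w = w / w.sum()
    species = rng.choice(cfg.n_species, size=cfg.n_trees, p=w)
    plot = rng.integers(0, cfg.n_plots, size=cfg.n_trees)
    x_local = rng.uniform(0, cfg.plot_size_m, size=cfg.n_trees)
    y_local = rng.uniform(0, cfg.plot_size_m, size=cfg.n_trees)
    # global coordinates: plots tiled along x with a gap
    x = x_local + plot * (cfg.plot_size_m + 100.0)
    y = y_local

    # species response vectors: random directions with a common norm, so every
    # species has the same total environmental response variance
    # n_fields * response_sd^2 and the two iv modes differ only in structure
    dirs = rng.normal(size=(cfg.n_species, cfg.n_fields))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    beta_env = dirs * cfg.response_sd * np.sqrt(cfg.n_fields)
    b_species = (
        rng.normal(0, cfg.species_effect_sd, cfg.n_species)
        if cfg.species_effect_sd > 0
        else np.zeros(cfg.n_species)
    )

    ncell = int(np.ceil(cfg.plot_size_m / cfg.field_cell_m))
    if cfg.env_ranges_m is not None:
        ranges = np.asarray(cfg.env_ranges_m, float)
        if ranges.size != cfg.n_fields:
            raise ValueError("env_ranges_m must have one range per field")
    else:
        ranges = np.geomspace(cfg.env_range_min_m, cfg.env_range_max_m, cfg.n_fields)
    cell_r = np.minimum((y_local // cfg.field_cell_m).astype(int), ncell - 1)
    cell_c = np.minimum((x_local // cfg.field_cell_m).astype(int), ncell - 1)
    env_value = np.zeros((cfg.n_trees, cfg.n_fields))
    for p in range(cfg.n_plots):
        inplot = plot == p
        for f in range(cfg.n_fields):
            fld = _exponential_grf(ncell, ranges[f] / cfg.field_cell_m, rng)
            env_value[inplot, f] = fld[cell_r[inplot], cell_c[inplot]]

    env_response = np.einsum("tf,tf->t", env_value, beta_env[species])
    if cfg.iv_mode == "unstructured":
        sd_i = np.sqrt(np.sum(beta_env**2, axis=1))[species]
        indiv_effect = rng.normal(0, 1, cfg.n_trees) * sd_i
    else:
        indiv_effect = env_response

    dbh = cfg.min_dbh_mm + rng.exponential(cfg.init_dbh_scale, cfg.n_trees)
    n_intervals = cfg.n_censuses - 1
    eps_store = np.empty((n_intervals, cfg.n_trees))
    growth_store = np.empty((n_intervals, cfg.n_trees))
    dbh_store = np.empty((cfg.n_censuses, cfg.n_trees))
    records = []
    for c in range(cfg.n_censuses):
        dbh_store[c] = dbh
        date = 2000.0 + c * cfg.periodicity_years
        visible = dbh >= cfg.min_dbh_mm
        records.append(
            pd.DataFrame(
                {
                    "tree_id": np.arange(cfg.n_trees)[visible],
                    "species": [f"sp{int(s):03d}" for s in species[visible]],
                    "plot": plot[visible],
                    "x": x[visible],
                    "y": y[visible],
                    "date": date,
                    "dbh_mm": dbh[visible],
                }
            )
        )
        if c == cfg.n_censuses - 1:
            break
        eps = rng.normal(0, np.sqrt(cfg.sigma2_resid), cfg.n_trees)
        eta = (
            cfg.beta0
            + b_species[species]
            + indiv_effect
            + cfg.beta_diam * (np.log(dbh) - cfg.lnD_center) / cfg.lnD_scale
            + eps
        )
        G = np.exp(eta) - 2.0  # mm/year; ln(G+2) = eta exactly
        eps_store[c], growth_store[c] = eps, G
        dbh = dbh + G * cfg.periodicity_years

    census = pd.concat(records, ignore_index=True)
    truth = {
        "config": asdict(cfg),
        "species_of_tree": species,
        "beta_env": beta_env,
        "b_species": b_species,
        "env_value": env_value,
        "env_response": env_response,
        "indiv_effect": indiv_effect,
        "eps": eps_store,
        "growth": growth_store,
        "dbh": dbh_store,
    }
    return census, truth
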