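"""Hierarchical Gaussian mixed models with conjugate Gibbs sampling.

All three growth models in this package share one form: a Gaussian response
with fixed effects and one or more crossed random intercepts,

    y = X beta + sum_k Z_k u_k + eps,   u_k ~ N(0, sigma_k^2 I),
    eps ~ N(0, sigma^2 I),

with Normal(0, prior_mean_sd^2) priors on the fixed effects and
half-Student-t(df, 0, scale) priors on every standard-deviation parameter
(random-effect and residual).  The half-t prior is handled exactly through
its inverse-gamma scale-mixture representation (Huang & Wand 2013):

    sigma_k^2 | a_k ~ InvGamma(df/2, df/a_k),  a_k ~ InvGamma(1/2, 1/scale^2)

which makes every full conditional conjugate, so the sampler is a plain
blocked Gibbs scheme — no tuning, no divergences, exact stationary
distribution.

The module exposes the three concrete fits used by the analyses:

- :func:`fit_imperfect_model` — attribute vs. a single observed covariate
  with a per-species individual random intercept (the "imperfect knowledge"
  view of a deterministic high-dimensional response);
- :func:`fit_clonal_growth_model` — clonal-trial growth with block,
  genotype, census-date and individual intercepts;
- :func:`fit_forest_growth_model` — forest-inventory growth with species and
  individual intercepts;

plus :func:`partition_variance`, :func:`check_convergence` and
:func:`predictive_envelope`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .growth import log_shift_scale, Scaler

__all__ = [
    "McmcConfig",
    "GibbsLMMFit",
    "ImperfectFit",
    "VariancePartition",
    "ConvergenceReport",
    "gibbs_lmm",
    "fit_imperfect_model",
    "fit_clonal_growth_model",
    "fit_forest_growth_model",
    "partition_variance",
    "check_convergence",
    "predictive_envelope",
]


@dataclass
class McmcConfig:
    """MCMC settings and priors.

    Defaults follow the reference analysis: 4 chains of 10,000 iterations
    with 5,000 warm-up and thinning by 5 (1,000 retained draws per chain),
    Normal(0, 1) priors on mean parameters and half-Student-t(3, 0, 2.5)
    priors on standard-deviation parameters.
    """

    n_chains: int = 4
    n_iter: int = 10_000
    n_warmup: int = 5_000
    thin: int = 5
    seed: int = 0
    prior_mean_sd: float = 1.0
    prior_var_df: int = 3
    prior_var_scale: float = 2.5

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_iter:
            raise ValueError("n_warmup must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @classmethod
    def test_mode(cls, seed: int = 0, **kw) -> "McmcConfig":
        """Reduced-size settings (2 chains x 2,000 iterations, 1,000
        warm-up, no thinning) with the same priors."""
        kw.setdefault("n_chains", 2)
        kw.setdefault("n_iter", 2_000)
        kw.setdefault("n_warmup", 1_000)
        kw.setdefault("thin", 1)
        return cls(seed=seed, **kw)


def _inv_gamma(rng: np.random.Generator, shape: float, scale, size=None) -> np.ndarray:
    return scale / rng.gamma(shape, 1.0, size=size)


def _gibbs_chain(
    y: np.ndarray,
    X: np.ndarray,
    codes: dict[str, np.ndarray],
    n_levels: dict[str, int],
    cfg: McmcConfig,
    rng: np.random.Generator,
    store_effects: bool,
) -> dict[str, np.ndarray]:
    n, p = X.shape
    nu, A = cfg.prior_var_df, cfg.prior_var_scale
    XtX = X.T @ X
    prior_prec_beta = np.eye(p) / cfg.prior_mean_sd**2

    # translation (interweaving) moves between the intercept and each
    # random-effect block need an intercept column; detect a constant one
    icol = next((j for j in range(p) if np.all(X[:, j] == 1.0)), None)

    beta = np.zeros(p)
    u = {k: np.zeros(q) for k, q in n_levels.items()}
    sig2 = {k: 1.0 for k in n_levels}
    a_k = {k: 1.0 for k in n_levels}
    sig2_e, a_e = 1.0, 1.0
    counts = {k: np.bincount(c, minlength=n_levels[k]).astype(float)
              for k, c in codes.items()}

    n_keep = (cfg.n_iter - cfg.n_warmup) // cfg.thin
    out = {
        "beta": np.empty((n_keep, p)),
        "sigma2_resid": np.empty(n_keep),
        **{f"sigma2_{k}": np.empty(n_keep) for k in n_levels},
    }
    if store_effects:
        out.update({f"u_{k}": np.empty((n_keep, q)) for k, q in n_levels.items()})

    ranef_sum = np.zeros(n)  # sum_k u_k[codes_k]
    kept = 0
    for it in range(cfg.n_iter):
        # fixed effects
        r = y - ranef_sum
        P = XtX / sig2_e + prior_prec_beta
        L = np.linalg.cholesky(P)
        m = np.linalg.solve(P, X.T @ r / sig2_e)
        beta = m + np.linalg.solve(L.T, rng.standard_normal(p))
        fitted_fix = X @ beta

        # random intercepts, one factor at a time
        for k, c in codes.items():
            ranef_sum -= u[k][c]
            rk = y - fitted_fix - ranef_sum
            prec = counts[k] / sig2_e + 1.0 / sig2[k]
            mean = (np.bincount(c, weights=rk, minlength=n_levels[k]) / sig2_e) / prec
            u[k] = mean + rng.standard_normal(n_levels[k]) / np.sqrt(prec)
            ranef_sum += u[k][c]

            q = n_levels[k]
            if icol is not None:
                # exact Gibbs step along the translation direction
                # (beta_0 + d, u_k - d): decorrelates the intercept from
                # the level means without changing the posterior
                prec_d = 1.0 / cfg.prior_mean_sd**2 + q / sig2[k]
                mean_d = (-beta[icol] / cfg.prior_mean_sd**2 + u[k].sum() / sig2[k]) / prec_d
                d = mean_d + rng.standard_normal() / np.sqrt(prec_d)
                beta[icol] += d
                u[k] -= d
                fitted_fix += d
                ranef_sum -= d
            sig2[k] = _inv_gamma(rng, (nu + q) / 2.0, nu / a_k[k] + 0.5 * u[k] @ u[k])
            a_k[k] = _inv_gamma(rng, (nu + 1) / 2.0, nu / sig2[k] + 1.0 / A**2)

        # residual variance
        e = y - fitted_fix - ranef_sum
        sig2_e = _inv_gamma(rng, (nu + n) / 2.0, nu / a_e + 0.5 * e @ e)
        a_e = _inv_gamma(rng, (nu + 1) / 2.0, nu / sig2_e + 1.0 / A**2)

        if it >= cfg.n_warmup and (it - cfg.n_warmup) % cfg.thin == 0:
            out["beta"][kept] = beta
            out["sigma2_resid"][kept] = sig2_e
            for k in n_levels:
                out[f"sigma2_{k}"][kept] = sig2[k]
                if store_effects:
                    out[f"u_{k}"][kept] = u[k]
            kept += 1
    return out


@dataclass
class GibbsLMMFit:
    """Posterior draws for one Gaussian mixed model.

    ``draws`` maps parameter names to arrays of shape (chains, draws) for
    scalars, (chains, draws, p) for the fixed-effect vector ``beta`` and
    (chains, draws, q_k) for the level effects ``u_<factor>``.
    """

    draws: dict[str, np.ndarray]
    fixed_names: list[str]
    factor_names: list[str]
    level_labels: dict[str, np.ndarray]
    config: McmcConfig
    response_scaler: Scaler | None = None
    meta: dict = field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def scalar_params(self) -> dict[str, np.ndarray]:
        """All scalar parameters as (chains, draws) arrays (beta unpacked)."""
        out = {}
        for i, nm in enumerate(self.fixed_names):
            out[f"beta_{nm}"] = self.draws["beta"][:, :, i]
        for k in self.factor_names:
            out[f"sigma2_{k}"] = self.draws[f"sigma2_{k}"]
        out["sigma2_resid"] = self.draws["sigma2_resid"]
        return out

    def summary(self) -> pd.DataFrame:
        """Posterior mean and estimation error (posterior sd) per scalar
        parameter."""
        rows = {
            nm: {"mean": d.mean(), "sd": d.std(ddof=1)}
            for nm, d in self.scalar_params().items()
        }
        return pd.DataFrame(rows).T

    def variance_components(self, scale: str = "fitted") -> dict[str, float]:
        """Posterior-mean variance components.

        ``scale="fitted"`` returns them on the (possibly z-scored) scale the
        model was fitted on; ``scale="response"`` multiplies by the stored
        response-scaler variance, i.e. back to the log-response scale.
        """
        comps = {k: float(self.draws[f"sigma2_{k}"].mean()) for k in self.factor_names}
        comps["resid"] = float(self.draws["sigma2_resid"].mean())
        if scale == "response":
            if self.response_scaler is None:
                raise ValueError("fit has no response scaler")
            s2 = self.response_scaler.sd**2
            comps = {k: v * s2 for k, v in comps.items()}
        elif scale != "fitted":
            raise ValueError("scale must be 'fitted' or 'response'")
        return comps

    def to_json(self) -> str:
        payload = {
            "fixed_names": self.fixed_names,
            "factor_names": self.factor_names,
            "summary": self.summary().to_dict(),
            "variance_components": self.variance_components(),
            "config": asdict(self.config),
            "meta": {k: v for k, v in self.meta.items() if isinstance(v, (int, float, str))},
        }
        return json.dumps(payload, indent=2)


def gibbs_lmm(
    y: np.ndarray,
    X: np.ndarray,
    factors: dict[str, np.ndarray],
    config: McmcConfig,
    fixed_names: list[str] | None = None,
    store_effects: bool = True,
    response_scaler: Scaler | None = None,
) -> GibbsLMMFit:
    """Sample the posterior of a Gaussian mixed model by blocked Gibbs.

    Parameters
    ----------
    y, X
        Response vector (n,) and fixed-effect design matrix (n, p).
    factors
        Mapping factor name -> length-n array of group labels (any dtype);
        each factor contributes a random intercept per level.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in response or design")
    codes, n_levels, level_labels = {}, {}, {}
    for k, lab in factors.items():
        lab = np.asarray(lab)
        if lab.shape[0] != y.shape[0]:
            raise ValueError(f"factor {k!r} has wrong length")
        uniq, c = np.unique(lab, return_inverse=True)
        codes[k], n_levels[k], level_labels[k] = c, len(uniq), uniq

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [
        _gibbs_chain(y, X, codes, n_levels, config,
                     np.random.default_rng(s), store_effects)
        for s in seeds
    ]
    draws = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    if fixed_names is None:
        fixed_names = [f"x{i}" for i in range(X.shape[1])]
    return GibbsLMMFit(
        draws=draws,
        fixed_names=list(fixed_names),
        factor_names=list(factors),
        level_labels=level_labels,
        config=config,
        response_scaler=response_scaler,
        meta={"n_obs": int(y.shape[0])},
    )


@dataclass
class ImperfectFit:
    """Per-species fits of the single-covariate individual-effects model."""

    species_fits: dict[object, GibbsLMMFit]

    def vbj(self) -> dict[object, float]:
        """Posterior-mean individual-effect variance per species."""
        return {
            j: f.variance_components()["individual"]
            for j, f in self.species_fits.items()
        }

    def vj(self) -> dict[object, float]:
        """Posterior-mean residual variance per species."""
        return {
            j: f.variance_components()["resid"] for j, f in self.species_fits.items()
        }


def fit_imperfect_model(
    data: pd.DataFrame,
    config: McmcConfig,
    covariates: tuple[str, ...] = ("X1",),
) -> ImperfectFit:
    """Fit, independently per species, ln Y against ln X1 with an
    individual random intercept.

    ``data`` needs columns ``i`` (individual), ``j`` (species), ``Y`` and
    ``X1``.  ``covariates`` may list further columns (entered linearly,
    untransformed) — passing all of X1..XN gives the fully observed
    benchmark in which the individual-effect and residual variances should
    collapse.
    """
    for col in ("i", "j", "Y", "X1"):
        if col not in data.columns:
            raise ValueError(f"data is missing required column {col!r}")
    if (data["Y"] <= 0).any() or (data["X1"] <= 0).any():
        raise ValueError("Y and X1 must be strictly positive (log model)")
    fits: dict[object, GibbsLMMFit] = {}
    for idx, (j, sub) in enumerate(data.groupby("j", sort=True)):
        y = np.log(sub["Y"].to_numpy(float))
        cols = [np.ones(len(sub)), np.log(sub["X1"].to_numpy(float))]
        names = ["intercept", "lnX1"]
        for c in covariates:
            if c == "X1":
                continue
            cols.append(sub[c].to_numpy(float))
            names.append(c)
        X = np.column_stack(cols)
        cfg = McmcConfig(**{**asdict(config), "seed": config.seed + idx})
        fits[j] = gibbs_lmm(
            y, X, {"individual": sub["i"].to_numpy()}, cfg, fixed_names=names
        )
    return ImperfectFit(species_fits=fits)


def fit_clonal_growth_model(growth: pd.DataFrame, config: McmcConfig) -> GibbsLMMFit:
    """Clonal-trial growth model: z(ln(G+1)) on z(ln D) and z(ln C) with
    block, genotype, census-date and individual random intercepts.

    ``growth`` needs columns ``G`` (mm/year), ``dbh_start`` (mm),
    ``comp_index`` (mm^2), ``block``, ``genotype``, ``date_start`` (or
    ``date``), ``tree_id``.
    """
    date_col = "date_start" if "date_start" in growth.columns else "date"
    for col in ("G", "dbh_start", "comp_index", "block", "genotype", date_col, "tree_id"):
        if col not in growth.columns:
            raise ValueError(f"growth table is missing required column {col!r}")
    y, sy = log_shift_scale(growth["G"].to_numpy(float), shift=1.0)
    lnD, _ = log_shift_scale(growth["dbh_start"].to_numpy(float), shift=0.0)
    # competition can be 0 for an isolated tree; 1 mm^2 shift keeps the log finite
    lnC, _ = log_shift_scale(growth["comp_index"].to_numpy(float), shift=1.0)
    X = np.column_stack([np.ones(len(growth)), lnD, lnC])
    factors = {
        "block": growth["block"].to_numpy(),
        "genotype": growth["genotype"].to_numpy(),
        "date": growth[date_col].to_numpy(),
        "individual": growth["tree_id"].to_numpy(),
    }
    return gibbs_lmm(
        y, X, factors, config,
        fixed_names=["intercept", "lnD", "lnC"],
        response_scaler=sy,
    )


def fit_forest_growth_model(growth: pd.DataFrame, config: McmcConfig) -> GibbsLMMFit:
    """Forest-inventory growth model: z(ln(G+2)) on z(ln D) with species and
    individual random intercepts.  Requires at least two species."""
    for col in ("G", "dbh_start", "species", "tree_id"):
        if col not in growth.columns:
            raise ValueError(f"growth table is missing required column {col!r}")
    n_species = growth["species"].nunique()
    if n_species < 2:
        raise ValueError(
            "species variance is unidentifiable with a single species; need >= 2"
        )
    singletons = growth.groupby("species")["tree_id"].nunique()
    if (singletons == 1).any():
        warnings.warn(
            f"{int((singletons == 1).sum())} species have a single individual; "
            "their species and individual effects are confounded",
            stacklevel=2,
        )
    y, sy = log_shift_scale(growth["G"].to_numpy(float), shift=2.0)
    lnD, _ = log_shift_scale(growth["dbh_start"].to_numpy(float), shift=0.0)
    X = np.column_stack([np.ones(len(growth)), lnD])
    factors = {
        "species": growth["species"].to_numpy(),
        "individual": growth["tree_id"].to_numpy(),
    }
    return gibbs_lmm(
        y, X, factors, config,
        fixed_names=["intercept", "lnD"],
        response_scaler=sy,
    )


@dataclass
class VariancePartition:
    """Named variance components and their shares of the summed variance."""

    components: dict[str, float]
    percent: dict[str, float]

    def __getitem__(self, k: str) -> float:
        return self.percent[k]


def partition_variance(components: dict[str, float]) -> VariancePartition:
    """Express each variance component as a percentage of their sum,
    reported at two decimals.

    This is the partition of the model's unexplained variance among its
    random effects (and the residual), as printed under hierarchical growth
    model fits.
    """
    if not components:
        raise ValueError("need at least one component")
    vals = np.array(list(components.values()), float)
    if np.any(vals < 0):
        raise ValueError("variance components must be nonnegative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("all components are zero: partition undefined")
    pct = {k: round(100.0 * v / total, 2) for k, v in components.items()}
    return VariancePartition(components=dict(components), percent=pct)


@dataclass
class ConvergenceReport:
    """Split R-hat and bulk ESS per scalar parameter, with a pass flag."""

    table: pd.DataFrame  # index: parameter; columns: rhat, ess
    rhat_max: float
    ess_min: float
    passed: bool


def check_convergence(
    fit: GibbsLMMFit, rhat_max: float = 1.05, ess_min: float = 400.0
) -> ConvergenceReport:
    """Compute split R-hat and bulk effective sample size for every scalar
    parameter via arviz; the report passes iff all R-hat <= rhat_max and all
    ESS >= ess_min.  Requires at least two chains."""
    import arviz as az

    params = fit.scalar_params()
    first = next(iter(params.values()))
    if first.shape[0] < 2:
        raise ValueError("convergence diagnostics require >= 2 chains")
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for nm, d in params.items():
            ds = az.convert_to_dataset(d)
            rows[nm] = {
                "rhat": float(np.asarray(az.rhat(ds)["x"])),
                "ess": float(np.asarray(az.ess(ds)["x"])),
            }
    table = pd.DataFrame(rows).T
    finite = table.replace([np.inf, -np.inf], np.nan)
    passed = bool(
        finite.notna().all().all()
        and (finite["rhat"] <= rhat_max).all()
        and (finite["ess"] >= ess_min).all()
    )
    return ConvergenceReport(table=table, rhat_max=rhat_max, ess_min=ess_min, passed=passed)


def predictive_envelope(
    fit: ImperfectFit,
    x1_grid: np.ndarray,
    level: float = 0.95,
    include_residual: bool = True,
    seed: int = 0,
) -> dict[object, pd.DataFrame]:
    """Per-species posterior-predictive mean curve and credible band over a
    grid of the observed covariate, marginalised over individuals.

    For each posterior draw the linear predictor at ln x1 is perturbed by a
    fresh individual effect ~ N(0, V_bj) (and, if ``include_residual``, a
    residual ~ N(0, V_j)); the band is the (1-level)/2 and 1-(1-level)/2
    quantile of those draws, so its width grows with V_bj.  Returned frames
    have columns ``x1, mean, lo, hi`` on the ln Y scale.
    """
    x1_grid = np.asarray(x1_grid, float)
    if x1_grid.size == 0:
        raise ValueError("x1_grid is empty")
    if np.any(x1_grid <= 0):
        raise ValueError("x1 grid values must be positive")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rng = np.random.default_rng(seed)
    out = {}
    for j, f in fit.species_fits.items():
        beta = f.stacked("beta")  # (S, p>=2)
        vb = f.stacked("sigma2_individual")
        ve = f.stacked("sigma2_resid")
        lnx = np.log(x1_grid)
        mu = beta[:, [0]] + beta[:, [1]] * lnx[None, :]  # (S, G)
        pred = mu + rng.standard_normal(mu.shape) * np.sqrt(vb)[:, None]
        if include_residual:
            pred = pred + rng.standard_normal(mu.shape) * np.sqrt(ve)[:, None]
        out[j] = pd.DataFrame(
            {
                "x1": x1_grid,
                "mean": mu.mean(axis=0),
                "lo": np.quantile(pred, lo_q, axis=0),
                "hi": np.quantile(pred, hi_q, axis=0),
            }
        )
    return out
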