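"""Virtual landscape simulation and the deterministic attribute model.

A landscape is a stack of ``N`` statistically independent environmental
dimensions on a ``C x C`` grid, each a stationary Gaussian random field with
exponential covariance (unit sill, configurable range).  The first dimension
plays the role of the single covariate an observer would actually measure in
the field (e.g. light); it is exponentiated so that it lives on a strictly
positive support and can be log-transformed by downstream models.  Dimensions
listed in ``dynamic_dims`` are regenerated independently at every date, the
rest are frozen at their initial value.

The attribute of individual ``i`` of species ``j`` at date ``t`` is fully
determined by the environment of its cell:

    ln Y_ijt = beta_0j + beta_1j * ln X1_ijt + sum_{n>=2} beta_nj * Xn_ijt

There is no noise term: conspecific individuals are clones, and all the
variation among them comes from where (and when) they sit in the landscape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EnvironmentalLandscape",
    "SpeciesResponseSet",
    "generate_environment",
    "place_individuals",
    "draw_species_responses",
    "simulate_attribute",
]


def _exponential_grf(C: int, corr_range: float, rng: np.random.Generator) -> np.ndarray:
    """One C x C draw of a zero-mean, unit-variance Gaussian random field
    with covariance exp(-h / corr_range), via circulant embedding on a
    2C x 2C torus.  Negative embedding eigenvalues (tiny for the
    exponential model) are clipped to zero.
    """
    M = 2 * C
    idx = np.arange(M)
    d = np.minimum(idx, M - idx).astype(float)
    h = np.hypot(d[:, None], d[None, :])
    lam = np.fft.fft2(np.exp(-h / corr_range)).real
    lam = np.clip(lam, 0.0, None)
    noise = rng.standard_normal((M, M)) + 1j * rng.standard_normal((M, M))
    fld = (np.fft.fft2(noise * np.sqrt(lam)) / M).real
    return np.ascontiguousarray(fld[:C, :C])


@dataclass
class EnvironmentalLandscape:
    """Stack of environmental fields, shape ``(N, T, C, C)``.

    ``fields[0]`` is the strictly positive observed dimension X1 (lognormal
    layer); ``fields[n-1]`` for n >= 2 are Gaussian layers.  Dimensions are
    1-based in the public API, matching the X1..XN notation.
    """

    grid_size: int
    n_dims: int
    n_dates: int
    autocorr_range: float
    dynamic_dims: frozenset[int]
    seed: int
    fields: np.ndarray = field(repr=False)

    def layer(self, dim: int, date: int) -> np.ndarray:
        """Field for 1-based dimension ``dim`` at 0-based ``date``."""
        if not 1 <= dim <= self.n_dims:
            raise ValueError(f"dimension must be in 1..{self.n_dims}, got {dim}")
        return self.fields[dim - 1, date]

    def covariates_at(self, rows: np.ndarray, cols: np.ndarray, date: int) -> np.ndarray:
        """Covariate matrix (len(rows), N) sampled at grid cells."""
        return self.fields[:, date, rows, cols].T

    def to_text(self, dim: int, date: int) -> str:
        """Plain-text matrix dump of one layer, for inspection."""
        return "\n".join(
            " ".join(f"{v:.6g}" for v in row) for row in self.layer(dim, date)
        )


@dataclass
class SpeciesResponseSet:
    """Per-species response coefficients beta_j = [beta_0j, ..., beta_Nj]."""

    n_species: int
    n_dims: int
    coefficients: np.ndarray  # (J, N + 1)
    seed: int

    def __post_init__(self) -> None:
        if self.coefficients.shape != (self.n_species, self.n_dims + 1):
            raise ValueError("coefficients must have shape (J, N + 1)")


def generate_environment(
    C: int,
    N: int,
    T: int,
    autocorr_range: float,
    dynamic_dims: set[int] | frozenset[int] | None = None,
    seed: int = 0,
) -> EnvironmentalLandscape:
    """Generate ``N`` independent spatially autocorrelated fields on a
    ``C x C`` grid at ``T`` dates.

    Parameters
    ----------
    C, N, T
        Grid side (cells), number of environmental dimensions, number of
        dates.
    autocorr_range
        Range parameter of the exponential covariance, in cell units.
    dynamic_dims
        1-based dimensions regenerated independently at each date; the
        default regenerates the upper half of the dimensions,
        {floor(N/2)+2, ..., N}, keeping X1 and the lower unobserved
        dimensions fixed in time.  A persistent unobserved component is
        what an individual random intercept can absorb: if every
        unobserved dimension were redrawn at each date, individual
        deviations would be serially independent and the individual-effect
        variance would be genuinely zero.  Including dimension 1 is
        allowed but logged, since X1 stands for the observed covariate.
    seed
        Seed; identical seeds give bit-identical landscapes.
    """
    if C < 2 or N < 1 or T < 1:
        raise ValueError(f"need C >= 2, N >= 1, T >= 1 (got C={C}, N={N}, T={T})")
    if autocorr_range <= 0:
        raise ValueError("autocorr_range must be positive")
    if dynamic_dims is None:
        dynamic_dims = set(range(N // 2 + 2, N + 1))
    dynamic_dims = frozenset(int(d) for d in dynamic_dims)
    if not dynamic_dims <= set(range(1, N + 1)):
        raise ValueError("dynamic_dims must be a subset of 1..N")
    if 1 in dynamic_dims:
        logger.warning(
            "dimension 1 (the observed covariate X1) is dynamic; "
            "its values will change between dates"
        )

    rng = np.random.default_rng(seed)
    fields = np.empty((N, T, C, C))
    for n in range(1, N + 1):
        base = _exponential_grf(C, autocorr_range, rng)
        for t in range(T):
            if t > 0 and n in dynamic_dims:
                fields[n - 1, t] = _exponential_grf(C, autocorr_range, rng)
            else:
                fields[n - 1, t] = base
    # X1 lives on positive support: lognormal layer, so ln X1 is Gaussian.
    fields[0] = np.exp(fields[0])
    return EnvironmentalLandscape(
        grid_size=C,
        n_dims=N,
        n_dates=T,
        autocorr_range=autocorr_range,
        dynamic_dims=dynamic_dims,
        seed=seed,
        fields=fields,
    )


def place_individuals(I: int, J: int, C: int, seed: int = 0) -> pd.DataFrame:
    """Place ``I`` individuals per species for ``J`` species uniformly at
    random on the grid (individuals are sessile: one placement for all
    dates).

    Returns a frame with columns ``i`` (unique id), ``j`` (0-based species),
    ``row``, ``col`` (cell indices) and ``x``, ``y`` (cell-centre
    coordinates, cell units).
    """
    if I < 1 or J < 1 or I * J < 1:
        raise ValueError("need I >= 1 and J >= 1")
    if C < 1:
        raise ValueError("need C >= 1")
    rng = np.random.default_rng(seed)
    n = I * J
    rows = rng.integers(0, C, size=n)
    cols = rng.integers(0, C, size=n)
    return pd.DataFrame(
        {
            "i": np.arange(n),
            "j": np.repeat(np.arange(J), I),
            "row": rows,
            "col": cols,
            "x": cols + 0.5,
            "y": rows + 0.5,
        }
    )


def draw_species_responses(
    J: int, N: int, coef_scale: float = 1.0, seed: int = 0
) -> SpeciesResponseSet:
    """Draw species response vectors beta_j ~ N(0, coef_scale^2), i.i.d.
    over the N + 1 coefficients, redrawing in the (measure-zero) event that
    two species share a vector."""
    if J < 1 or N < 1:
        raise ValueError("need J >= 1 and N >= 1")
    if coef_scale <= 0:
        raise ValueError(
            "coef_scale must be positive: with zero scale all species "
            "would share the all-zero response vector"
        )
    rng = np.random.default_rng(seed)
    while True:
        beta = rng.normal(0.0, coef_scale, size=(J, N + 1))
        if len(np.unique(beta, axis=0)) == J:
            break
    return SpeciesResponseSet(n_species=J, n_dims=N, coefficients=beta, seed=seed)


def simulate_attribute(
    landscape: EnvironmentalLandscape,
    placements: pd.DataFrame,
    responses: SpeciesResponseSet,
) -> pd.DataFrame:
    """Evaluate the deterministic attribute model at every (individual,
    date).

    Returns one row per (individual, date) with columns
    ``i, j, t, x, y, Y, X1, ..., XN``; ``ln Y`` equals the linear predictor
    exactly.
    """
    if landscape.n_dims != responses.n_dims:
        raise ValueError(
            f"landscape has N={landscape.n_dims} but responses have "
            f"N={responses.n_dims}"
        )
    rows = placements["row"].to_numpy()
    cols = placements["col"].to_numpy()
    jj = placements["j"].to_numpy()
    if jj.max() >= responses.n_species:
        raise ValueError("placement species index out of range for responses")
    beta = responses.coefficients
    out = []
    for t in range(landscape.n_dates):
        X = landscape.covariates_at(rows, cols, t)  # (n, N)
        if np.any(X[:, 0] <= 0):
            raise ValueError("X1 must be strictly positive at occupied cells")
        Z = X.copy()
        Z[:, 0] = np.log(X[:, 0])
        lnY = beta[jj, 0] + np.einsum("nk,nk->n", Z, beta[jj, 1:])
        frame = pd.DataFrame(
            {
                "i": placements["i"].to_numpy(),
                "j": jj,
                "t": t,
                "x": placements["x"].to_numpy(),
                "y": placements["y"].to_numpy(),
                "Y": np.exp(lnY),
            }
        )
        for n in range(landscape.n_dims):
            frame[f"X{n + 1}"] = X[:, n]
        out.append(frame)
    return pd.concat(out, ignore_index=True)
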