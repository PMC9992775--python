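"""Census-table processing: growth computation, filtering, transforms.

All DBH values are in mm, dates in decimal years, growth in mm/year and
basal areas in mm^2.  Census tables are pandas frames with columns
``tree_id, species, plot, x, y, date, dbh_mm`` (plus ``block``/``genotype``
and grid ``row``/``col`` for trial data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "FilterLog",
    "Scaler",
    "annualized_growth",
    "mean_individual_growth",
    "apply_growth_filters",
    "competition_index",
    "log_shift_scale",
]


@dataclass
class FilterLog:
    """Row counts removed per filtering rule; conserves the input total."""

    n_input: int = 0
    growth_bounds: int = 0
    min_dbh: int = 0
    unidentified_species: int = 0
    singleton_individuals: int = 0
    singleton_species: int = 0
    n_retained: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.growth_bounds
            + self.min_dbh
            + self.unidentified_species
            + self.singleton_individuals
            + self.singleton_species
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Scaler:
    """Parameters of a log-shift-scale transform, kept for inversion."""

    shift: float
    mean: float
    sd: float

    def transform(self, v: np.ndarray) -> np.ndarray:
        return (np.log(np.asarray(v, float) + self.shift) - self.mean) / self.sd

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.exp(np.asarray(z, float) * self.sd + self.mean) - self.shift


def _check_census(df: pd.DataFrame, cols=("tree_id", "date", "dbh_mm")) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"census table missing columns: {missing}")


def annualized_growth(censuses: pd.DataFrame) -> pd.DataFrame:
    """Annualized growth per consecutive census pair and tree:
    G = (DBH_next - DBH) / (date_next - date), in mm/year.

    Carries over identity columns (species, plot, genotype, block, x, y,
    row, col) and records the start-of-interval DBH as ``dbh_start``.
    Single-census trees simply produce no interval.
    """
    _check_census(censuses)
    df = censuses.sort_values(["tree_id", "date"], kind="mergesort")
    g = df.groupby("tree_id", sort=False)
    nxt_dbh = g["dbh_mm"].shift(-1)
    nxt_date = g["date"].shift(-1)
    mask = nxt_dbh.notna()
    dt = (nxt_date - df["date"])[mask]
    bad = dt <= 0
    if bad.any():
        offender = df.loc[bad[bad].index[0], "tree_id"]
        raise ValueError(
            f"non-increasing census dates for tree {offender!r} "
            "(zero or negative interval)"
        )
    out = df.loc[mask, [c for c in df.columns if c != "dbh_mm"]].copy()
    out = out.rename(columns={"date": "date_start"})
    out["date_end"] = nxt_date[mask]
    out["dbh_start"] = df.loc[mask, "dbh_mm"]
    out["G"] = (nxt_dbh[mask] - df.loc[mask, "dbh_mm"]) / dt
    return out.reset_index(drop=True)


def mean_individual_growth(censuses: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Mean annual growth per tree from its first and last measurement:
    (DBH_last - DBH_first) / (t_last - t_first).

    Returns the per-tree table and the count of single-measurement trees
    excluded.  Identity columns are taken from the first census of each
    tree.
    """
    _check_census(censuses)
    df = censuses.sort_values(["tree_id", "date"], kind="mergesort")
    g = df.groupby("tree_id", sort=False)
    first = g.first()
    last = g.last()
    n_meas = g.size()
    dt = last["date"] - first["date"]
    keep = n_meas >= 2
    if (dt[keep] <= 0).any():
        offender = dt[keep][dt[keep] <= 0].index[0]
        raise ValueError(f"non-increasing census dates for tree {offender!r}")
    out = first.loc[keep, [c for c in first.columns if c not in ("date", "dbh_mm")]].copy()
    out["mean_growth"] = (last["dbh_mm"] - first["dbh_mm"])[keep] / dt[keep]
    out["n_censuses"] = n_meas[keep]
    out = out.reset_index()
    return out, int((~keep).sum())


def _is_unidentified(species: pd.Series) -> pd.Series:
    s = species.astype("string")
    return s.isna() | (s.str.strip() == "") | s.str.lower().str.contains("indet")


def apply_growth_filters(
    growth: pd.DataFrame,
    min_dbh: float = 100.0,
    g_min: float = -2.0,
    g_max: float = 100.0,
    drop_unidentified: bool = True,
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply the growth-record filters, in order: growth bounds (keep
    g_min <= G <= g_max, strict-inequality removal), minimum
    start-of-interval DBH, unidentified species (missing/empty or
    'indet'-like names), individuals with a single remaining observation,
    then species with a single remaining individual.

    Returns the retained table and a :class:`FilterLog` whose removed
    counts plus the retained count equal the input count.
    """
    if g_min >= g_max:
        raise ValueError("need g_min < g_max")
    log = FilterLog(n_input=len(growth))
    df = growth

    bad = (df["G"] < g_min) | (df["G"] > g_max)
    log.growth_bounds = int(bad.sum())
    df = df[~bad]

    if "dbh_start" in df.columns and min_dbh is not None:
        small = df["dbh_start"] < min_dbh
        log.min_dbh = int(small.sum())
        df = df[~small]

    if drop_unidentified and "species" in df.columns:
        unid = _is_unidentified(df["species"])
        log.unidentified_species = int(unid.sum())
        df = df[~unid]

    counts = df.groupby("tree_id")["tree_id"].transform("size")
    single = counts == 1
    log.singleton_individuals = int(single.sum())
    df = df[~single]

    if "species" in df.columns:
        n_ind = df.groupby("species")["tree_id"].transform("nunique")
        lone = n_ind == 1
        log.singleton_species = int(lone.sum())
        df = df[~lone]

    log.n_retained = len(df)
    return df.reset_index(drop=True), log


def competition_index(
    trees: pd.DataFrame,
    group_cols: tuple[str, ...] = ("block",),
    row_col: tuple[str, str] = ("row", "col"),
    dbh_col: str = "dbh_mm",
) -> pd.DataFrame:
    """Competition index on a regular planting grid: for each tree, the sum
    of the basal areas pi*(DBH/2)^2 of its (up to) eight Moore neighbours
    sharing the same grouping (e.g. block).

    Returns a copy of ``trees`` with columns ``comp_index`` (mm^2),
    ``n_neighbors`` and ``edge_tree`` (fewer than 8 neighbours present).
    """
    r, c = row_col
    out = trees.copy()
    out["comp_index"] = 0.0
    out["n_neighbors"] = 0
    ba = np.pi * (out[dbh_col].to_numpy(float) / 2.0) ** 2
    groups = out.groupby(list(group_cols)).indices if group_cols else {None: np.arange(len(out))}
    comp = np.zeros(len(out))
    nnb = np.zeros(len(out), dtype=int)
    rows_all = out[r].to_numpy(int)
    cols_all = out[c].to_numpy(int)
    for idx in groups.values():
        pos = {(rows_all[i], cols_all[i]): i for i in idx}
        if len(pos) != len(idx):
            raise ValueError("duplicate (row, col) position within a group")
        for i in idx:
            rr, cc = rows_all[i], cols_all[i]
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    nb = pos.get((rr + dr, cc + dc))
                    if nb is not None:
                        comp[i] += ba[nb]
                        nnb[i] += 1
    out["comp_index"] = comp
    out["n_neighbors"] = nnb
    out["edge_tree"] = nnb < 8
    return out


def log_shift_scale(values: np.ndarray, shift: float = 0.0) -> tuple[np.ndarray, Scaler]:
    """z-score of ln(values + shift); the returned :class:`Scaler` inverts
    the transform exactly.

    The shift is the additive constant that keeps the logarithm defined for
    zero (or mildly negative) growth values: 1 mm/year for the clonal-trial
    response, 2 mm/year for the forest-inventory response.
    """
    v = np.asarray(values, float)
    shifted = v + shift
    if np.any(shifted <= 0):
        bad = np.nonzero(shifted <= 0)[0]
        raise ValueError(
            f"{bad.size} values have value + shift <= 0 (first rows: {bad[:5].tolist()})"
        )
    logv = np.log(shifted)
    mean = float(logv.mean())
    sd = float(logv.std(ddof=0))
    if sd == 0:
        raise ValueError("constant input: standard deviation is zero")
    return (logv - mean) / sd, Scaler(shift=shift, mean=mean, sd=sd)
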