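"""Readers, run configuration and the pipeline driver."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import growth as gp
from . import hier, landscape, spatial, synth

logger = logging.getLogger(__name__)

__all__ = ["read_census", "RunConfig", "run_pipeline", "prepare_mean_growth"]

REQUIRED_CENSUS_COLUMNS = ("tree_id", "species", "plot", "x", "y", "date", "dbh_mm")
_KNOWN_KEYS = {
    "pipeline", "seed", "out_dir", "min_dbh", "g_min", "g_max", "radius",
    "alpha", "max_sample", "max_per_species", "census_path", "test_mode",
    "sim", "forest", "clonal", "mcmc",
}


def read_census(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a census CSV/TSV, enforcing the required schema and units.

    Required columns: tree_id, species, plot, x, y, date, dbh_mm (genotype,
    block, row, col are carried through when present).  Raises on missing
    columns; reports malformed (non-numeric) rows with their line numbers;
    warns when the DBH distribution suggests cm rather than mm (median
    below 30 is implausible for a >= 10 cm-DBH inventory in mm).
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"census file {path} is missing columns: {missing}")
    bad_rows = []
    for col in ("x", "y", "date", "dbh_mm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        bad_rows.extend((int(i) + 2, col) for i in df.index[bad])  # +2: header + 1-base
        df[col] = coerced
    if bad_rows:
        raise ValueError(f"non-numeric values in census file (line, column): {bad_rows[:10]}")
    if df["dbh_mm"].isna().any():
        raise ValueError("missing DBH values in census file")
    if df["dbh_mm"].median() < 30:
        warnings.warn(
            "median DBH < 30: values look like cm, expected mm", stacklevel=2
        )
    return df


def prepare_mean_growth(
    censuses: pd.DataFrame,
    min_dbh: float = 100.0,
    g_min: float = -2.0,
    g_max: float = 100.0,
) -> tuple[pd.DataFrame, gp.FilterLog]:
    """Standard preparation chain for the spatial analyses: annualized
    growth -> growth filters -> per-tree mean growth restricted to trees
    that survived filtering."""
    growth = gp.annualized_growth(censuses)
    kept, log = gp.apply_growth_filters(growth, min_dbh=min_dbh, g_min=g_min, g_max=g_max)
    surviving = set(kept["tree_id"])
    mean_growth, _ = gp.mean_individual_growth(
        censuses[censuses["tree_id"].isin(surviving)]
    )
    return mean_growth, log


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected so typos in
    config files fail loudly instead of silently using defaults."""

    pipeline: str = "inventory"  # "virtual" | "inventory"
    seed: int = 0
    out_dir: str = "ivscape_out"
    census_path: str | None = None
    min_dbh: float = 100.0
    g_min: float = -2.0
    g_max: float = 100.0
    radius: float = 100.0
    alpha: float = 0.05
    max_sample: int = 3000
    max_per_species: int | None = None
    test_mode: bool = False
    sim: dict = field(default_factory=dict)
    forest: dict = field(default_factory=dict)
    clonal: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def mcmc_config(self) -> hier.McmcConfig:
        kw = dict(self.mcmc)
        kw.setdefault("seed", self.seed)
        if self.test_mode:
            return hier.McmcConfig.test_mode(**kw)
        return hier.McmcConfig(**kw)


def _manifest(config: RunConfig, stages: list[str], extra: dict) -> dict:
    from . import __version__

    return {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": stages,
        "thresholds": {
            "min_dbh": config.min_dbh, "g_min": config.g_min,
            "g_max": config.g_max, "radius": config.radius,
            "alpha": config.alpha,
        },
        **extra,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run one of the two bundled pipelines and write its outputs.

    ``pipeline="virtual"``: simulate the landscape attribute data, fit the
    imperfect-knowledge model, compute per-species and pooled
    semivariograms.  ``pipeline="inventory"``: generate (or read) a census
    table, prepare mean growth, run the Moran screen and the
    intra-vs-inter comparison.

    Outputs land under ``config.out_dir`` with a ``manifest.json``
    recording seed, config hash and thresholds.  Returns the result bundle.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    bundle: dict = {}
    try:
        if config.pipeline == "virtual":
            sim = {
                "C": 100, "N": 10, "T": 2, "I": 100, "J": 2,
                "range": 10.0, "coef_scale": 1.0,
            }
            sim.update(config.sim)
            env = landscape.generate_environment(
                sim["C"], sim["N"], sim["T"], sim["range"], seed=config.seed
            )
            placements = landscape.place_individuals(
                sim["I"], sim["J"], sim["C"], seed=config.seed + 1
            )
            responses = landscape.draw_species_responses(
                sim["J"], sim["N"], sim["coef_scale"], seed=config.seed + 2
            )
            data = landscape.simulate_attribute(env, placements, responses)
            data.to_csv(out / "attribute.csv", index=False)
            stages.append("simulate")

            fit = hier.fit_imperfect_model(data, config.mcmc_config())
            for j, f in fit.species_fits.items():
                (out / f"fit_species{j}.json").write_text(f.to_json())
            bundle["vbj"] = fit.vbj()
            stages.append("fit-imperfect")

            mean_y = data.groupby(["i", "j", "x", "y"], as_index=False)["Y"].mean()
            edges = np.linspace(0, sim["C"] / 2, 11)
            curves = {"all": spatial.empirical_semivariogram(
                mean_y["Y"], mean_y[["x", "y"]], edges)}
            for j, sub in mean_y.groupby("j"):
                curves[f"species{j}"] = spatial.empirical_semivariogram(
                    sub["Y"], sub[["x", "y"]], edges)
            for name, curve in curves.items():
                curve.to_csv(out / f"semivariogram_{name}.csv", index=False)
            bundle["semivariograms"] = curves
            bundle["fit"] = fit
            stages.append("semivariogram")

        elif config.pipeline == "inventory":
            if config.census_path:
                census = read_census(config.census_path)
            else:
                fcfg = synth.ForestInventoryConfig(
                    **{**config.forest, "seed": config.seed}
                )
                census, _ = synth.generate_forest_inventory(fcfg)
            census.to_csv(out / "census.csv", index=False)
            stages.append("census")

            mean_growth, flog = prepare_mean_growth(
                census, config.min_dbh, config.g_min, config.g_max
            )
            mean_growth.to_csv(out / "mean_growth.csv", index=False)
            (out / "filter_log.json").write_text(json.dumps(flog.to_dict(), indent=2))
            bundle["filter_log"] = flog
            stages.append("prep-growth")

            screen, screen_summary = spatial.species_autocorrelation_screen(
                mean_growth, radius=config.radius, alpha=config.alpha,
                max_sample=config.max_sample, seed=config.seed,
            )
            screen.to_csv(out / "moran_screen.csv", index=False)
            bundle["screen"], bundle["screen_summary"] = screen, screen_summary
            stages.append("spatial-screen")

            comp, comp_summary = spatial.compare_intra_inter(
                mean_growth, radius=config.radius, alpha=config.alpha,
                max_per_species=config.max_per_species, seed=config.seed,
            )
            comp.to_csv(out / "semivar_comparison.csv", index=False)
            bundle["comparison"], bundle["comparison_summary"] = comp, comp_summary
            (out / "summaries.json").write_text(json.dumps(
                {"screen": screen_summary, "comparison": comp_summary}, indent=2))
            stages.append("semivar-compare")
        else:
            raise ValueError(f"unknown pipeline {config.pipeline!r}")
    except Exception:
        (out / "manifest.json").write_text(
            json.dumps(_manifest(config, stages, {"status": "failed"}), indent=2)
        )
        logger.exception("pipeline failed after stages %s", stages)
        raise
    manifest = _manifest(config, stages, {"status": "ok"})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
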