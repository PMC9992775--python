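import numpy as np
import pandas as pd
import pytest

from ivscape import hier, landscape, synth


@pytest.fixture(scope="session")
def small_virtual_data():
    """Attribute dataset from a small virtual landscape (2 species)."""
    env = landscape.generate_environment(60, 5, 2, 8.0, seed=11)
    placements = landscape.place_individuals(60, 2, 60, seed=12)
    responses = landscape.draw_species_responses(2, 5, 1.0, seed=13)
    data = landscape.simulate_attribute(env, placements, responses)
    return env, placements, responses, data


@pytest.fixture(scope="session")
def small_clonal():
    cfg = synth.ClonalTrialConfig(
        n_blocks=3, n_genotypes=4, trees_per_plot=16, n_censuses=4, seed=21
    )
    return synth.generate_clonal_trial(cfg)


@pytest.fixture(scope="session")
def small_inventory():
    cfg = synth.ForestInventoryConfig(
        n_trees=600, n_species=8, n_plots=2, n_censuses=4, seed=31
    )
    return synth.generate_forest_inventory(cfg)


@pytest.fixture(scope="session")
def mcmc_test_config():
    return hier.McmcConfig.test_mode(seed=5)


@pytest.fixture
def toy_census():
    """Three trees, three censuses each, mm DBH, decimal-year dates."""
    rows = []
    for tid, (d0, inc) in {"t1": (120.0, 4.0), "t2": (150.0, 0.0), "t3": (200.0, 8.0)}.items():
        for k in range(3):
            rows.append(
                {
                    "tree_id": tid,
                    "species": "sp_a" if tid != "t3" else "sp_b",
                    "plot": 0,
                    "x": 1.0,
                    "y": float(len(rows)),
                    "date": 2000.0 + 2.0 * k,
                    "dbh_mm": d0 + inc * 2.0 * k,
                }
            )
    return pd.DataFrame(rows)
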