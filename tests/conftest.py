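"""Shared fixtures: a small reference tree with R-verified values, and the
default synthetic world (session-scoped — several suites analyse it)."""

import numpy as np
import pandas as pd
import pytest

from phylospat.grids import GridSpec
from phylospat.diversity import diversity_table
from phylospat.env_layers import cell_predictors
from phylospat.occurrences import assign_cells, build_presence, clean_records, retained
from phylospat.phylo import load_tree
from phylospat.synthetic import WorldConfig, generate_world

#: 7-tip reference tree used for the frozen comparative-method oracle values
REF_NEWICK = "((A:1.0,B:2.0):1.5,((C:0.8,D:1.2):0.6,(E:2.2,(F:0.9,G:1.1):0.7):0.4):1.3);"
REF_TRAIT = {"A": 3.1, "B": 1.2, "C": 4.5, "D": 5.0, "E": 0.3, "F": 2.2, "G": 2.9}


@pytest.fixture
def ref_tree():
    return load_tree(REF_NEWICK)


@pytest.fixture
def ref_trait():
    return pd.Series(REF_TRAIT)


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world (fixed seed 0): the package's study system."""
    return generate_world(WorldConfig())


@pytest.fixture(scope="session")
def world_cell_table(default_world):
    """Per-cell diversity + predictors of the default world, 1-degree grid."""
    w = default_world
    kept = retained(clean_records(w.records))
    grid = GridSpec(1.0)
    P = build_presence(assign_cells(kept, grid), grid)
    div = diversity_table(P, grid)
    env = cell_predictors(w.altitude, w.climate["mat"], w.climate["map"],
                          w.climate["lgm_mat"], w.climate["lgm_map"], grid)
    table = div.merge(env, on="cell_id").dropna()
    return {"presence": P, "table": table, "grid": grid, "kept": kept}


@pytest.fixture
def small_world_config():
    """A fast, small world for pipeline-level tests."""
    return WorldConfig(extent=(80.0, 100.0, 20.0, 40.0),
                       plateau_box=(84.0, 96.0, 25.0, 35.0),
                       n_species=15, n_tips=15, records_per_species=40, seed=1)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
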