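"""Shared fixtures: one default synthetic scenario reused across the suite.

The heavy artifacts (fleet simulation, cleaned/labelled learning set, the
20-repeat cross-validation) are session-scoped so each is computed once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from driftstate.classify import cross_validate
from driftstate.features import compute_track_features
from driftstate.labeling import MatchConfig, build_learning_set
from driftstate.preprocess import clean
from driftstate.synthetic import (
    ScenarioConfig,
    generate_world,
    inject_artifacts,
    simulate_fleet,
)

SEED = 11


@pytest.fixture(scope="session")
def scenario() -> ScenarioConfig:
    return ScenarioConfig(seed=SEED)


@pytest.fixture(scope="session")
def world(scenario):
    return generate_world(scenario)


@pytest.fixture(scope="session")
def fleet(world, scenario):
    return simulate_fleet(world, scenario)


@pytest.fixture(scope="session")
def raw_positions(fleet, scenario) -> pd.DataFrame:
    return inject_artifacts(fleet.buoys, scenario)


@pytest.fixture(scope="session")
def cleaned(raw_positions) -> pd.DataFrame:
    return clean(raw_positions.drop(columns=["state"]))


@pytest.fixture(scope="session")
def features_table(cleaned, world) -> pd.DataFrame:
    return compute_track_features(cleaned, world.port_array)


@pytest.fixture(scope="session")
def learning_set(features_table, fleet, world) -> pd.DataFrame:
    return build_learning_set(features_table, fleet.vms, world.port_array, MatchConfig())


@pytest.fixture(scope="session")
def cv20(learning_set):
    """20-repeat, 4-method cross-validation on the default scenario."""
    return cross_validate(learning_set, n_repeats=20, seed=SEED, keep_predictions=True)


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """Light scenario for structural tests that do not need the full fleet."""
    return ScenarioConfig(n_vessels=2, n_buoys=6, horizon_days=30, seed=5)


@pytest.fixture(scope="session")
def small_fleet(small_scenario):
    return simulate_fleet(generate_world(small_scenario), small_scenario)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
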