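"""Shared fixtures: small synthetic study systems built once per session."""

import numpy as np
import pytest

from locustlens.augment import assemble_dataset, attack_calendar, generate_negatives
from locustlens.fusion import build_positive_rows
from locustlens.simulate import (
    SimulationConfig,
    make_atlas,
    make_climate,
    simulate_events,
    two_country_config,
)


@pytest.fixture(scope="session")
def small_config():
    # default desk scale: 3 countries x 2 regions, 4 years
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def small_system(small_config):
    atlas = make_atlas(small_config)
    grid = make_climate(small_config, atlas)
    events = simulate_events(small_config, atlas, grid)
    return small_config, atlas, grid, events


@pytest.fixture(scope="session")
def small_dataset(small_system):
    config, atlas, grid, events = small_system
    positives = build_positive_rows(events, grid, atlas)
    negatives = generate_negatives(
        attack_calendar(positives), atlas, grid, config.year_span
    )
    return assemble_dataset(positives, negatives)


@pytest.fixture(scope="session")
def two_country_dataset():
    config = two_country_config(seed=42)
    atlas = make_atlas(config)
    grid = make_climate(config, atlas)
    events = simulate_events(config, atlas, grid)
    positives = build_positive_rows(events, grid, atlas)
    negatives = generate_negatives(
        attack_calendar(positives), atlas, grid, config.year_span
    )
    return assemble_dataset(positives, negatives)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
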