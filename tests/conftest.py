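"""Shared fixtures: the documented synthetic cohort and derived artifacts.

Session scope keeps the expensive pieces (region calling with 1000
permutations) computed once per run.
"""

import pytest

from conexic.aberrations import AberrationConfig, call_regions
from conexic.simulate import (
    SimulationConfig,
    default_fixture,
    default_fixture_annotation,
    generate_dataset,
)

#: A small cohort for fast unit tests (valid config, two planted regions).
SMALL_CONFIG = SimulationConfig(
    n_samples=40,
    n_genes=400,
    n_gain_regions=1,
    n_loss_regions=1,
    region_width=8,
    module_size=20,
    seed=7,
)


@pytest.fixture(scope="session")
def fixture_data():
    return default_fixture()


@pytest.fixture(scope="session")
def fixture_annotation():
    return default_fixture_annotation()


@pytest.fixture(scope="session")
def fixture_regions(fixture_data, fixture_annotation):
    cn = fixture_data[0]
    return call_regions(cn, fixture_annotation, AberrationConfig(seed=1))


@pytest.fixture(scope="session")
def small_data():
    return generate_dataset(SMALL_CONFIG)
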