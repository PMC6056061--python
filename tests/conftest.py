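import numpy as np
import pytest

from dynsub import (
    StudyDesign,
    assemble_configuration,
    build_signed_networks,
    normalize_configuration,
)
from dynsub.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(
        n_subjects=4,
        tasks=("alpha",),
        conditions=("fixation", "low", "high"),
        blocks_per_condition=2,
        samples_per_block=30,
        n_regions=20,
        n_systems=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_cohort(small_design, n_subgraphs=2, seed=3,
                           behavior_effect=40.0)


@pytest.fixture(scope="session")
def small_config(small_cohort):
    networks = build_signed_networks(small_cohort.series)
    return assemble_configuration(
        networks,
        task_order=list(small_cohort.design.tasks),
        condition_order=list(small_cohort.design.conditions),
    )


@pytest.fixture(scope="session")
def small_config_normalized(small_config):
    return normalize_configuration(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
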