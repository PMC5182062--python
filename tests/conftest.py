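"""Shared fixtures: one medium synthetic genome reused across the suite."""

import numpy as np
import pytest

from micmac import pipeline
from micmac.simulate import SimConfig


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=3)


@pytest.fixture(scope="session")
def genomes(sim_config):
    """(mic, mac, truth) for the default study conditions, zero jitter."""
    return pipeline.simulate_genomes(sim_config)


@pytest.fixture(scope="session")
def ies_run(genomes, sim_config):
    mic, mac, truth = genomes
    return pipeline.run_ies_detection(mic, mac, truth, sim_config)


@pytest.fixture(scope="session")
def toy_config() -> SimConfig:
    """A <10 kb single-chromosome world for brute-force oracle checks."""
    return SimConfig(seed=5, n_chromosomes=1, chromosome_length=6000,
                     n_cbs_per_chromosome=1, n_ies=3,
                     ies_length_lognormal=(420.0, 380.0),
                     n_tandem_dup_cbs=0, n_longrange_dup_cbs=0,
                     coverage=15.0, read_length=150)


@pytest.fixture(scope="session")
def toy_genomes(toy_config):
    return pipeline.simulate_genomes(toy_config)
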