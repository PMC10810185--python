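"""Shared fixtures: one small synthetic experiment reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from xrquant.read_processing import GenomeIndex
from xrquant.synthetic_data import (SimulationParams, make_genes, make_genome,
                                    simulate_library)


@pytest.fixture(scope="session")
def std_params() -> SimulationParams:
    return SimulationParams(seed=0)


@pytest.fixture(scope="session")
def std_genome(std_params):
    return make_genome(std_params)


@pytest.fixture(scope="session")
def std_genes(std_params, std_genome):
    return make_genes(std_genome, std_params)


@pytest.fixture(scope="session")
def std_library(std_params, std_genome, std_genes):
    return simulate_library(std_genome, std_genes, std_params, sample_id="wt")


@pytest.fixture(scope="session")
def std_index(std_genome):
    return GenomeIndex(std_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
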