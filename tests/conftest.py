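"""Shared fixtures: small simulated datasets and layouts, reused across
tests (session-scoped where regeneration would dominate runtime)."""

import numpy as np
import pytest

from domcost import simdata
from domcost.simdata.config import DemographyTruth, Epoch, SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Two small populations with a mild bottleneck; fast to simulate."""
    dem = DemographyTruth(
        N_anc=120.0,
        t_split=30.0,
        epochs1=(Epoch(30.0, 0.0, 120.0, 120.0),),
        epochs2=(Epoch(30.0, 15.0, 120.0, 40.0), Epoch(15.0, 0.0, 40.0, 100.0)),
        m12=0.001,
        m21=0.002,
    )
    return SimulationConfig(
        contig_length_bp=120_000,
        mu=2e-6,
        rec_rate=1e-6,
        dfe_mean_s=0.02,
        demography=dem,
        sample_sizes=(8, 8),
        n_outgroup=3,
        outgroup_divergence=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simdata.simulate_two_population(small_config)


@pytest.fixture(scope="session")
def small_layout(small_dataset):
    return small_dataset.layout


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
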