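import numpy as np
import pandas as pd
import pytest

from elevdiv.core_data import AsvTable, SampleMeta
from elevdiv.synthetic import SimulationConfig, simulate_community


@pytest.fixture
def toy_table() -> AsvTable:
    counts = pd.DataFrame(
        [[5, 3, 0, 2], [1, 0, 4, 4], [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3", "a4"],
    )
    tax = pd.Series(
        ["Eukaryota;Alveolata;Ciliophora", "Eukaryota;Opisthokonta;Metazoa;Arthropoda",
         "Eukaryota;Rhizaria;Cercozoa", "Eukaryota;Archaeplastida;Streptophyta"],
        index=counts.columns,
    )
    return AsvTable(counts, tax)


@pytest.fixture
def toy_meta() -> SampleMeta:
    frame = pd.DataFrame(
        {"elevation_m": [500.0, 900.0, 1600.0], "band_id": ["B500", "B900", "B1600"]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return SampleMeta(frame)


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic dataset shared across tests."""
    return simulate_community(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """A reduced design (4 bands, 2 replicated) for fast structural tests."""
    return SimulationConfig(
        band_elevations_m=(400, 900, 1500, 2000),
        replicated_bands=(900, 2000),
        n_replicates=3,
        n_species_pool=900,
        richness_intercept=160,
        richness_slope=-0.05,
    )
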