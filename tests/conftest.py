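import numpy as np
import pytest

from sexchrom.simulate import SimulationConfig, simulate_trio


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size simulated trio shared across the suite."""
    return simulate_trio(SimulationConfig(seed=11))


@pytest.fixture()
def small_config():
    """A scaled-down layout for tests that re-simulate repeatedly."""
    return SimulationConfig(
        seed=5,
        autosome_lengths={"A1": 60_000, "A2": 50_000},
        slr_layout={
            "PAR1": (0, 10_000),
            "oldSLR": (10_000, 60_000),
            "newSLR": (60_000, 110_000),
            "PAR2": (110_000, 120_000),
        },
        genes_per_region={"PAR1": 12, "oldSLR": 200, "newSLR": 80, "PAR2": 12},
        genes_per_autosome={"A1": 40, "A2": 30},
        n_sexlinked_sites=20,
        n_autosomal_sites=80,
        nonsyntenic_counts={"oldSLR": (30, 3), "autosome": (10, 10)},
        inversions={"newSLR": (2, 0.3), "A1": (1, 0.1)},
        n_coverage_windows=100,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
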