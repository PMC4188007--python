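import numpy as np
import pytest
from hypothesis import settings

from mxindex import UnitCell, default_experiment, random_crystal
from mxindex.simulate import SimulationSpec, simulate_multi_lattice

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cubic_cell():
    return UnitCell(100.0, 100.0, 100.0)


@pytest.fixture(scope="session")
def ortho_cell():
    # trypsin-like orthorhombic cell
    return UnitCell(54.7, 58.5, 67.5)


@pytest.fixture(scope="session")
def wedge_experiment():
    """1 degree wedge of 0.1 degree frames, narrow-wedge defaults."""
    return default_experiment(n_frames=10)


@pytest.fixture(scope="session")
def single_lattice_sim(cubic_cell, wedge_experiment):
    """Noise-free single-lattice simulation over 1 degree."""
    rng = np.random.default_rng(101)
    crystal = random_crystal(cubic_cell, rng)
    spec = SimulationSpec(
        crystals=[crystal],
        geometry=wedge_experiment,
        d_min=4.0,
        noise_sd=(0.0, 0.0, 0.0),
        seed=101,
    )
    table, truth = simulate_multi_lattice(spec)
    return table, truth, wedge_experiment


@pytest.fixture(scope="session")
def six_lattice_sim(cubic_cell, wedge_experiment):
    """Six-lattice 1 degree simulation with 0.3 px centroid noise."""
    rng = np.random.default_rng(202)
    truth = [random_crystal(cubic_cell, rng) for _ in range(6)]
    spec = SimulationSpec(
        crystals=truth,
        geometry=wedge_experiment,
        d_min=4.0,
        noise_sd=(0.3, 0.3, 0.3),
        seed=202,
    )
    table, _ = simulate_multi_lattice(spec)
    return table, truth, wedge_experiment
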