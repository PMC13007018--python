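import numpy as np
import pytest

from qeqnn.descriptors import water_symmetry_functions, fit_scaling
from qeqnn.electrostatics import QeqParameters
from qeqnn.model import ConfigRecord, FourthGenCommittee, TrainingConfig
from qeqnn.oracle import SystemRecipe, build_system, generate_pool, label


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def water_molecule():
    """Gas-phase water at the oracle's internal equilibrium geometry."""
    cfg = build_system(SystemRecipe(kind="bulk", n_molecules=1, cell=(30, 30, 30), seed=0))
    cfg.pbc = np.zeros(3, dtype=bool)
    cfg.cell = None
    return cfg


@pytest.fixture
def water_box8():
    """Periodic 8-molecule bulk box at 0.997 g/cm^3."""
    return build_system(SystemRecipe(kind="bulk", n_molecules=8, seed=3))


@pytest.fixture
def perturbed_box8(water_box8, rng):
    return water_box8.with_positions(
        water_box8.positions + rng.normal(0, 0.04, water_box8.positions.shape)
    )


@pytest.fixture(scope="session")
def compact_sf():
    return water_symmetry_functions("compact")


@pytest.fixture(scope="session")
def tiny_dataset():
    """40 labeled 4-molecule configurations (thermal-scale displacements)."""
    pool = generate_pool(
        SystemRecipe(n_molecules=4, seed=0), 40, amplitude_range=(0.02, 0.08)
    )
    return [label(c) for c in pool]


@pytest.fixture(scope="session")
def quick_committee(tiny_dataset):
    """A small trained committee shared across tests (2 members, short fit)."""
    sf = water_symmetry_functions("compact")
    qeq = QeqParameters()
    committee = FourthGenCommittee.create(sf, qeq, n=2, seed=9)
    fit_scaling(tiny_dataset[:30], sf)
    records = [ConfigRecord(l.configuration, sf, qeq) for l in tiny_dataset[:30]]
    committee.train(
        tiny_dataset[:30],
        TrainingConfig(epochs_elec=20, epochs_short=25),
        records=records,
    )
    return committee
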