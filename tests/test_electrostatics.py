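import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize

from qeqnn.core_types import AtomicConfiguration
from qeqnn.electrostatics import (
    EwaldSystem,
    QeqParameters,
    build_A_matrix,
    electrostatic_energy,
    electrostatic_forces,
    pair_screened_energy,
    self_energy,
    solve_constrained,
    solve_qeq,
)
from qeqnn.oracle import SystemRecipe, build_system
from qeqnn.units import KE


def test_pair_screened_limits():
    # point-charge limit: tiny widths, 1 A separation
    assert pair_screened_energy(1.0, 1.0, 1.0, 1e-4, 1e-4) == pytest.approx(
        14.399645, abs=1e-6
    )
    assert pair_screened_energy(0.0, 1.0, 0.7, 0.5, 0.5) == 0.0
    gamma = math.sqrt(0.5**2 + 0.5**2)
    r = 10.0 * gamma
    assert pair_screened_energy(1.0, -1.0, r, 0.5, 0.5) == pytest.approx(
        -KE / r, rel=1e-6
    )
    with pytest.raises(ValueError):
        pair_screened_energy(1.0, 1.0, 0.0, 0.5, 0.5)


def test_self_energy_quadratic():
    assert self_energy(0.0, 0.5) == 0.0
    assert self_energy(2.0, 0.7) == pytest.approx(4.0 * self_energy(1.0, 0.7))
    assert self_energy(1.0, 1.0) == pytest.approx(KE / (2.0 * math.sqrt(math.pi)))


def test_single_atom_matrix_open_boundary():
    cfg = AtomicConfiguration(species=["O"], positions=[[0, 0, 0]])
    p = QeqParameters()
    A = build_A_matrix(cfg, p)
    expected = p.hardness["O"] + KE / (math.sqrt(math.pi) * p.sigma["O"])
    assert A.shape == (1, 1)
    assert A[0, 0] == pytest.approx(expected)


def test_ewald_splitting_independence(water_box8, rng):
    q = rng.normal(size=24)
    q -= q.mean()
    e = [
        electrostatic_energy(water_box8, q, QeqParameters(ewald_eta=eta))
        for eta in (0.5, 1.0)
    ]
    assert abs(e[0] - e[1]) < 1e-6
    # forces too (fixed chi, so the response term is geometric only)
    chi = rng.normal(size=24)
    forces = []
    for eta in (0.5, 1.0):
        p = QeqParameters(ewald_eta=eta)
        sysm = EwaldSystem(water_box8, p, gradients=True)
        sol = sysm.solve(chi, 0.0)
        forces.append(electrostatic_forces(water_box8, sol, None, p, sysm))
    assert np.max(np.abs(forces[0] - forces[1])) < 1e-6


def _evjen_madelung(shells=8):
    """Direct rock-salt lattice sum with Evjen fractional surface weights."""
    s = 0.0
    n = shells
    for i, j, k in itertools.product(range(-n, n + 1), repeat=3):
        if i == j == k == 0:
            continue
        w = 1.0
        for c in (i, j, k):
            if abs(c) == n:
                w *= 0.5
        s += w * (-1.0) ** (i + j + k) / math.sqrt(i * i + j * j + k * k)
    return -s


def test_madelung_energy_rock_salt():
    a = 2.0  # nearest-neighbor distance 1 A
    na = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
    cl = [(0.5, 0, 0), (0, 0.5, 0), (0, 0, 0.5), (0.5, 0.5, 0.5)]
    pos = np.array([np.array(b) * a for b in na + cl])
    cfg = AtomicConfiguration(
        species=["Na"] * 4 + ["Cl"] * 4,
        positions=pos,
        cell=np.eye(3) * a,
        pbc=[True] * 3,
    )
    p = QeqParameters(
        hardness={"Na": 10.0, "Cl": 10.0}, sigma={"Na": 0.01, "Cl": 0.01}
    )
    q = np.array([1.0] * 4 + [-1.0] * 4)
    system = EwaldSystem(cfg, p)
    e_int = system.energy(q) - sum(self_energy(qi, 0.01) for qi in q)
    per_pair = e_int / 4.0
    madelung = _evjen_madelung(8)
    assert madelung == pytest.approx(1.7475646, abs=1e-4)  # oracle sanity
    assert per_pair == pytest.approx(-KE * madelung / 1.0, rel=1e-3)


def test_two_site_closed_form():
    # decoupled sites: A = diag(J), J1 = J2 = 1
    sol = solve_constrained(np.diag([1.0, 1.0]), np.array([-1.0, 1.0]), 0.0)
    assert sol.charges == pytest.approx([1.0, -1.0])
    # the lower-chi atom carries the positive charge
    assert sol.charges[0] == pytest.approx((1.0 - (-1.0)) / (1.0 + 1.0))


def test_symmetric_system_equal_charges():
    cfg = AtomicConfiguration(
        species=["H"] * 4,
        positions=[[0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0]],
        total_charge=1.0,
    )
    sol = solve_qeq(cfg, np.full(4, 0.7), QeqParameters())
    assert np.max(np.abs(sol.charges - 0.25)) < 1e-10
    assert sol.charges.sum() == pytest.approx(1.0, abs=1e-10)


def test_qeq_matches_numerical_minimizer(rng):
    cfg = build_system(SystemRecipe(n_molecules=8, seed=2))
    cluster = AtomicConfiguration(
        species=cfg.species, positions=cfg.positions, total_charge=0.0
    )  # open boundary 8-water cluster
    p = QeqParameters()
    chi = rng.normal(scale=2.0, size=24)
    system = EwaldSystem(cluster, p)
    sol = system.solve(chi, 0.0)

    A = system.A

    def objective(qfree):
        q = np.concatenate([qfree, [0.0 - qfree.sum()]])  # charge-conserving chart
        return 0.5 * q @ A @ q + chi @ q

    res = minimize(
        objective,
        np.zeros(23),
        method="L-BFGS-B",
        options={"ftol": 1e-18, "gtol": 1e-12, "maxiter": 5000},
    )
    q_num = np.concatenate([res.x, [-res.x.sum()]])
    assert np.max(np.abs(q_num - sol.charges)) < 1e-8
    # linear-solve energy is at least as low
    assert sol.e_qeq <= objective(res.x) + 1e-10


def test_chi_shift_absorbed_by_multiplier(water_box8, rng):
    p = QeqParameters()
    system = EwaldSystem(water_box8, p)
    chi = rng.normal(size=24)
    s0 = system.solve(chi, 0.0)
    s1 = system.solve(chi + 5.0, 0.0)
    assert np.max(np.abs(s0.charges - s1.charges)) < 1e-9
    assert s1.multiplier == pytest.approx(s0.multiplier - 5.0, abs=1e-8)


def test_energy_compositions(rng):
    cfg = AtomicConfiguration(
        species=["O", "H"], positions=[[0, 0, 0], [3, 0, 0]]
    )
    p = QeqParameters(sigma={"O": 0.5, "H": 0.5})
    assert electrostatic_energy(cfg, np.zeros(2), p) == 0.0
    e = electrostatic_energy(cfg, np.array([1.0, -1.0]), p)
    expected = (
        pair_screened_energy(1.0, -1.0, 3.0, 0.5, 0.5)
        + self_energy(1.0, 0.5)
        + self_energy(-1.0, 0.5)
    )
    assert e == pytest.approx(expected, abs=1e-12)


def _project_neutral_dipole_free(q, pos):
    """Remove net charge and net dipole (the Ewald tin-foil surface term)."""
    basis = np.column_stack([np.ones(len(q)), pos - pos.mean(0)])
    coef, *_ = np.linalg.lstsq(basis, q, rcond=None)
    return q - basis @ coef


def test_periodic_matches_padded_open_cell(rng):
    # a compact neutral, dipole-free cluster in a huge periodic box
    # approaches open boundaries (the residual is quadrupole-order in 1/L)
    cfg = build_system(SystemRecipe(n_molecules=2, cell=(7, 7, 7), seed=4))
    q = _project_neutral_dipole_free(rng.normal(size=6), cfg.positions)
    pos = cfg.positions - cfg.positions.mean(0) + 40.0
    p = QeqParameters()
    big = AtomicConfiguration(
        species=cfg.species, positions=pos, cell=np.eye(3) * 80.0, pbc=[True] * 3
    )
    open_cfg = AtomicConfiguration(species=cfg.species, positions=pos)
    e_per = electrostatic_energy(big, q, p)
    e_open = electrostatic_energy(open_cfg, q, p)
    assert abs(e_per - e_open) < 1e-4


def test_force_symmetry_and_conservation(rng):
    cfg = AtomicConfiguration(
        species=["H", "H"], positions=[[0, 0, 0], [1.5, 0, 0]]
    )
    p = QeqParameters(hardness={"H": 14.7}, sigma={"H": 0.31})
    system = EwaldSystem(cfg, p, gradients=True)
    sol = system.solve(np.array([0.3, 0.3]), 1.0)
    F = electrostatic_forces(cfg, sol, None, p, system)
    assert np.allclose(F[0], -F[1], atol=1e-12)
    assert abs(F[0, 1]) < 1e-12 and abs(F[0, 2]) < 1e-12  # along the bond
    cfg2 = build_system(SystemRecipe(n_molecules=4, cell=(9, 9, 9), seed=6))
    p2 = QeqParameters()
    system2 = EwaldSystem(cfg2, p2, gradients=True)
    sol2 = system2.solve(rng.normal(size=12), 0.0)
    F2 = electrostatic_forces(cfg2, sol2, None, p2, system2)
    assert np.max(np.abs(F2.sum(axis=0))) < 1e-8


def test_forces_match_finite_differences(rng):
    cfg = build_system(SystemRecipe(n_molecules=4, cell=(8.5, 8.5, 8.5), seed=8))
    cluster = AtomicConfiguration(species=cfg.species, positions=cfg.positions)
    p = QeqParameters()
    chi = rng.normal(size=12)
    system = EwaldSystem(cluster, p, gradients=True)
    sol = system.solve(chi, 0.0)
    F = electrostatic_forces(cluster, sol, None, p, system)
    h = 1e-4
    for a, c in [(0, 0), (3, 1), (5, 2), (11, 0), (7, 1)]:
        es = []
        for sgn in (1, -1):
            pos = cluster.positions.copy()
            pos[a, c] += sgn * h
            s2 = EwaldSystem(cluster.with_positions(pos), p)
            es.append(s2.solve(chi, 0.0).e_elec)
        fd = -(es[0] - es[1]) / (2 * h)
        assert abs(fd - F[a, c]) < 1e-5


def test_convexity_on_neutral_subspace(water_box8):
    A = build_A_matrix(water_box8, QeqParameters())
    n = 24
    P = np.eye(n) - np.ones((n, n)) / n
    eig = np.linalg.eigvalsh(P @ A @ P)
    assert eig[1] > 0  # all but the projector null direction positive


def test_energy_extensivity_two_replicas(rng):
    cfg = build_system(SystemRecipe(n_molecules=2, cell=(7, 7, 7), seed=9))
    q = _project_neutral_dipole_free(rng.normal(size=6), cfg.positions)
    pos = cfg.positions - cfg.positions.mean(0)
    p = QeqParameters()
    one = AtomicConfiguration(species=cfg.species, positions=pos + 30.0,
                              cell=np.eye(3) * 60.0, pbc=[True] * 3)
    two = AtomicConfiguration(
        species=np.concatenate([cfg.species, cfg.species]),
        positions=np.vstack([pos + 15.0, pos + 45.0]),
        cell=np.eye(3) * 60.0,
        pbc=[True] * 3,
    )
    e1 = electrostatic_energy(one, q, p)
    e2 = electrostatic_energy(two, np.concatenate([q, q]), p)
    assert e2 == pytest.approx(2 * e1, abs=1e-4)
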