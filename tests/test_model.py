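import numpy as np
import pytest

from qeqnn.core_types import AtomicConfiguration
from qeqnn.descriptors import fit_scaling, water_symmetry_functions
from qeqnn.electrostatics import QeqParameters
from qeqnn.model import (
    CommitteePrediction,
    FourthGenCommittee,
    FourthGenModel,
    TrainingConfig,
    committee_predict,
    load_committee,
    save_committee,
    second_gen_mode,
    train_electrostatic,
    train_short_range,
)


def test_charge_sum_constraint(quick_committee, perturbed_box8):
    for m in quick_committee.members:
        sol = m.predict_charges(perturbed_box8)
        assert sol.charges.sum() == pytest.approx(0.0, abs=1e-10)


def test_symmetric_molecule_equal_charges(quick_committee, water_molecule):
    model = quick_committee.members[0]
    sol = model.predict_charges(water_molecule)
    assert sol.charges[1] == pytest.approx(sol.charges[2], abs=1e-10)


def test_forces_match_finite_differences(quick_committee, tiny_dataset):
    """Analytic 4G forces (descriptor chain + dQ/dR adjoint) vs central FD."""
    model = quick_committee.members[0]
    cfg = tiny_dataset[32].configuration
    E, F, _ = model.predict_energy_forces(cfg)
    h = 1e-4
    for a, c in [(0, 0), (2, 1), (5, 2), (8, 0), (11, 1)]:
        es = []
        for sgn in (1, -1):
            pos = cfg.positions.copy()
            pos[a, c] += sgn * h
            es.append(model.predict_energy_forces(cfg.with_positions(pos))[0])
        fd = -(es[0] - es[1]) / (2 * h)
        assert abs(fd - F[a, c]) < 1e-5
    assert np.max(np.abs(F.sum(axis=0))) < 1e-8


def test_translation_invariance(quick_committee, tiny_dataset):
    model = quick_committee.members[0]
    cfg = tiny_dataset[31].configuration
    E0, F0, _ = model.predict_energy_forces(cfg)
    shifted = cfg.with_positions(cfg.positions + np.array([0.8, -0.4, 1.1]))
    E1, F1, _ = model.predict_energy_forces(shifted)
    assert E1 == pytest.approx(E0, abs=1e-8)
    assert np.max(np.abs(F1 - F0)) < 1e-8


def test_like_atom_permutation_invariance(quick_committee, tiny_dataset):
    model = quick_committee.members[0]
    cfg = tiny_dataset[30].configuration
    E0, F0, sol0 = model.predict_energy_forces(cfg)
    perm = np.arange(cfg.n_atoms)
    perm[[0, 1, 2, 6, 7, 8]] = [6, 7, 8, 0, 1, 2]  # swap two molecules
    permuted = AtomicConfiguration(
        species=cfg.species[perm],
        positions=cfg.positions[perm],
        cell=cfg.cell,
        pbc=cfg.pbc,
    )
    E1, F1, sol1 = model.predict_energy_forces(permuted)
    assert E1 == pytest.approx(E0, abs=1e-9)
    assert np.max(np.abs(F1 - F0[perm])) < 1e-9
    assert np.max(np.abs(sol1.charges - sol0.charges[perm])) < 1e-10


def test_rotational_covariance_of_forces(quick_committee, water_molecule):
    model = quick_committee.members[0]
    th = 1.1
    R = np.array(
        [[np.cos(th), 0, np.sin(th)], [0, 1, 0], [-np.sin(th), 0, np.cos(th)]]
    )
    E0, F0, _ = model.predict_energy_forces(water_molecule)
    rotated = water_molecule.with_positions(water_molecule.positions @ R.T)
    E1, F1, _ = model.predict_energy_forces(rotated)
    assert E1 == pytest.approx(E0, abs=1e-8)
    assert np.max(np.abs(F1 - F0 @ R.T)) < 1e-8


def test_stage_order_enforced(tiny_dataset):
    sf = water_symmetry_functions("compact")
    model = FourthGenModel.create(sf, QeqParameters(), seed=3)
    with pytest.raises(RuntimeError):
        train_short_range(model, tiny_dataset[:5], TrainingConfig())


def test_single_config_overfit_and_report_definition(tiny_dataset):
    sf = water_symmetry_functions("compact")
    model = FourthGenModel.create(sf, QeqParameters(), seed=1)
    one = tiny_dataset[:1]
    fit_scaling(tiny_dataset[:10], sf)
    tc = TrainingConfig(epochs_elec=40, epochs_short=40, force_weight=1.0)
    rep1 = train_electrostatic(model, one, tc)
    assert rep1["train_charge_rmse_me"] < 1.0  # capacity check on one config
    # report matches the definition sqrt(mean(dQ^2))
    sol = model.predict_charges(one[0].configuration)
    rmse = np.sqrt(np.mean((sol.charges - one[0].charges) ** 2)) * 1000
    assert rep1["train_charge_rmse_me"] == pytest.approx(rmse, rel=1e-6)
    rep2 = train_short_range(model, one, tc)
    assert rep2["train_energy_rmse_mev_per_atom"] < 5.0


def test_energy_only_training_path(tiny_dataset):
    sf = water_symmetry_functions("compact")
    model = FourthGenModel.create(sf, QeqParameters(), seed=2)
    fit_scaling(tiny_dataset[:10], sf)
    tc = TrainingConfig(epochs_elec=10, epochs_short=10, force_weight=0.0)
    train_electrostatic(model, tiny_dataset[:10], tc)
    rep = train_short_range(model, tiny_dataset[:10], tc)
    assert np.isfinite(rep["train_energy_rmse_mev_per_atom"])


def test_committee_mean_and_disagreement(quick_committee, perturbed_box8):
    pred = committee_predict(quick_committee, perturbed_box8)
    assert pred.energy == pytest.approx(pred.member_energies.mean())
    assert np.all(pred.sigma_f >= 0)
    # closed form for n = 2: sigma = |f1 - f2| / 2 per atom
    dev = 0.5 * np.linalg.norm(pred.member_forces[0] - pred.member_forces[1], axis=1)
    assert np.allclose(pred.sigma_f, dev, atol=1e-12)


def test_single_member_committee_zero_disagreement(tiny_dataset, quick_committee):
    lone = FourthGenCommittee(members=[quick_committee.members[0]])
    pred = lone.predict(tiny_dataset[0].configuration)
    assert np.all(pred.sigma_f == 0.0)


def test_two_member_mirror_forces_closed_form():
    f = np.array([[0.3, -0.4, 1.2]])
    pred = CommitteePrediction(
        energy=0.0,
        forces=np.zeros((1, 3)),
        charges=np.zeros(1),
        sigma_f=np.sqrt(np.mean(np.sum((np.array([f, -f]) - 0.0) ** 2, axis=2), axis=0)),
        member_energies=np.zeros(2),
        member_forces=np.array([f, -f]),
    )
    assert pred.sigma_f[0] == pytest.approx(np.linalg.norm(f))


def test_second_gen_mode_fixed_charges(tiny_dataset):
    sf = water_symmetry_functions("compact")
    committee = FourthGenCommittee.create(
        sf, QeqParameters(), n=2, seed=4, fourth_gen=False
    )
    fit_scaling(tiny_dataset[:15], sf)
    committee.train(tiny_dataset[:15], TrainingConfig(epochs_elec=5, epochs_short=15))
    cfg = tiny_dataset[0].configuration
    spc = {"O": -0.82, "H": 0.41}
    tip4p = {"O": -1.1128, "H": 0.5564}
    e1, f1, q1 = second_gen_mode(committee, spc, cfg)
    e2, f2, q2 = second_gen_mode(committee, tip4p, cfg)
    assert np.allclose(q1[::3], -0.82) and np.allclose(q1[1::3], 0.41)
    assert q1[0] + 2 * q1[1] == pytest.approx(0.0)
    # charges decouple from energetics: same forces, different dipoles
    assert e1 == e2 and np.array_equal(f1, f2)
    assert not np.allclose(q1, q2)
    with pytest.raises(KeyError):
        second_gen_mode(committee, {"O": -0.8}, cfg)


def test_second_gen_mode_requires_2g_committee(quick_committee, tiny_dataset):
    with pytest.raises(ValueError):
        second_gen_mode(
            quick_committee, {"O": -0.82, "H": 0.41}, tiny_dataset[0].configuration
        )


def test_committee_archive_round_trip(tmp_path, quick_committee, perturbed_box8):
    save_committee(quick_committee, tmp_path / "arch")
    back = load_committee(tmp_path / "arch")
    p0 = quick_committee.predict(perturbed_box8)
    p1 = back.predict(perturbed_box8)
    assert p1.energy == pytest.approx(p0.energy, abs=1e-10)
    assert np.max(np.abs(p1.forces - p0.forces)) < 1e-10
    assert np.max(np.abs(p1.charges - p0.charges)) < 1e-12


def test_missing_element_rejected(quick_committee):
    cfg = AtomicConfiguration(species=["N"], positions=[[0, 0, 0]])
    with pytest.raises(KeyError):
        quick_committee.members[0].predict_charges(cfg)
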