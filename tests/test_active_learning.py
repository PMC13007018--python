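import numpy as np
import pytest

from qeqnn.active_learning import (
    ALConfig,
    BiasParameters,
    CandidatePool,
    al_round,
    bias_energy_forces,
    config_disagreement,
    farthest_point_select,
    generation_protocol,
    pool_features,
    run_active_learning,
)
from qeqnn.model import CommitteePrediction, FourthGenCommittee
from qeqnn.oracle import SystemRecipe, build_system, generate_pool, label


class StubCommittee:
    """Duck-typed committee with prescribed member forces (for closed forms)."""

    def __init__(self, member_forces):
        self.member_forces = np.asarray(member_forces, dtype=float)
        self.n = len(self.member_forces)

    def predict(self, config):
        forces = self.member_forces
        fbar = forces.mean(axis=0)
        dev = forces - fbar
        sigma = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
        return CommitteePrediction(
            energy=0.0,
            forces=fbar,
            charges=np.zeros(forces.shape[1]),
            sigma_f=sigma,
            member_energies=np.zeros(self.n),
            member_forces=forces,
        )


def test_fps_all_and_guards():
    X = np.array([[0.0], [1.0], [2.0]])
    assert sorted(farthest_point_select(X, 3)) == [0, 1, 2]
    with pytest.raises(ValueError):
        farthest_point_select(X, 4)


def test_fps_collinear_endpoints():
    X = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
    picked = farthest_point_select(X, 2)
    assert sorted(picked) == [0, 2]


def test_fps_duplicates_ranked_last():
    X = np.array([[0.0], [0.0], [5.0], [2.5]])
    picked = farthest_point_select(X, 3)
    assert not ({0, 1} <= set(picked))  # never both duplicates before distinct items


def test_disagreement_aggregations_closed_form():
    # two atoms with sigma_F = (1, 3): max -> 3, mean -> 2
    f = np.zeros((2, 2, 3))
    f[0, 0, 0] = 1.0
    f[1, 0, 0] = -1.0
    f[0, 1, 0] = 3.0
    f[1, 1, 0] = -3.0
    stub = StubCommittee(f)
    assert config_disagreement(stub, None, "max") == pytest.approx(3.0)
    assert config_disagreement(stub, None, "mean") == pytest.approx(2.0)
    with pytest.raises(ValueError):
        config_disagreement(StubCommittee(f[:1]), None)
    with pytest.raises(ValueError):
        config_disagreement(stub, None, "median")


def test_disagreement_identical_members_and_permutation():
    f = np.random.default_rng(0).normal(size=(1, 4, 3))
    same = StubCommittee(np.repeat(f, 3, axis=0))
    assert config_disagreement(same, None) < 1e-12
    two = StubCommittee(np.concatenate([f, -f]))
    perm = StubCommittee(np.concatenate([f, -f])[:, ::-1, :])
    assert config_disagreement(two, None) == pytest.approx(
        config_disagreement(perm, None)
    )


@pytest.fixture(scope="module")
def al_setup():
    pool_cfgs = generate_pool(
        SystemRecipe(n_molecules=4, seed=21), 40, amplitude_range=(0.02, 0.06)
    )
    # one artificially strained configuration the committee cannot know
    bad = pool_cfgs[7].copy()
    pos = bad.positions.copy()
    pos[1] += 0.45  # stretch one O-H bond hard
    pool_cfgs[7] = bad.with_positions(pos)
    from qeqnn.descriptors import water_symmetry_functions
    from qeqnn.electrostatics import QeqParameters

    committee = FourthGenCommittee.create(
        water_symmetry_functions("compact"), QeqParameters(), n=2, seed=30
    )
    al = ALConfig(configs_per_round=5, rounds=2, committee_size=2, quick_epochs=5)
    return pool_cfgs, committee, al


def test_al_loop_bookkeeping_and_outlier_selection(al_setup):
    pool_cfgs, committee, al = al_setup
    pool = CandidatePool(pool_cfgs)
    committee, dataset, records = run_active_learning(
        pool, label, committee, al
    )
    # arithmetic: initial + rounds * batch
    assert len(dataset) == 5 + 2 * 5
    sel_rounds = [set(r["selected"]) for r in records]
    flat = [i for s in sel_rounds for i in s]
    assert len(flat) == len(set(flat))  # never resampled
    # the strained configuration is picked in the first disagreement round
    assert 7 in sel_rounds[0] or 7 in sel_rounds[1]
    # scores refreshed over the full remaining pool each round
    assert np.isfinite(pool.scores[pool.remaining]).all()


def test_pool_exhaustion_warns(al_setup):
    pool_cfgs, committee, _ = al_setup
    pool = CandidatePool(pool_cfgs[:3])
    pool.mark_selected([0, 1])
    al = ALConfig(configs_per_round=5, rounds=1, committee_size=2, quick_epochs=1)
    dataset = [label(pool_cfgs[0])] * 3
    with pytest.warns(UserWarning):
        rec = al_round(pool, committee, label, al, list(dataset))
    assert rec["selected"] == [2]
    with pytest.warns(UserWarning):
        rec2 = al_round(pool, committee, label, al, list(dataset))
    assert rec2["selected"] == []


def test_monotone_pool_coverage(al_setup):
    pool_cfgs, committee, _ = al_setup
    pool = CandidatePool(pool_cfgs)
    feats = pool_features(pool, committee)
    mins = []
    picked = []
    for k in (5, 10, 15):
        picked = farthest_point_select(feats, k)
        d = np.min(
            np.linalg.norm(feats[:, None, :] - feats[picked][None, :, :], axis=2),
            axis=1,
        )
        mins.append(d.max())
    assert mins[0] >= mins[1] >= mins[2]


def test_bias_below_threshold_inactive():
    f = np.zeros((2, 3, 3))
    f[0, 1, 0] = 0.05
    f[1, 1, 0] = -0.05
    stub = StubCommittee(f)
    params = BiasParameters(sigma0=0.5, strength=5.0)
    cfg = build_system(SystemRecipe(n_molecules=1, cell=(20, 20, 20), seed=0))
    e, F = bias_energy_forces(stub, cfg, params)
    assert e == 0.0 and np.all(F == 0.0)
    # C^1 at the threshold: energy grows quadratically just above sigma0
    for eps, bound in ((1e-3, 1e-5), (1e-2, 1e-3)):
        f2 = np.zeros((2, 3, 3))
        f2[0, 1, 0] = params.sigma0 + eps
        f2[1, 1, 0] = -(params.sigma0 + eps)
        e2, _ = bias_energy_forces(StubCommittee(f2), cfg, params)
        assert 0 < e2 < bound


def test_bias_pushes_toward_agreement(quick_committee, tiny_dataset):
    """A strongly displaced atom raises disagreement; the bias force on it
    points back toward the training manifold (reduces the bias energy)."""
    cfg = tiny_dataset[0].configuration.copy()
    pos = cfg.positions.copy()
    pos[1] += np.array([0.5, 0.0, 0.0])  # stretch an O-H bond
    cfg = cfg.with_positions(pos)
    pred = quick_committee.predict(cfg)
    smax = pred.sigma_f.max()
    params = BiasParameters(sigma0=0.5 * smax, strength=5.0, neighborhood=2.5)
    e, F = bias_energy_forces(quick_committee, cfg, params)
    assert e > 0
    # following the bias force downhill lowers the bias energy
    step = 1e-3 * F / max(np.linalg.norm(F, axis=1).max(), 1e-12)
    e2, _ = bias_energy_forces(
        quick_committee, cfg.with_positions(cfg.positions + step), params
    )
    assert e2 < e


def test_generation_protocol_single_stage_equals_plain_al(al_setup):
    pool_cfgs, committee, al = al_setup
    committee.reinitialize()
    stages = [{"pool": pool_cfgs, "al": ALConfig(configs_per_round=4, rounds=1,
                                                 committee_size=2, quick_epochs=2)}]
    from qeqnn.model import TrainingConfig

    trained, history = generation_protocol(
        stages, label, committee,
        final_training=TrainingConfig(epochs_elec=5, epochs_short=5),
    )
    assert len(history) == 1
    assert history[0]["train_size"] == 8
    assert all(m.stage2_trained for m in trained.members)
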