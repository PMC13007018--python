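import math

import numpy as np
import pytest

from qeqnn.core_types import AtomicConfiguration
from qeqnn.dynamics import (
    HarmonicPotential,
    IntegratorSpec,
    harmonic_finite_p_kinetic_energy,
    initialize_state,
    normal_mode_matrix,
    run_trajectory,
    step,
)
from qeqnn.units import AMU_TO_EVFS2_PER_A2, HBAR, KB


@pytest.fixture
def oscillator():
    cfg = AtomicConfiguration(species=["H"], positions=[[0.1, 0.0, 0.0]])
    pot = HarmonicPotential(np.zeros((1, 3)), k=5.0)
    m = 1.008 * AMU_TO_EVFS2_PER_A2
    omega = math.sqrt(5.0 / m)
    return cfg, pot, m, omega


def test_normal_mode_matrix_orthogonal():
    for P in (1, 2, 3, 4, 8, 16):
        C, k = normal_mode_matrix(P)
        assert np.max(np.abs(C @ C.T - np.eye(P))) < 1e-12
        assert k[0] == 0


def test_p2_mode_frequency_matches_spring_matrix():
    P, T = 2, 300.0
    beta = 1.0 / (KB * T)
    omega_p = P / (beta * HBAR)
    # bead-spring coupling matrix for P=2: [[2,-2],[-2,2]] * omega_p^2 / 2
    K = omega_p**2 * np.array([[2.0, -2.0], [-2.0, 2.0]])
    eig = np.sort(np.linalg.eigvalsh(K))
    cfg = AtomicConfiguration(species=["H"], positions=[[0, 0, 0]])
    st = initialize_state(cfg, IntegratorSpec(scheme="pimd_nvt", nbeads=2, temperature=T))
    assert st.omega_k[1] == pytest.approx(math.sqrt(eig[1]), rel=1e-12)


def test_zero_force_zero_velocity_is_stationary():
    cfg = AtomicConfiguration(species=["H"], positions=[[0.0, 0.0, 0.0]])
    pot = HarmonicPotential(np.zeros((1, 3)), k=1.0)  # at the minimum
    spec = IntegratorSpec(scheme="classical_nve", dt=0.5)
    st = initialize_state(cfg, spec)
    st.momenta[:] = 0.0
    step(st, pot, spec)
    assert np.max(np.abs(st.beads)) < 1e-15
    assert np.max(np.abs(st.momenta)) < 1e-15


def test_harmonic_nve_energy_conservation(oscillator):
    cfg, pot, m, omega = oscillator
    spec = IntegratorSpec(scheme="classical_nve", dt=1e-3, seed=3)
    st = initialize_state(cfg, spec)
    cons = []
    for _ in range(1000):
        est = step(st, pot, spec)
        cons.append(est["conserved"])
    cons = np.array(cons)
    assert np.max(np.abs(cons - cons[0])) / abs(cons[0]) < 1e-8


def test_nvt_equipartition(oscillator):
    cfg, pot, m, omega = oscillator
    spec = IntegratorSpec(
        scheme="classical_nvt", dt=0.5, tau=20.0, temperature=300.0, seed=4
    )
    st = initialize_state(cfg, spec)
    kes = []
    for i in range(15000):
        est = step(st, pot, spec)
        if i > 1500:
            kes.append(est["kinetic_bead"])
    target = 1.5 * KB * 300.0
    kes = np.array(kes)[: len(kes) // 27 * 27]
    blocks = kes.reshape(27, -1).mean(axis=1)
    se = blocks.std(ddof=1) / math.sqrt(len(blocks))
    assert abs(np.mean(kes) - target) < 3 * se + 0.002 * target


def test_pimd_virial_matches_analytic_finite_p(oscillator):
    cfg, pot, m, omega = oscillator
    T = HBAR * omega / (2.0 * KB)  # beta hbar omega = 2
    P = 8
    spec = IntegratorSpec(
        scheme="pimd_nvt", dt=0.25, tau=15.0, temperature=T, nbeads=P, seed=5
    )
    st = initialize_state(cfg, spec, spread_beads=True)
    kv, kp = [], []
    for i in range(24000):
        est = step(st, pot, spec)
        if i > 3000 and i % 5 == 0:
            kv.append(est["kinetic_virial"])
            kp.append(est["kinetic_primitive"])
    analytic = 3.0 * harmonic_finite_p_kinetic_energy(omega, m, T, P)
    kv = np.array(kv)[: len(kv) // 30 * 30]
    kp = np.array(kp)[: len(kp) // 30 * 30]
    blocks = kv.reshape(30, -1).mean(axis=1)
    se = blocks.std(ddof=1) / math.sqrt(len(blocks))
    assert abs(np.mean(kv) - analytic) < 3 * se + 0.01 * analytic
    # primitive and virial estimators agree with each other
    bp = kp.reshape(30, -1).mean(axis=1)
    se_p = bp.std(ddof=1) / math.sqrt(len(bp))
    assert abs(np.mean(kp) - analytic) < 3 * se_p + 0.02 * analytic


def test_p1_pimd_reduces_to_classical_langevin(oscillator):
    cfg, pot, *_ = oscillator
    s1 = IntegratorSpec(scheme="pimd_nvt", dt=0.5, tau=30.0, nbeads=1, seed=11)
    s2 = IntegratorSpec(scheme="classical_nvt", dt=0.5, tau=30.0, nbeads=1, seed=11)
    a = initialize_state(cfg, s1)
    b = initialize_state(cfg, s2)
    for _ in range(200):
        step(a, pot, s1)
        step(b, pot, s2)
    assert np.array_equal(a.beads, b.beads)


def test_p1_trpmd_is_plain_nve(oscillator):
    cfg, pot, *_ = oscillator
    s1 = IntegratorSpec(scheme="trpmd", dt=0.5, nbeads=1, seed=12)
    s2 = IntegratorSpec(scheme="classical_nve", dt=0.5, nbeads=1, seed=12)
    a = initialize_state(cfg, s1)
    b = initialize_state(cfg, s2)
    for _ in range(200):
        step(a, pot, s1)
        step(b, pot, s2)
    assert np.array_equal(a.beads, b.beads)


def test_deterministic_integrator_time_reversible(oscillator):
    cfg, pot, *_ = oscillator
    spec = IntegratorSpec(scheme="trpmd", dt=0.5, trpmd_lambda=0.0, nbeads=4, seed=6)
    st = initialize_state(cfg, spec, spread_beads=True)
    b0 = st.beads.copy()
    for _ in range(64):
        step(st, pot, spec)
    st.momenta *= -1.0
    st.cached_forces = None
    for _ in range(64):
        step(st, pot, spec)
    assert np.max(np.abs(st.beads - b0)) < 1e-10


def test_momentum_conservation_translation_invariant_potential():
    class FreePotential:
        def energy_forces(self, config):
            return 0.0, np.zeros_like(config.positions)

    cfg = AtomicConfiguration(
        species=["O", "H", "H"], positions=[[0, 0, 0], [1, 0, 0], [0, 1, 0]]
    )
    spec = IntegratorSpec(scheme="classical_nve", dt=1.0, seed=7)
    st = initialize_state(cfg, spec)
    p0 = st.momenta.sum(axis=(0, 1))
    for _ in range(100):
        step(st, FreePotential(), spec)
    assert np.max(np.abs(st.momenta.sum(axis=(0, 1)) - p0)) < 1e-8


def test_pa_cmd_requires_adiabaticity():
    with pytest.raises(ValueError):
        IntegratorSpec(scheme="pa_cmd", adiabaticity=0.5)


def test_centroid_spectrum_peak_harmonic(oscillator):
    """TRPMD and PA-CMD centroids oscillate at omega0 for a harmonic well."""
    cfg, pot, m, omega = oscillator
    for scheme, dt, kw in (
        ("trpmd", 0.5, {}),
        ("pa_cmd", 0.25, {"adiabaticity": 8.0, "cmd_omega_ref": 0.22}),
    ):
        spec = IntegratorSpec(
            scheme=scheme, dt=dt, temperature=300.0, nbeads=8, seed=13, **kw
        )
        st = initialize_state(cfg, spec, spread_beads=True)
        xs = []
        for _ in range(12000):
            step(st, pot, spec)
            xs.append(st.centroid[0, 0])
        x = np.array(xs) - np.mean(xs)
        power = np.abs(np.fft.rfft(x * np.hanning(len(x)))) ** 2
        freqs = 2.0 * math.pi * np.fft.rfftfreq(len(x), dt)
        peak = freqs[np.argmax(power)]
        assert abs(peak - omega) <= freqs[1] + 1e-12


def test_run_trajectory_zero_steps_and_fanout(oscillator):
    cfg, pot, *_ = oscillator
    spec = IntegratorSpec(scheme="classical_nvt", dt=0.5, seed=1)
    frames, logs = run_trajectory(cfg, pot, spec, [{"n_steps": 0}])
    assert len(frames) == 1
    assert np.allclose(frames[0].configuration.positions, cfg.positions)
    # fan-out: distinct seeds give distinct, reproducible trajectories
    ends = []
    for s in (101, 102, 101):
        fr, _ = run_trajectory(
            cfg, pot, spec, [{"n_steps": 50, "stride": 50, "seed": s}]
        )
        ends.append(fr[-1].configuration.positions.copy())
    assert not np.allclose(ends[0], ends[1])
    assert np.array_equal(ends[0], ends[2])


def test_nve_drift_reported_and_small(oscillator):
    cfg, pot, *_ = oscillator
    spec = IntegratorSpec(scheme="classical_nve", dt=0.5, seed=2)
    frames, logs = run_trajectory(cfg, pot, spec, [{"n_steps": 2000, "stride": 10}])
    cons = [row["conserved"] for row in logs if "conserved" in row]
    drift = abs(cons[-1] - cons[1])
    assert drift < 1e-4  # eV/atom over 1 ps at dt = 0.5 fs


def test_state_restart_round_trip(tmp_path, oscillator):
    cfg, pot, *_ = oscillator
    spec = IntegratorSpec(scheme="pimd_nvt", dt=0.5, nbeads=4, seed=21)
    st = initialize_state(cfg, spec, spread_beads=True)
    for _ in range(10):
        step(st, pot, spec)
    from qeqnn.dynamics import load_state, save_state

    save_state(st, tmp_path / "restart.npz")
    back = load_state(tmp_path / "restart.npz")
    # restarted trajectory continues identically (counter-based noise)
    for _ in range(20):
        step(st, pot, spec)
        step(back, pot, spec)
    assert np.array_equal(st.beads, back.beads)
    assert np.array_equal(st.momenta, back.momenta)
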