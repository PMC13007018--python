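import math

import numpy as np
import pytest

from qeqnn.core_types import AtomicConfiguration, TrajectoryFrame
from qeqnn.oracle import OracleParameters, SystemRecipe, build_system, label
from qeqnn.spectra import (
    DipoleSeries,
    LayerSpec,
    autocorrelation,
    density_profile,
    dipole_derivative,
    frame_dipole,
    hann_window,
    ir_spectrum,
    layer_resolved_spectrum,
    rdf,
)
from qeqnn.units import C_CM_PER_FS


def test_linear_symmetric_molecule_zero_dipole():
    cfg = AtomicConfiguration(
        species=["H", "O", "H"],
        positions=[[-1.0, 0, 0], [0, 0, 0], [1.0, 0, 0]],
    )
    mu = frame_dipole(cfg, np.array([0.41, -0.82, 0.41]))
    assert np.max(np.abs(mu)) < 1e-14


def test_single_water_closed_form_dipole(water_molecule):
    p = OracleParameters()
    q = np.array([-0.82, 0.41, 0.41])
    mu = frame_dipole(water_molecule, q)
    expected = 2 * 0.41 * p.r0 * math.cos(p.theta0 / 2.0)
    assert np.linalg.norm(mu) == pytest.approx(expected, abs=1e-12)
    # COM shift is irrelevant for a neutral molecule
    shifted = water_molecule.with_positions(water_molecule.positions + 13.0)
    assert np.allclose(frame_dipole(shifted, q), mu, atol=1e-12)


def test_dipole_additivity_over_molecules(perturbed_box8):
    lab = label(perturbed_box8)
    total, mu_mol, mol, _ = frame_dipole(
        perturbed_box8, lab.charges, return_molecular=True
    )
    assert np.allclose(mu_mol.sum(axis=0), total, atol=1e-14)
    assert len(mu_mol) == 8


def test_dipole_derivative_exactness():
    t = np.arange(0, 50, 0.5)
    const = DipoleSeries(t, np.tile([1.0, -2.0, 0.5], (len(t), 1)))
    assert np.max(np.abs(dipole_derivative(const).dipoles)) == 0.0
    linear = DipoleSeries(t, np.column_stack([t, 0 * t, 0 * t]))
    d = dipole_derivative(linear).dipoles
    assert np.allclose(d[:, 0], 1.0, atol=1e-12)
    # cosine: error is O(dt^2)
    errs = []
    for dt in (0.5, 0.25):
        tt = np.arange(0, 40, dt)
        w = 0.4
        ser = DipoleSeries(tt, np.column_stack([np.cos(w * tt), 0 * tt, 0 * tt]))
        d = dipole_derivative(ser).dipoles[1:-1, 0]
        errs.append(np.max(np.abs(d + w * np.sin(w * tt[1:-1]))))
    assert errs[1] < errs[0] / 3.0  # ~ factor 4 for second order


def test_dipole_series_requires_uniform_grid():
    with pytest.raises(ValueError):
        DipoleSeries(np.array([0.0, 1.0, 2.5]), np.zeros((3, 3)))


def test_autocorrelation_matches_direct_loop(rng):
    x = rng.normal(size=(700, 3))
    max_lag = 120
    fft_acf = autocorrelation(x, max_lag)
    direct = np.array(
        [
            np.mean(
                [x[s] @ x[s + l] for s in range(len(x) - l)]
            ) / 3.0
            for l in range(max_lag + 1)
        ]
    )
    assert np.max(np.abs(fft_acf - direct)) < 1e-10 * max(1.0, np.abs(direct).max())
    # white noise: C(0) = variance, C(t != 0) ~ 0
    assert fft_acf[0] == pytest.approx(np.mean(np.sum(x * x, axis=1)) / 3, rel=1e-10)
    assert np.max(np.abs(fft_acf[1:])) < 5.0 / math.sqrt(len(x))
    with pytest.raises(ValueError):
        autocorrelation(x, 700)


def test_autocorrelation_cosine_and_bound():
    t = np.arange(0, 400, 0.5)
    w = 0.3
    x = np.column_stack([np.cos(w * t), np.zeros_like(t), np.zeros_like(t)])
    acf = autocorrelation(x, 200)
    ref = 0.5 * np.cos(w * t[:201]) / 3.0
    assert np.max(np.abs(acf - ref)) < 0.02
    assert np.all(acf <= acf[0] + 5e-2 * abs(acf[0]))


def test_hann_window_values():
    assert hann_window(0.0, 300.0) == pytest.approx(1.0)
    assert hann_window(300.0, 300.0) == pytest.approx(0.0, abs=1e-30)
    assert hann_window(150.0, 300.0) == pytest.approx(0.5)
    assert hann_window(301.0, 300.0) == 0.0
    with pytest.raises(ValueError):
        hann_window(1.0, 0.0)


def test_cosine_dipole_peak_position():
    dt = 0.5
    t = np.arange(0, 4000, dt)
    nu = 0.1  # cycles/fs = 100 THz
    M = np.column_stack([np.cos(2 * math.pi * nu * t), 0 * t, 0 * t])
    spec = ir_spectrum(DipoleSeries(t, M), tau=300.0)
    peak = spec.wavenumbers[np.argmax(spec.intensity)]
    expected = nu / C_CM_PER_FS  # 3335.6 cm^-1
    assert expected == pytest.approx(3335.64, abs=0.01)
    assert abs(peak - expected) <= 35.0  # window-limited resolution


def test_zero_series_zero_spectrum():
    t = np.arange(0, 1000, 0.5)
    spec = ir_spectrum(DipoleSeries(t, np.zeros((len(t), 3))), tau=300.0)
    assert np.max(np.abs(spec.intensity)) == 0.0


def test_longer_window_sharpens_peak():
    dt = 0.5
    t = np.arange(0, 6000, dt)
    M = np.column_stack([np.cos(2 * math.pi * 0.1 * t), 0 * t, 0 * t])
    widths = []
    for tau in (150.0, 300.0):
        spec = ir_spectrum(DipoleSeries(t, M), tau=tau)
        half = spec.intensity.max() / 2
        widths.append(np.sum(spec.intensity > half) * spec.resolution)
    assert widths[1] < widths[0]


def test_window_exceeding_trajectory_rejected():
    t = np.arange(0, 100, 0.5)
    with pytest.raises(ValueError):
        ir_spectrum(DipoleSeries(t, np.zeros((len(t), 3))), tau=300.0)


def _frames_from(configs, charges=None):
    return [
        TrajectoryFrame(configuration=c, time=i, charges=q)
        for i, (c, q) in enumerate(
            zip(configs, charges or [None] * len(configs))
        )
    ]


def test_rdf_ideal_gas_is_flat(rng):
    L = 12.0
    frames = []
    for k in range(40):
        pos = rng.uniform(0, L, size=(60, 3))
        cfg = AtomicConfiguration(
            species=["H"] * 60, positions=pos, cell=np.eye(3) * L, pbc=[True] * 3
        )
        frames.append(TrajectoryFrame(configuration=cfg, time=k))
    r, g = rdf(frames, ("H", "H"), r_max=5.5, bins=22)
    sel = r > 0.8  # ignore tiny-shell noise
    assert np.all(np.abs(g[sel] - 1.0) < 0.12)
    assert abs(np.mean(g[sel]) - 1.0) < 0.02


def test_rdf_two_atoms_single_bin():
    cfg = AtomicConfiguration(
        species=["O", "H"],
        positions=[[0, 0, 0], [1.05, 0, 0]],
        cell=np.eye(3) * 10.0,
        pbc=[True] * 3,
    )
    r, g = rdf([TrajectoryFrame(configuration=cfg)], ("O", "H"), r_max=3.0, bins=30)
    occupied = np.nonzero(g)[0]
    assert len(occupied) == 1
    assert r[occupied[0]] == pytest.approx(1.05, abs=0.05)


def test_rdf_r_max_guard(water_box8):
    with pytest.raises(ValueError):
        rdf([TrajectoryFrame(configuration=water_box8)], ("O", "O"), r_max=5.0)


def test_oracle_water_oh_peak(perturbed_box8):
    frames = [TrajectoryFrame(configuration=perturbed_box8)]
    r, g = rdf(frames, ("O", "H"), r_max=3.0, bins=60)
    peak_r = r[np.argmax(g)]
    assert abs(peak_r - OracleParameters().r0) < 0.1


def test_density_profile_uniform_and_mass_conserving(water_box8):
    frames = [TrajectoryFrame(configuration=water_box8)]
    z, rho = density_profile(frames, bins=4)
    binvol = water_box8.volume / 4
    total_mass_amu = (rho / 1.66053906660).sum() * binvol  # g/cm3 -> amu/A3
    assert total_mass_amu == pytest.approx(8 * 18.015, rel=1e-3)
    assert np.all(np.abs(rho - 0.997) < 0.75)  # coarse bins, one frame


def test_slab_density_profile_shape():
    cfg = build_system(SystemRecipe(kind="slab", n_molecules=24, cell=(8.5, 8.5, 40.0), seed=1))
    z, rho = density_profile([TrajectoryFrame(configuration=cfg)], bins=20)
    center = rho[(z > 15) & (z < 25)]
    edges = rho[(z < 8) | (z > 32)]
    assert center.mean() > 0.5
    assert np.all(edges < 0.05)


def test_layer_spectrum_partition_and_degenerate_case():
    cfg = build_system(
        SystemRecipe(kind="slab", n_molecules=24, cell=(8.5, 8.5, 40.0), seed=1)
    )
    rng = np.random.default_rng(0)
    frames = []
    for k in range(400):
        jitter = rng.normal(0, 0.02, cfg.positions.shape)
        c = cfg.with_positions(cfg.positions + jitter)
        q = label(c).charges
        frames.append(TrajectoryFrame(configuration=c, time=0.5 * k, charges=q))
    spec = LayerSpec(layer1_half_thickness=1.5, layer2_thickness=4.0)
    out = layer_resolved_spectrum(frames, spec, tau=100.0)
    assert set(out) == {"total", "layer1", "layer2"}
    for sp in out.values():
        assert np.all(np.isfinite(sp.intensity))
    # degenerate partition: everything in layer 1 -> layer-1 == total
    wide = LayerSpec(layer1_half_thickness=50.0, layer2_thickness=1.0)
    with pytest.raises(ValueError):
        layer_resolved_spectrum(frames, wide, tau=100.0)  # layer 2 empty
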