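"""Classical and path-integral molecular dynamics.

Each nucleus is represented by P ring-polymer beads joined by harmonic
springs of frequency omega_P = P/(beta hbar); the bead system is sampled at
temperature P*T.  Integration is in normal modes with exact free-ring-polymer
propagation and the PILE thermostat (per-mode Ornstein-Uhlenbeck kicks,
internal-mode friction gamma_k = 2 omega_k, centroid friction 1/tau), in an
O-B-A-B-O splitting.  P = 1 reduces to classical velocity Verlet (plus
Langevin for NVT).

Approximate quantum dynamics:

* TRPMD -- centroid unthermostatted, internal modes damped with
  gamma_k = lambda * 2 omega_k (lambda = 0.5 default);
* PA-CMD -- internal-mode masses scaled so every internal frequency equals
  Gamma times a reference frequency; strongly thermostatted internal modes
  leave the centroid moving on an adiabatically averaged surface.

Random streams are counter-based (Philox keyed by seed, counter = step), so
fanned-out trajectories are reproducible and independent.

Internal mass units are eV fs^2/A^2 (amu * 103.64); momenta divided by these
masses give velocities in A/fs directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.random import Generator, Philox

from .core_types import AtomicConfiguration, TrajectoryFrame
from .units import AMU_TO_EVFS2_PER_A2, HBAR, KB, mass_of

__all__ = [
    "IntegratorSpec",
    "RingPolymerState",
    "initialize_state",
    "normal_mode_matrix",
    "classical_step",
    "pimd_step",
    "trpmd_step",
    "pa_cmd_step",
    "step",
    "run_segment",
    "run_trajectory",
    "CommitteePotential",
    "save_state",
    "load_state",
    "HarmonicPotential",
    "harmonic_finite_p_kinetic_energy",
]

_DEFAULT_DT = {
    "classical_nve": 1.0,
    "classical_nvt": 1.0,
    "pimd_nvt": 0.5,
    "trpmd": 0.5,
    "pa_cmd": 0.25,
}


@dataclass
class IntegratorSpec:
    scheme: str = "classical_nve"
    dt: Optional[float] = None  # fs; None -> scheme default
    temperature: float = 298.0  # K
    nbeads: int = 1
    thermostat: str = "langevin"  # classical NVT: "langevin" or "svr"
    tau: float = 100.0  # fs, centroid / classical thermostat time constant
    trpmd_lambda: float = 0.5
    adiabaticity: float = 16.0  # PA-CMD Gamma
    cmd_omega_ref: float = 0.5  # rad/fs, stiffest-physical-mode proxy
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in _DEFAULT_DT:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.dt is None:
            self.dt = _DEFAULT_DT[self.scheme]
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.scheme == "pa_cmd" and self.adiabaticity <= 1:
            raise ValueError("PA-CMD adiabaticity must exceed 1")
        if self.nbeads < 1:
            raise ValueError("nbeads must be >= 1")


def normal_mode_matrix(P: int) -> Tuple[np.ndarray, np.ndarray]:
    """Orthogonal transform C (modes = C @ beads) and mode indices k.

    Row 0 is the centroid; rows come in cos/sin pairs of wavenumber j with
    free-ring-polymer frequency 2 omega_P sin(pi j / P).
    """
    C = np.zeros((P, P))
    kidx = np.zeros(P)
    C[0, :] = 1.0 / math.sqrt(P)
    row = 1
    b = np.arange(P)
    for j in range(1, P // 2 + 1):
        if 2 * j == P:
            C[row, :] = ((-1.0) ** b) / math.sqrt(P)
            kidx[row] = j
            row += 1
        else:
            C[row, :] = math.sqrt(2.0 / P) * np.cos(2.0 * math.pi * j * b / P)
            kidx[row] = j
            row += 1
            C[row, :] = math.sqrt(2.0 / P) * np.sin(2.0 * math.pi * j * b / P)
            kidx[row] = j
            row += 1
    return C, kidx


@dataclass
class RingPolymerState:
    """Bead positions/momenta plus cached normal-mode machinery."""

    species: np.ndarray
    beads: np.ndarray  # (P, N, 3) A
    momenta: np.ndarray  # (P, N, 3) in internal mass units * A/fs
    masses: np.ndarray  # (N,) internal units (eV fs^2/A^2)
    temperature: float  # K
    cell: Optional[np.ndarray] = None
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))
    total_charge: float = 0.0
    step_count: int = 0
    cached_forces: Optional[np.ndarray] = None  # forces at current bead positions
    cached_epot: float = 0.0
    nm_C: np.ndarray = None
    nm_k: np.ndarray = None
    omega_k: np.ndarray = None  # (P,) free-RP mode angular frequencies [1/fs]

    def __post_init__(self):
        P = self.beads.shape[0]
        if self.nm_C is None:
            self.nm_C, self.nm_k = normal_mode_matrix(P)
            beta = 1.0 / (KB * self.temperature)
            omega_p = P / (beta * HBAR)
            self.omega_k = 2.0 * omega_p * np.sin(math.pi * self.nm_k / P)

    @property
    def nbeads(self) -> int:
        return self.beads.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.beads.mean(axis=0)

    def centroid_config(self) -> AtomicConfiguration:
        return AtomicConfiguration(
            species=self.species,
            positions=self.centroid,
            cell=self.cell,
            pbc=self.pbc,
            total_charge=self.total_charge,
        )

    def bead_config(self, b: int) -> AtomicConfiguration:
        return AtomicConfiguration(
            species=self.species,
            positions=self.beads[b],
            cell=self.cell,
            pbc=self.pbc,
            total_charge=self.total_charge,
        )


def _rng_for(seed: int, step_index: int) -> Generator:
    return Generator(Philox(key=seed, counter=[0, 0, 0, step_index]))


def initialize_state(
    config: AtomicConfiguration,
    spec: IntegratorSpec,
    spread_beads: bool = False,
) -> RingPolymerState:
    """Bead stack at the classical positions with thermal momenta.

    ``spread_beads`` adds small Gaussian bead spread to break the classical
    start (free-particle thermal width); the centroid stays at the input
    positions.
    """
    P = spec.nbeads
    masses = np.array([mass_of(s) for s in config.species]) * AMU_TO_EVFS2_PER_A2
    beads = np.repeat(config.positions[None, :, :], P, axis=0)
    rng = _rng_for(spec.seed, 0)
    if spread_beads and P > 1:
        beta = 1.0 / (KB * spec.temperature)
        width = np.sqrt(beta * HBAR * HBAR / (4.0 * masses * P))  # rough rg
        noise = rng.normal(size=(P, len(masses), 3)) * width[None, :, None]
        beads = beads + noise - noise.mean(axis=0, keepdims=True)
    sigma = np.sqrt(masses * KB * spec.temperature * P)
    momenta = rng.normal(size=(P, len(masses), 3)) * sigma[None, :, None]
    return RingPolymerState(
        species=config.species.copy(),
        beads=beads,
        momenta=momenta,
        masses=masses,
        temperature=spec.temperature,
        cell=None if config.cell is None else config.cell.copy(),
        pbc=config.pbc.copy(),
        total_charge=config.total_charge,
    )


def _mode_masses(state: RingPolymerState, spec: IntegratorSpec) -> np.ndarray:
    """Per-mode kinetic masses (P, N); PA-CMD scales internal modes."""
    P = state.nbeads
    mm = np.repeat(state.masses[None, :], P, axis=0)
    if spec.scheme == "pa_cmd" and P > 1:
        omega_target = spec.adiabaticity * spec.cmd_omega_ref
        scale = (state.omega_k / omega_target) ** 2
        mm[1:] = mm[1:] * scale[1:, None]
    return mm


def _frictions(state: RingPolymerState, spec: IntegratorSpec) -> Optional[np.ndarray]:
    """Per-mode friction (P,), or None when the step is fully Hamiltonian."""
    P = state.nbeads
    g = np.zeros(P)
    if spec.scheme == "classical_nve":
        return None
    if spec.scheme == "classical_nvt":
        g[:] = 1.0 / spec.tau
        return g
    if spec.scheme == "pimd_nvt":
        g[0] = 1.0 / spec.tau
        g[1:] = 2.0 * state.omega_k[1:]
        return g
    if spec.scheme == "trpmd":
        g[0] = 0.0
        g[1:] = spec.trpmd_lambda * 2.0 * state.omega_k[1:]
        return None if P == 1 else g
    if spec.scheme == "pa_cmd":
        g[0] = 0.0
        if P > 1:
            omega_target = spec.adiabaticity * spec.cmd_omega_ref
            g[1:] = 2.0 * omega_target
        return None if P == 1 else g
    raise ValueError(spec.scheme)


def _forces_all_beads(state: RingPolymerState, potential) -> Tuple[np.ndarray, float]:
    F = np.empty_like(state.beads)
    epot = 0.0
    for b in range(state.nbeads):
        e, f = potential.energy_forces(state.bead_config(b))
        if not np.all(np.isfinite(f)):
            bad = int(np.argwhere(~np.isfinite(f))[0][0])
            raise FloatingPointError(f"non-finite force on atom {bad}")
        F[b] = f
        epot += e
    return F, epot


def _ou_half(state, spec, frictions, mode_masses, rng, half_id):
    """Exact Ornstein-Uhlenbeck half-step on normal-mode momenta."""
    if frictions is None:
        return
    P = state.nbeads
    dt2 = 0.5 * spec.dt
    p_nm = np.tensordot(state.nm_C, state.momenta, axes=(1, 0))
    if spec.scheme == "classical_nvt" and spec.thermostat == "svr":
        # stochastic velocity rescaling on the full momentum vector
        ndof = state.momenta.size
        kt = KB * spec.temperature
        ke = 0.5 * np.sum(state.momenta**2 / mode_masses[..., None])
        c = math.exp(-dt2 / spec.tau)
        r1 = rng.normal()
        r2 = np.sum(rng.normal(size=ndof - 1) ** 2)
        ke_target = 0.5 * ndof * kt
        alpha2 = (
            c
            + (1 - c) * ke_target / (ndof * ke) * (r1 * r1 + r2)
            + 2.0 * r1 * math.sqrt(c * (1 - c) * ke_target / (ndof * ke))
        )
        state.momenta *= math.sqrt(max(alpha2, 1e-12))
        return
    kt_p = KB * spec.temperature * P  # bead temperature
    c1 = np.exp(-frictions * dt2)[:, None]
    sigma = np.sqrt(mode_masses * kt_p)
    noise = rng.normal(size=p_nm.shape)
    p_nm = c1[..., None] * p_nm + np.sqrt(1.0 - c1[..., None] ** 2) * sigma[
        ..., None
    ] * noise
    state.momenta = np.tensordot(state.nm_C.T, p_nm, axes=(1, 0))


def _free_rp_drift(state, spec, mode_masses):
    """Exact evolution under kinetic + ring-polymer springs (A step)."""
    dt = spec.dt
    P = state.nbeads
    if P == 1:
        state.beads = state.beads + dt * state.momenta / mode_masses[..., None]
        return
    x_nm = np.tensordot(state.nm_C, state.beads, axes=(1, 0))
    p_nm = np.tensordot(state.nm_C, state.momenta, axes=(1, 0))
    # centroid: free flight
    x_nm[0] += dt * p_nm[0] / mode_masses[0][:, None]
    # internal modes: exact harmonic rotation; spring constant m_phys omega_k^2
    for k in range(1, P):
        m_k = mode_masses[k][:, None]
        m_phys = state.masses[:, None]
        om = state.omega_k[k] * np.sqrt(m_phys / m_k)  # effective frequency
        cwt = np.cos(om * dt)
        swt = np.sin(om * dt)
        x_old = x_nm[k].copy()
        x_nm[k] = cwt * x_old + swt * p_nm[k] / (m_k * om)
        p_nm[k] = cwt * p_nm[k] - swt * (m_k * om) * x_old
    state.beads = np.tensordot(state.nm_C.T, x_nm, axes=(1, 0))
    state.momenta = np.tensordot(state.nm_C.T, p_nm, axes=(1, 0))


def step(state: RingPolymerState, potential, spec: IntegratorSpec) -> Dict[str, float]:
    """One O-B-A-B-O step; mutates the state, returns estimator values."""
    rng = _rng_for(spec.seed, state.step_count + 1)
    mode_masses = _mode_masses(state, spec)
    frictions = _frictions(state, spec)
    _ou_half(state, spec, frictions, mode_masses, rng, 0)
    if state.cached_forces is None:
        F, _ = _forces_all_beads(state, potential)
    else:
        F = state.cached_forces
    state.momenta += 0.5 * spec.dt * F
    _free_rp_drift(state, spec, mode_masses)
    F, epot = _forces_all_beads(state, potential)
    state.momenta += 0.5 * spec.dt * F
    _ou_half(state, spec, frictions, mode_masses, rng, 1)
    state.step_count += 1
    state.cached_forces = F
    state.cached_epot = epot
    return estimators(state, spec, F, epot)


# aliases matching the scheme names
def classical_step(state, potential, spec):
    return step(state, potential, spec)


def pimd_step(state, potential, spec):
    return step(state, potential, spec)


def trpmd_step(state, potential, spec):
    return step(state, potential, spec)


def pa_cmd_step(state, potential, spec):
    return step(state, potential, spec)


def estimators(
    state: RingPolymerState,
    spec: IntegratorSpec,
    forces: Optional[np.ndarray] = None,
    epot: Optional[float] = None,
) -> Dict[str, float]:
    """Energies, temperature, and quantum kinetic-energy estimators."""
    P = state.nbeads
    mode_masses = _mode_masses(state, spec)
    ke_beads = 0.5 * float(np.sum(state.momenta**2 / mode_masses[..., None]))
    ndof = state.momenta.size
    out = {
        "kinetic_bead": ke_beads,
        "temperature": 2.0 * ke_beads / (ndof * KB),
    }
    if epot is not None:
        out["potential"] = epot / P
    beta = 1.0 / (KB * state.temperature)
    if P > 1:
        omega_p = P / (beta * HBAR)
        spring = 0.0
        for b in range(P):
            d = state.beads[b] - state.beads[(b + 1) % P]
            spring += 0.5 * omega_p**2 * float(np.sum(state.masses[:, None] * d * d))
        natoms = state.beads.shape[1]
        # estimator spring coefficient is m omega_P^2 / P (Tuckerman convention)
        out["kinetic_primitive"] = 3.0 * natoms * P / (2.0 * beta) - spring / P
        if forces is not None:
            centroid = state.centroid
            dv = state.beads - centroid[None]
            out["kinetic_virial"] = 3.0 * natoms / (2.0 * beta) - 0.5 / P * float(
                np.sum(dv * forces)
            )
        out["spring_energy"] = spring
    if epot is not None:
        out["conserved"] = ke_beads + epot + out.get("spring_energy", 0.0)
    return out


def run_segment(
    config: AtomicConfiguration,
    potential,
    spec: IntegratorSpec,
    n_steps: int,
    state: Optional[RingPolymerState] = None,
) -> Tuple[AtomicConfiguration, RingPolymerState]:
    """Advance n_steps and return (centroid configuration, state)."""
    if state is None:
        state = initialize_state(config, spec)
    for _ in range(n_steps):
        step(state, potential, spec)
    return state.centroid_config(), state


def run_trajectory(
    initial: AtomicConfiguration,
    potential,
    spec: IntegratorSpec,
    schedule: Sequence[Dict],
    charge_mode: str = "auto",
) -> Tuple[List[TrajectoryFrame], List[Dict[str, float]]]:
    """Run a schedule of segments, collecting frames with predicted charges.

    Each schedule entry is ``{"scheme": ..., "n_steps": ..., "stride": ...}``
    (missing keys inherit the spec).  Charges stored per frame come from
    ``potential.charges`` at the centroid ("centroid") or averaged over the
    beads ("bead_average"); "auto" picks bead averaging for trpmd/pimd.
    """
    frames: List[TrajectoryFrame] = []
    logs: List[Dict[str, float]] = []
    state: Optional[RingPolymerState] = None
    t = 0.0
    has_charges = hasattr(potential, "charges")

    def snapshot(est: Dict[str, float], scheme: str):
        cfg = state.centroid_config()
        q = None
        if has_charges:
            mode = charge_mode
            if mode == "auto":
                mode = "bead_average" if scheme in ("trpmd", "pimd_nvt") else "centroid"
            if mode == "bead_average" and state.nbeads > 1:
                q = np.mean(
                    [potential.charges(state.bead_config(b)) for b in range(state.nbeads)],
                    axis=0,
                )
            else:
                q = potential.charges(cfg)
            cfg.total_charge = float(q.sum())
        vel = state.momenta.mean(axis=0) / state.masses[:, None]
        frames.append(
            TrajectoryFrame(
                configuration=cfg,
                time=t,
                velocities=vel,
                charges=q,
                energy=est.get("potential"),
            )
        )
        logs.append({"time": t, **est})

    for seg in schedule:
        seg_spec = replace(
            spec,
            scheme=seg.get("scheme", spec.scheme),
            dt=seg.get("dt", spec.dt),
            seed=seg.get("seed", spec.seed),
        )
        if state is None:
            state = initialize_state(initial, seg_spec)
            est = estimators(state, seg_spec)
            snapshot(est, seg_spec.scheme)
        stride = max(1, int(seg.get("stride", 1)))
        for i in range(int(seg["n_steps"])):
            est = step(state, potential, seg_spec)
            t = state.step_count * seg_spec.dt
            if (i + 1) % stride == 0:
                snapshot(est, seg_spec.scheme)
    return frames, logs


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------


class CommitteePotential:
    """Adapter: committee mean energy/forces (and charges) as a potential."""

    def __init__(self, committee):
        self.committee = committee

    def energy_forces(self, config: AtomicConfiguration):
        pred = self.committee.predict(config)
        return pred.energy, pred.forces

    def charges(self, config: AtomicConfiguration):
        return self.committee.predict(config).charges


class HarmonicPotential:
    """Isotropic harmonic wells V = sum_i k_i |r_i - r0_i|^2 / 2 (tests, guards)."""

    def __init__(self, centers: np.ndarray, k: float):
        self.centers = np.asarray(centers, dtype=float)
        self.k = k

    def energy_forces(self, config: AtomicConfiguration):
        d = config.positions - self.centers
        return 0.5 * self.k * float(np.sum(d * d)), -self.k * d


def harmonic_finite_p_kinetic_energy(
    omega: float, mass: float, temperature: float, P: int
) -> float:
    """Analytic P-bead kinetic energy (one Cartesian dof) of a harmonic well.

    KE_P = 1/(2 beta) + (omega^2 / (2 beta)) sum_{k>=1} 1/(omega_k^2 + omega^2)
    with omega_k the free-ring-polymer normal-mode frequencies; equals the
    centroid-virial estimator expectation at finite P.
    """
    beta = 1.0 / (KB * temperature)
    omega_p = P / (beta * HBAR)
    ks = np.arange(1, P)
    om_k = 2.0 * omega_p * np.sin(math.pi * ks / P)
    return 1.0 / (2.0 * beta) + omega**2 / (2.0 * beta) * float(
        np.sum(1.0 / (om_k**2 + omega**2))
    )


def save_state(state: RingPolymerState, path) -> None:
    """Full restart file for a ring-polymer state (npz)."""
    np.savez(
        path,
        species=state.species.astype("U4"),
        beads=state.beads,
        momenta=state.momenta,
        masses=state.masses,
        temperature=state.temperature,
        cell=state.cell if state.cell is not None else np.zeros((0, 3)),
        pbc=state.pbc,
        total_charge=state.total_charge,
        step_count=state.step_count,
    )


def load_state(path) -> RingPolymerState:
    data = np.load(path, allow_pickle=False)
    cell = data["cell"]
    return RingPolymerState(
        species=data["species"],
        beads=data["beads"],
        momenta=data["momenta"],
        masses=data["masses"],
        temperature=float(data["temperature"]),
        cell=None if cell.size == 0 else cell,
        pbc=data["pbc"],
        total_charge=float(data["total_charge"]),
        step_count=int(data["step_count"]),
    )
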