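"""Synthetic reference oracle: water boxes/slabs with analytic labels.

The oracle is a self-contained "reference theory" for flexible water that
every other module can be trained and validated against at desk scale:

* intramolecular harmonic O-H bonds and H-O-H angle,
* a switched Lennard-Jones interaction between oxygens,
* ground-truth electrostatics from its own charge equilibration, in which
  the per-atom electronegativity depends smoothly on the local coordination
  number, chi_i = chi0(element) + c * CN_i.

The coordination coupling makes the reference charges genuinely
environment-dependent (gas-phase and condensed-phase molecular charges
differ), which is exactly the feature a charge-equilibration potential must
capture and a fixed-charge (2G) model cannot.  Labels (energy, analytic
forces including the charge response dQ/dR, charges) are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core_types import AtomicConfiguration, LabeledConfiguration
from .electrostatics import EwaldSystem, QeqParameters
from .geometry import minimum_image_vector, neighbor_list
from .units import AMU_PER_A3_TO_G_PER_CM3, mass_of

__all__ = [
    "OracleParameters",
    "SystemRecipe",
    "build_system",
    "label",
    "generate_pool",
    "OraclePotential",
    "water_density",
]


@dataclass
class OracleParameters:
    """Declared constants of the synthetic reference theory."""

    r0: float = 0.9572  # A, O-H equilibrium bond
    theta0: float = math.radians(104.52)  # rad, H-O-H equilibrium angle
    k_bond: float = 20.0  # eV/A^2
    k_angle: float = 4.0  # eV/rad^2
    lj_epsilon: float = 0.0067  # eV, O-O
    lj_sigma: float = 3.166  # A
    lj_r_on: float = 5.0  # A, switching starts
    lj_r_off: float = 6.0  # A, interaction ends
    chi0: Dict[str, float] = field(default_factory=lambda: {"O": 17.8, "H": 0.0})
    coord_coupling: float = 0.3  # eV/e per neighbor
    coord_r_cut: float = 3.2  # A, smooth coordination counting radius
    qeq: QeqParameters = field(default_factory=QeqParameters)

    def __post_init__(self):
        if min(self.k_bond, self.k_angle, self.lj_epsilon) <= 0:
            raise ValueError("force-field constants must be positive")


@dataclass
class SystemRecipe:
    kind: str = "bulk"  # or "slab"
    n_molecules: int = 8
    cell: Optional[Tuple[float, float, float]] = None  # A; None -> from density
    density: float = 0.997  # g/cm^3 target for the liquid region
    vacuum: float = 12.5  # A on each slab side
    temperature: float = 298.0  # K
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("bulk", "slab"):
            raise ValueError(f"unknown system kind {self.kind!r}")
        if not (0.5 <= self.density <= 1.5):
            raise ValueError("target density must be physical (0.5-1.5 g/cm^3)")


def water_density(n_molecules: int, volume_a3: float) -> float:
    """Mass density of n water molecules in a volume [g/cm^3]."""
    m = n_molecules * (mass_of("O") + 2 * mass_of("H"))
    return m / volume_a3 * AMU_PER_A3_TO_G_PER_CM3


def _water_template(params: OracleParameters) -> np.ndarray:
    half = params.theta0 / 2.0
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [params.r0 * math.sin(half), 0.0, params.r0 * math.cos(half)],
            [-params.r0 * math.sin(half), 0.0, params.r0 * math.cos(half)],
        ]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_system(
    recipe: SystemRecipe, params: Optional[OracleParameters] = None
) -> AtomicConfiguration:
    """Pack water molecules on a jittered lattice with random orientations.

    Bulk: cubic cell from the target density unless given.  Slab: molecules
    fill a central layer along z with vacuum on both sides.  Packing retries
    until all intermolecular O-O minimum-image distances exceed 2.4 A.
    """
    params = params or OracleParameters()
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_molecules
    m_w = mass_of("O") + 2 * mass_of("H")
    if recipe.kind == "bulk":
        if recipe.cell is None:
            vol = n * m_w * AMU_PER_A3_TO_G_PER_CM3 / recipe.density
            L = vol ** (1.0 / 3.0)
            cell_dims = (L, L, L)
        else:
            cell_dims = tuple(recipe.cell)
        z_lo, z_hi = 0.0, cell_dims[2]
    else:
        if recipe.cell is None:
            raise ValueError("slab recipe requires explicit cell dimensions")
        cell_dims = tuple(recipe.cell)
        lx, ly, lz = cell_dims
        thickness = n * m_w * AMU_PER_A3_TO_G_PER_CM3 / (recipe.density * lx * ly)
        if thickness + 2 * recipe.vacuum > lz:
            raise ValueError("cell too short for slab + vacuum")
        z_lo = 0.5 * (lz - thickness)
        z_hi = z_lo + thickness
    cell = np.diag(cell_dims)
    template = _water_template(params)

    for attempt in range(50):
        # lattice sites inside the liquid region
        region = np.array([cell_dims[0], cell_dims[1], z_hi - z_lo])
        scale = (n / region.prod()) ** (1.0 / 3.0)
        counts = np.maximum(1, np.floor(region * scale + 1e-9).astype(int))
        while counts.prod() < n:
            counts[np.argmax(region / counts)] += 1
        grid = np.stack(
            np.meshgrid(*[np.arange(c) for c in counts], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        spacing = region / counts
        sites = (grid + 0.5) * spacing + np.array([0.0, 0.0, z_lo])
        order = rng.permutation(len(sites))[:n]
        jitter = rng.uniform(-0.06, 0.06, size=(n, 3)) * spacing
        positions = np.empty((3 * n, 3))
        for k, s in enumerate(sites[order] + jitter):
            R = _random_rotation(rng)
            positions[3 * k : 3 * k + 3] = s + template @ R.T
        cfg = AtomicConfiguration(
            species=np.array(["O", "H", "H"] * n),
            positions=positions,
            cell=cell,
            pbc=np.array([True, True, True]),
            total_charge=0.0,
        )
        o_idx = np.arange(0, 3 * n, 3)
        if n == 1:
            return cfg
        sub = AtomicConfiguration(
            species=cfg.species[o_idx],
            positions=cfg.positions[o_idx],
            cell=cell,
            pbc=cfg.pbc,
        )
        _, _, _, dist = neighbor_list(sub, 2.4)
        if len(dist) == 0:
            return cfg
    raise RuntimeError("packing failed: could not satisfy the O-O distance floor")


def _molecule_topology(config: AtomicConfiguration) -> int:
    """Validate the O,H,H repeating pattern and return the molecule count."""
    sp = config.species
    if len(sp) % 3 != 0:
        raise ValueError("oracle systems must be all-water (O,H,H per molecule)")
    n = len(sp) // 3
    pattern = np.array(["O", "H", "H"] * n)
    if not np.array_equal(sp, pattern):
        raise ValueError("oracle systems must be ordered O,H,H per molecule")
    return n


def _switch(r: np.ndarray, r_on: float, r_off: float):
    """C^1 switching function: 1 below r_on, 0 above r_off, and its derivative."""
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    mid = (r > r_on) & (r < r_off)
    x = (r[mid] - r_on) / (r_off - r_on)
    s[mid] = 0.5 * (np.cos(np.pi * x) + 1.0)
    ds[mid] = -0.5 * np.pi / (r_off - r_on) * np.sin(np.pi * x)
    s[r >= r_off] = 0.0
    return s, ds


def _bonded_energy_forces(
    config: AtomicConfiguration, params: OracleParameters
) -> Tuple[float, np.ndarray]:
    n_mol = _molecule_topology(config)
    F = np.zeros((config.n_atoms, 3))
    E = 0.0
    for m in range(n_mol):
        o, h1, h2 = 3 * m, 3 * m + 1, 3 * m + 2
        v1 = minimum_image_vector(config, o, h1)
        v2 = minimum_image_vector(config, o, h2)
        a, b = np.linalg.norm(v1), np.linalg.norm(v2)
        for h, v, d in ((h1, v1, a), (h2, v2, b)):
            E += 0.5 * params.k_bond * (d - params.r0) ** 2
            g = params.k_bond * (d - params.r0) * v / d  # dE/d r_h
            F[h] -= g
            F[o] += g
        c = float(v1 @ v2 / (a * b))
        c = max(-1.0 + 1e-12, min(1.0 - 1e-12, c))
        theta = math.acos(c)
        dEdtheta = params.k_angle * (theta - params.theta0)
        pref = -1.0 / math.sqrt(1.0 - c * c)
        dc_dv1 = v2 / (a * b) - c * v1 / (a * a)
        dc_dv2 = v1 / (a * b) - c * v2 / (b * b)
        g1 = dEdtheta * pref * dc_dv1
        g2 = dEdtheta * pref * dc_dv2
        E += 0.5 * params.k_angle * (theta - params.theta0) ** 2
        F[h1] -= g1
        F[h2] -= g2
        F[o] += g1 + g2
    return E, F


def _lj_energy_forces(
    config: AtomicConfiguration, params: OracleParameters
) -> Tuple[float, np.ndarray]:
    n_mol = _molecule_topology(config)
    o_idx = np.arange(0, 3 * n_mol, 3)
    sub = AtomicConfiguration(
        species=config.species[o_idx],
        positions=config.positions[o_idx],
        cell=config.cell,
        pbc=config.pbc,
    )
    i_idx, j_idx, rvec, dist = neighbor_list(sub, params.lj_r_off)
    F = np.zeros((config.n_atoms, 3))
    if len(dist) == 0:
        return 0.0, F
    sr6 = (params.lj_sigma / dist) ** 6
    v = 4.0 * params.lj_epsilon * (sr6 * sr6 - sr6)
    dv = 4.0 * params.lj_epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / dist
    s, ds = _switch(dist, params.lj_r_on, params.lj_r_off)
    # directed pairs double-count the energy
    E = 0.5 * float(np.sum(v * s))
    dt = dv * s + v * ds  # d(v*s)/dd, per directed pair
    # dE/dR_i for pair term = -0.5 * dt * rhat per directed pair, summed twice
    contrib = (dt / dist)[:, None] * rvec  # d(pair)/dR_j direction
    f_o = np.zeros((n_mol, 3))
    np.add.at(f_o, j_idx, -0.5 * contrib)
    np.add.at(f_o, i_idx, 0.5 * contrib)
    F[o_idx] = f_o
    return E, F


def _coordination(
    config: AtomicConfiguration, params: OracleParameters, gradients: bool = False
):
    """Smooth coordination numbers CN_i and optionally dCN_i/dR [N,N,3]."""
    n = config.n_atoms
    cn = np.zeros(n)
    dcn = np.zeros((n, n, 3)) if gradients else None
    i_idx, j_idx, rvec, dist = neighbor_list(config, params.coord_r_cut)
    if len(dist):
        x = np.pi * dist / params.coord_r_cut
        fc = 0.5 * (np.cos(x) + 1.0)
        np.add.at(cn, i_idx, fc)
        if gradients:
            dfc = -0.5 * np.pi / params.coord_r_cut * np.sin(x)
            g = (dfc / dist)[:, None] * rvec  # d fc / d R_j
            np.add.at(dcn, (i_idx, j_idx), g)
            np.add.at(dcn, (i_idx, i_idx), -g)
    return cn, dcn


def oracle_charges(
    config: AtomicConfiguration,
    params: OracleParameters,
    system: Optional[EwaldSystem] = None,
):
    """Ground-truth Qeq charges from coordination-dependent electronegativities."""
    _molecule_topology(config)
    if system is None:
        system = EwaldSystem(config, params.qeq)
    cn, _ = _coordination(config, params)
    chi = np.array([params.chi0[s] for s in config.species]) + params.coord_coupling * cn
    return system.solve(chi, config.total_charge)


def label(
    config: AtomicConfiguration, params: Optional[OracleParameters] = None
) -> LabeledConfiguration:
    """Deterministic reference labels: energy, analytic forces, charges."""
    params = params or OracleParameters()
    _molecule_topology(config)
    e_b, f_b = _bonded_energy_forces(config, params)
    e_lj, f_lj = _lj_energy_forces(config, params)
    system = EwaldSystem(config, params.qeq, gradients=True)
    cn, dcn = _coordination(config, params, gradients=True)
    chi = np.array([params.chi0[s] for s in config.species]) + params.coord_coupling * cn
    sol = system.solve(chi, config.total_charge)
    q = sol.charges
    g = system.A_prime @ q
    u = system.adjoint(g)
    dchi_dpos = params.coord_coupling * dcn
    grad_elec = (
        0.5 * system.pair_grad(q, q)
        - system.pair_grad(u, q)
        - np.einsum("i,iac->ac", u, dchi_dpos)
    )
    return LabeledConfiguration(
        configuration=config,
        energy=e_b + e_lj + sol.e_elec,
        forces=f_b + f_lj - grad_elec,
        charges=q,
    )


class OraclePotential:
    """Potential-protocol adapter so the dynamics module can run oracle MD."""

    def __init__(self, params: Optional[OracleParameters] = None):
        self.params = params or OracleParameters()

    def energy_forces(self, config: AtomicConfiguration) -> Tuple[float, np.ndarray]:
        lab = label(config, self.params)
        return lab.energy, lab.forces

    def charges(self, config: AtomicConfiguration) -> np.ndarray:
        return oracle_charges(config, self.params).charges


def generate_pool(
    recipe: SystemRecipe,
    n_configs: int,
    sampler: str = "random_displacement",
    params: Optional[OracleParameters] = None,
    amplitude_range: Tuple[float, float] = (0.02, 0.2),
    stride: int = 100,
    dt: float = 0.5,
) -> List[AtomicConfiguration]:
    """Decorrelated unlabeled configurations around a packed system.

    ``random_displacement`` draws a per-configuration Gaussian displacement
    amplitude uniformly from ``amplitude_range`` [A], so the pool spans
    near-equilibrium to strongly distorted structures.  ``oracle_md`` runs
    Langevin dynamics on the oracle potential at the recipe temperature and
    keeps every ``stride``-th step (>= 100 steps decorrelates the fast
    intramolecular modes).
    """
    params = params or OracleParameters()
    base = build_system(recipe, params)
    rng = np.random.default_rng(recipe.seed + 1)
    if n_configs == 0:
        return []
    if sampler == "random_displacement":
        out = []
        for _ in range(n_configs):
            amp = rng.uniform(*amplitude_range)
            out.append(
                base.with_positions(
                    base.positions + rng.normal(0.0, max(amp, 0.0), base.positions.shape)
                )
            )
        return out
    if sampler == "oracle_md":
        from .dynamics import IntegratorSpec, run_segment

        spec = IntegratorSpec(
            scheme="classical_nvt",
            dt=dt,
            temperature=recipe.temperature,
            seed=recipe.seed + 2,
        )
        out = []
        state = None
        pot = OraclePotential(params)
        config = base
        for _ in range(n_configs):
            config, state = run_segment(config, pot, spec, n_steps=stride, state=state)
            out.append(config.copy())
        return out
    raise ValueError(f"unknown sampler {sampler!r}")
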