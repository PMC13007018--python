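"""Screened-Coulomb electrostatics and charge equilibration (Qeq).

Atomic charges are Gaussians of per-element width sigma_i; the pair
interaction is ``ke qi qj erf(r/(sqrt(2) gamma_ij))/r`` with
``gamma_ij = sqrt(sigma_i^2 + sigma_j^2)``, plus self energies
``ke qi^2/(2 sigma_i sqrt(pi))``.  The Qeq energy adds learned per-atom
electronegativities chi_i and element hardness J_i:

    E_Qeq(Q) = E_elec(Q) + sum_i (chi_i Q_i + J_i Q_i^2 / 2)

and is minimized under the total-charge constraint by a single linear solve
of the stationarity system augmented with a Lagrange multiplier row.  For
periodic cells the Coulomb matrix is built by Ewald summation with a
splitting width eta chosen from an accuracy target; energies and forces are
independent of eta to within that target.

Forces include the implicit charge response dQ/dR, obtained by one adjoint
solve of the (factored) augmented system per configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.special import erf, erfcinv

from .core_types import AtomicConfiguration
from .geometry import neighbor_list
from .units import KE

__all__ = [
    "QeqParameters",
    "ChargeSolution",
    "EwaldSystem",
    "pair_screened_energy",
    "self_energy",
    "build_A_matrix",
    "solve_constrained",
    "solve_qeq",
    "electrostatic_energy",
    "electrostatic_forces",
]

SQRT2 = math.sqrt(2.0)
SQRT_2_PI = math.sqrt(2.0 / math.pi)

# per-element placeholders (always configurable): sigma ~ covalent radius
DEFAULT_SIGMA = {"O": 0.66, "H": 0.31}
DEFAULT_HARDNESS = {"O": 13.8, "H": 14.7}


@dataclass
class QeqParameters:
    """Element hardness J [eV/e^2], Gaussian widths sigma [A], Ewald knobs."""

    hardness: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HARDNESS))
    sigma: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    ewald_eta: Optional[float] = None  # A; None -> chosen from tolerance
    r_cut_real: Optional[float] = None  # A
    kspace_cutoff: Optional[float] = None  # A^-1
    tolerance: float = 1e-8  # target truncation error scale

    def __post_init__(self) -> None:
        for e, s in self.sigma.items():
            if s <= 0:
                raise ValueError(f"sigma[{e}] must be positive")
        for e, j in self.hardness.items():
            if j <= 0:
                raise ValueError(f"hardness[{e}] must be positive")

    def sigmas(self, species: np.ndarray) -> np.ndarray:
        return np.array([self.sigma[s] for s in species])

    def hardnesses(self, species: np.ndarray) -> np.ndarray:
        return np.array([self.hardness[s] for s in species])

    def resolve(self, config: AtomicConfiguration) -> Tuple[float, float, float]:
        """Ewald (eta, r_cut_real, k_cutoff) meeting the accuracy target."""
        tol = self.tolerance
        s = math.sqrt(2.0 * math.log(1.0 / tol))
        if self.ewald_eta is not None:
            eta = self.ewald_eta
        else:
            vol = config.volume
            eta = max(0.7, min(1.3, vol ** (1.0 / 3.0) / 6.0))
        sig_max = max(self.sigma[e] for e in set(config.species))
        gamma_max = SQRT2 * sig_max
        r_cut = self.r_cut_real
        if r_cut is None:
            r_cut = SQRT2 * max(eta, gamma_max) * erfcinv(tol)
        k_cut = self.kspace_cutoff if self.kspace_cutoff is not None else s / eta
        return eta, r_cut, k_cut

    @classmethod
    def from_text(cls, path) -> "QeqParameters":
        """Plain key-value parameter file: ``J_O 13.8`` / ``sigma_H 0.31`` /
        ``tolerance 1e-8`` / ``ewald_eta 1.0`` lines."""
        hardness: Dict[str, float] = {}
        sigma: Dict[str, float] = {}
        extra: Dict[str, float] = {}
        from pathlib import Path

        for raw in Path(path).read_text().splitlines():
            parts = raw.split()
            if not parts or parts[0].startswith("#"):
                continue
            key, val = parts[0], float(parts[1])
            if key.startswith("J_"):
                hardness[key[2:]] = val
            elif key.startswith("sigma_"):
                sigma[key[6:]] = val
            else:
                extra[key] = val
        kwargs = {}
        for name in ("ewald_eta", "r_cut_real", "kspace_cutoff", "tolerance"):
            if name in extra:
                kwargs[name] = extra[name]
        return cls(hardness=hardness, sigma=sigma, **kwargs)


@dataclass
class ChargeSolution:
    """Equilibrated charges, constraint multiplier, and energies."""

    charges: np.ndarray  # e
    multiplier: float  # eV/e
    e_elec: float  # eV (screened Coulomb + self terms)
    e_qeq: float  # eV (adds chi and hardness terms)


def pair_screened_energy(
    qi: float, qj: float, rij: float, sigma_i: float, sigma_j: float
) -> float:
    """Screened Coulomb interaction of two Gaussian charges [eV]."""
    if rij <= 0:
        raise ValueError("rij must be positive")
    gamma = math.sqrt(sigma_i**2 + sigma_j**2)
    return KE * qi * qj * erf(rij / (SQRT2 * gamma)) / rij


def self_energy(qi: float, sigma_i: float) -> float:
    """Gaussian self-interaction ke qi^2 / (2 sigma_i sqrt(pi)) [eV]."""
    if sigma_i <= 0:
        raise ValueError("sigma must be positive")
    return KE * qi * qi / (2.0 * sigma_i * math.sqrt(math.pi))


def _phi(d: np.ndarray, c: float) -> np.ndarray:
    """erf(d/(sqrt(2) c))/d."""
    return erf(d / (SQRT2 * c)) / d


def _dphi(d: np.ndarray, c: float) -> np.ndarray:
    """d/dd of erf(d/(sqrt(2) c))/d."""
    g = SQRT_2_PI / c * np.exp(-(d * d) / (2.0 * c * c))
    return g / d - erf(d / (SQRT2 * c)) / (d * d)


def _k_vectors(cell: np.ndarray, k_cut: float) -> np.ndarray:
    """Half-space reciprocal vectors with |k| <= k_cut, excluding zero."""
    recip = 2.0 * math.pi * np.linalg.inv(cell).T  # rows are b1,b2,b3
    nmax = []
    for a in range(3):
        # conservative per-axis bound from the real-space lattice vector length
        nmax.append(int(np.ceil(k_cut * np.linalg.norm(cell[a]) / (2.0 * math.pi))) + 1)
    rng = [np.arange(-n, n + 1) for n in nmax]
    ns = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    # lexicographically positive half-space
    keep = (
        (ns[:, 0] > 0)
        | ((ns[:, 0] == 0) & (ns[:, 1] > 0))
        | ((ns[:, 0] == 0) & (ns[:, 1] == 0) & (ns[:, 2] > 0))
    )
    ks = ns[keep] @ recip
    k2 = np.einsum("ij,ij->i", ks, ks)
    sel = k2 <= k_cut * k_cut
    return ks[sel]


class EwaldSystem:
    """Cached Coulomb matrix, augmented-solve factorization and gradients.

    ``A_prime`` is the pure Coulomb quadratic form (screened pairs + self
    terms, no hardness), so ``E_elec = Q^T A_prime Q / 2``.  ``A`` adds the
    per-element hardness on the diagonal.  When built with gradients, ``dA``
    holds d(A_prime[i, j])/d(R_i) so that force kernels are plain
    contractions.
    """

    def __init__(
        self,
        config: AtomicConfiguration,
        params: QeqParameters,
        gradients: bool = False,
    ):
        self.config = config
        self.params = params
        n = config.n_atoms
        sig = params.sigmas(config.species)
        self.J = params.hardnesses(config.species)
        gamma = np.sqrt(sig[:, None] ** 2 + sig[None, :] ** 2)
        pos = config.positions
        A = np.zeros((n, n))
        dA = np.zeros((n, n, 3)) if gradients else None

        if config.periodic:
            eta, r_cut, k_cut = params.resolve(config)
            vol = config.volume
            ks = _k_vectors(config.cell, k_cut)
            k2 = np.einsum("ij,ij->i", ks, ks)
            f = (8.0 * math.pi * KE / vol) * np.exp(-0.5 * eta * eta * k2) / k2
            phase = pos @ ks.T  # (n, nk)
            C = np.cos(phase)
            S = np.sin(phase)
            A += (C * f) @ C.T + (S * f) @ S.T
            A += -2.0 * math.pi * KE * eta * eta / vol  # charged-cell background
            i_idx, j_idx, rvec, dist = neighbor_list(config, r_cut)
            g_pair = gamma[i_idx, j_idx]
            terms = KE * (erf(dist / (SQRT2 * g_pair)) - erf(dist / (SQRT2 * eta))) / dist
            np.add.at(A, (i_idx, j_idx), terms)
            diag = KE * SQRT_2_PI * (1.0 / np.diag(gamma) - 1.0 / eta)
            A[np.diag_indices(n)] += diag
            if gradients:
                for c in range(3):
                    Sf = S * (f * ks[:, c])
                    Cf = C * (f * ks[:, c])
                    dA[:, :, c] = -(Sf @ C.T - Cf @ S.T)
                dterm = KE * (_dphi(dist, g_pair) - _dphi(dist, eta))
                contrib = dterm[:, None] * (-rvec / dist[:, None])
                np.add.at(dA, (i_idx, j_idx), contrib)
                dA[np.arange(n), np.arange(n), :] = 0.0
        else:
            diff = pos[None, :, :] - pos[:, None, :]
            dist = np.linalg.norm(diff, axis=-1)
            np.fill_diagonal(dist, 1.0)
            A = KE * erf(dist / (SQRT2 * gamma)) / dist
            np.fill_diagonal(A, KE * SQRT_2_PI / np.diag(gamma))
            if gradients:
                dterm = KE * _dphi(dist, gamma)
                np.fill_diagonal(dterm, 0.0)
                dA = dterm[:, :, None] * (-diff / dist[:, :, None])

        self.A_prime = 0.5 * (A + A.T)  # enforce exact symmetry
        self.A = self.A_prime + np.diag(self.J)
        self.dA = dA
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = self.A
        M[:n, n] = 1.0
        M[n, :n] = 1.0
        try:
            self._lu = lu_factor(M)
        except Exception as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(
                "augmented Qeq system is singular; check hardness/sigma parameters"
            ) from exc
        self._n = n

    # -- linear algebra ----------------------------------------------------
    def solve(self, chi: np.ndarray, total_charge: float) -> ChargeSolution:
        n = self._n
        rhs = np.empty(n + 1)
        rhs[:n] = -np.asarray(chi, dtype=float)
        rhs[n] = total_charge
        sol = lu_solve(self._lu, rhs)
        q, lam = sol[:n], float(sol[n])
        resid = self.A @ q + chi + lam
        if np.max(np.abs(resid)) > 1e-8:
            raise np.linalg.LinAlgError(
                f"Qeq stationarity residual {np.max(np.abs(resid)):.2e} eV/e; "
                "degenerate parameters"
            )
        e_elec = 0.5 * q @ self.A_prime @ q
        e_qeq = 0.5 * q @ self.A @ q + chi @ q
        return ChargeSolution(charges=q, multiplier=lam, e_elec=e_elec, e_qeq=e_qeq)

    def adjoint(self, g: np.ndarray) -> np.ndarray:
        """Solve M [u; mu] = [g; 0]; returns u (charge-response adjoint)."""
        n = self._n
        rhs = np.zeros(n + 1)
        rhs[:n] = g
        return lu_solve(self._lu, rhs)[:n]

    def energy(self, charges: np.ndarray) -> float:
        return 0.5 * float(charges @ self.A_prime @ charges)

    def pair_grad(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Gradient of u^T A_prime v with respect to every atom position."""
        if self.dA is None:
            raise RuntimeError("EwaldSystem built without gradients")
        W = np.outer(u, v) + np.outer(v, u)
        return np.einsum("aj,ajc->ac", W, self.dA)


def solve_constrained(
    A: np.ndarray, chi: np.ndarray, total_charge: float = 0.0
) -> ChargeSolution:
    """Constrained stationary point of 1/2 Q^T A Q + chi^T Q for a given A.

    Useful when the caller supplies the Qeq matrix directly (e.g. decoupled
    sites where A is just diag(J)); ``solve_qeq`` builds A from geometry.
    The returned ``e_qeq`` is the quadratic objective at the solution;
    ``e_elec`` is not separable here and is reported as 0.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = 1.0
    M[n, :n] = 1.0
    rhs = np.concatenate([-np.asarray(chi, dtype=float), [total_charge]])
    sol = np.linalg.solve(M, rhs)
    q, lam = sol[:n], float(sol[n])
    return ChargeSolution(
        charges=q,
        multiplier=lam,
        e_elec=0.0,
        e_qeq=0.5 * q @ A @ q + chi @ q,
    )


def build_A_matrix(
    config: AtomicConfiguration, params: QeqParameters, check: bool = True
) -> np.ndarray:
    """N x N symmetric Qeq matrix (hardness on the diagonal) [eV/e^2]."""
    sys_ = EwaldSystem(config, params)
    A = sys_.A
    if check and config.n_atoms > 1:
        n = config.n_atoms
        P = np.eye(n) - np.ones((n, n)) / n
        eig = np.linalg.eigvalsh(P @ A @ P)
        if eig[0] < -1e-8:
            warnings.warn(
                "Qeq matrix is not positive definite on the charge-neutral "
                "subspace; hardness parameters are ill-conditioned",
                stacklevel=2,
            )
    return A


def solve_qeq(
    config: AtomicConfiguration,
    chi: np.ndarray,
    params: QeqParameters,
    system: Optional[EwaldSystem] = None,
) -> ChargeSolution:
    """Minimize E_Qeq under the total-charge constraint (single linear solve)."""
    if system is None:
        system = EwaldSystem(config, params)
    return system.solve(np.asarray(chi, dtype=float), config.total_charge)


def electrostatic_energy(
    config: AtomicConfiguration,
    charges: np.ndarray,
    params: QeqParameters,
    system: Optional[EwaldSystem] = None,
) -> float:
    """E_elec = Q^T A' Q / 2 for given (not necessarily equilibrated) charges."""
    if system is None:
        system = EwaldSystem(config, params)
    return system.energy(np.asarray(charges, dtype=float))


def electrostatic_forces(
    config: AtomicConfiguration,
    solution: ChargeSolution,
    dchi_dpos: Optional[np.ndarray],
    params: QeqParameters,
    system: Optional[EwaldSystem] = None,
) -> np.ndarray:
    """Total derivative of E_elec(R, Q(R)) including the charge response.

    ``dchi_dpos[i, a, c]`` is d(chi_i)/d(R_a,c) from the electronegativity
    model (zero if None).  Forces are the negative total gradient.
    """
    if system is None or system.dA is None:
        system = EwaldSystem(config, params, gradients=True)
    q = solution.charges
    g = system.A_prime @ q
    u = system.adjoint(g)
    grad = 0.5 * system.pair_grad(q, q) - system.pair_grad(u, q)
    if dchi_dpos is not None:
        grad -= np.einsum("i,iac->ac", u, dchi_dpos)
    return -grad
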