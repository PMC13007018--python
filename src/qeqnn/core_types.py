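"""Domain records shared by every module.

An :class:`AtomicConfiguration` is the universal input: element symbols,
Cartesian positions in Angstrom, an optional 3x3 cell with per-axis periodic
flags, and the total charge in units of e.  Labeled configurations add the
reference energy (eV), per-atom forces (eV/A) and per-atom charges (e) that
a reference theory -- in this package the synthetic oracle -- assigns to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AtomicConfiguration",
    "LabeledConfiguration",
    "TrajectoryFrame",
]


def _as_species(species: Sequence[str]) -> np.ndarray:
    arr = np.asarray(species, dtype="U4")
    if arr.ndim != 1:
        raise ValueError("species must be a 1-D sequence of element symbols")
    return arr


@dataclass
class AtomicConfiguration:
    """Species, positions [A], optional cell [A], periodic flags, total charge [e]."""

    species: np.ndarray
    positions: np.ndarray
    cell: Optional[np.ndarray] = None
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))
    total_charge: float = 0.0

    def __post_init__(self) -> None:
        self.species = _as_species(self.species)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape != (len(self.species), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.species)} species"
            )
        self.pbc = np.asarray(self.pbc, dtype=bool).reshape(3)
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        if self.pbc.any():
            if self.cell is None:
                raise ValueError("periodic configuration requires a cell")
            if abs(np.linalg.det(self.cell)) < 1e-10:
                raise ValueError("periodic cell is singular")
        if not np.isfinite(self.total_charge):
            raise ValueError("total_charge must be finite")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def periodic(self) -> bool:
        return bool(self.pbc.any())

    @property
    def volume(self) -> float:
        if self.cell is None:
            raise ValueError("open-boundary configuration has no volume")
        return abs(float(np.linalg.det(self.cell)))

    def copy(self) -> "AtomicConfiguration":
        return AtomicConfiguration(
            species=self.species.copy(),
            positions=self.positions.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            pbc=self.pbc.copy(),
            total_charge=self.total_charge,
        )

    def with_positions(self, positions: np.ndarray) -> "AtomicConfiguration":
        new = self.copy()
        new.positions = np.asarray(positions, dtype=float).reshape(-1, 3).copy()
        if new.positions.shape[0] != self.n_atoms:
            raise ValueError("position count changed")
        return new


@dataclass
class LabeledConfiguration:
    """A configuration with reference energy/forces/charges labels."""

    configuration: AtomicConfiguration
    energy: float
    forces: np.ndarray
    charges: np.ndarray

    def __post_init__(self) -> None:
        n = self.configuration.n_atoms
        self.forces = np.asarray(self.forces, dtype=float).reshape(n, 3)
        self.charges = np.asarray(self.charges, dtype=float).reshape(n)
        if not np.isfinite(self.energy):
            raise ValueError("energy must be finite")
        if abs(self.charges.sum() - self.configuration.total_charge) > 1e-8:
            raise ValueError(
                "labeled charges do not sum to the declared total charge "
                f"({self.charges.sum():.3e} vs {self.configuration.total_charge:.3e})"
            )


@dataclass
class TrajectoryFrame:
    """One frame of a trajectory; optional per-atom columns travel with it."""

    configuration: AtomicConfiguration
    time: float = 0.0
    velocities: Optional[np.ndarray] = None  # A/fs
    charges: Optional[np.ndarray] = None  # e
    forces: Optional[np.ndarray] = None  # eV/A
    energy: Optional[float] = None  # eV
    bead_positions: Optional[np.ndarray] = None  # nbeads x N x 3

    def __post_init__(self) -> None:
        n = self.configuration.n_atoms
        if self.time < 0:
            raise ValueError("time must be non-negative")
        for name in ("velocities", "charges", "forces"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                shape = (n,) if name == "charges" else (n, 3)
                setattr(self, name, val.reshape(shape))
        if self.bead_positions is not None:
            self.bead_positions = np.asarray(self.bead_positions, dtype=float)
            if self.bead_positions.ndim != 3 or self.bead_positions.shape[1:] != (n, 3):
                raise ValueError("bead_positions must have shape (P, N, 3)")
            centroid = self.bead_positions.mean(axis=0)
            if np.max(np.abs(centroid - self.configuration.positions)) > 1e-10:
                raise ValueError("bead centroid does not match positions")


def validate_trajectory(frames: Sequence[TrajectoryFrame]) -> None:
    """Check that frame times are strictly increasing."""
    times = [f.time for f in frames]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("trajectory times must be strictly increasing")
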