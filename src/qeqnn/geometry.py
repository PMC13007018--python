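"""Periodic geometry: minimum images, neighbor lists, molecule reassembly.

Neighbor lists are built by explicit replication of the cell by however many
images the cutoff requires, so they remain correct when the cutoff exceeds
the box length (common for the small desk-scale cells used throughout).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from .core_types import AtomicConfiguration

__all__ = [
    "minimum_image_distance",
    "minimum_image_vector",
    "neighbor_list",
    "make_molecules_whole",
    "identify_molecules",
]

DEFAULT_BONDING_CUTOFFS: Dict[frozenset, float] = {frozenset(("O", "H")): 1.3}


def _image_ranges(cell: np.ndarray, pbc: np.ndarray, r_cut: float) -> np.ndarray:
    """Number of periodic images needed per axis to cover ``r_cut``."""
    # plane spacing along axis a is V / |b x c|
    vol = abs(np.linalg.det(cell))
    n = np.zeros(3, dtype=int)
    for a in range(3):
        if not pbc[a]:
            continue
        cross = np.cross(cell[(a + 1) % 3], cell[(a + 2) % 3])
        height = vol / np.linalg.norm(cross)
        n[a] = int(np.ceil(r_cut / height))
    return n


def _all_shifts(cell: np.ndarray, pbc: np.ndarray, r_cut: float) -> np.ndarray:
    n = _image_ranges(cell, pbc, r_cut)
    ranges = [np.arange(-ni, ni + 1) for ni in n]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid @ cell


def minimum_image_vector(
    config: AtomicConfiguration, i: int, j: int
) -> np.ndarray:
    """Shortest displacement vector from atom i to atom j over periodic images."""
    if i == j:
        raise ValueError("minimum image of an atom with itself is undefined")
    d = config.positions[j] - config.positions[i]
    if not config.periodic:
        return d
    cell = config.cell
    frac = np.linalg.solve(cell.T, d)
    frac = frac - np.where(config.pbc, np.round(frac), 0.0)
    d0 = cell.T @ frac
    # wrapped vector plus a shell of neighboring images covers skewed cells
    best = d0
    best_d2 = d0 @ d0
    for shift in _all_shifts(cell, config.pbc, np.sqrt(best_d2) + 1e-12):
        v = d0 + shift
        d2 = v @ v
        if d2 < best_d2 - 1e-15:
            best_d2 = d2
            best = v
    return best


def minimum_image_distance(config: AtomicConfiguration, i: int, j: int) -> float:
    """Shortest distance between atoms i and j over periodic images [A]."""
    return float(np.linalg.norm(minimum_image_vector(config, i, j)))


def neighbor_list(
    config: AtomicConfiguration, r_cut: float, r_min: float = 1e-8
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All directed pairs (i, j, image) with r_min < |r_j + L - r_i| < r_cut.

    Returns ``(i_idx, j_idx, rvec, dist)`` where ``rvec = r_j + L - r_i``.
    Self pairs ``i == j`` appear only through nonzero image shifts.
    """
    pos = config.positions
    n = len(pos)
    if config.periodic:
        # wrap into the fundamental cell so far-flung images are reachable
        frac = np.linalg.solve(config.cell.T, pos.T).T
        frac -= np.where(config.pbc, np.floor(frac), 0.0)
        pos = frac @ config.cell
        shifts = _all_shifts(config.cell, config.pbc, r_cut)
    else:
        shifts = np.zeros((1, 3))
    # displacement tensor: (n_i, n_j, n_s, 3)
    disp = pos[None, :, None, :] + shifts[None, None, :, :] - pos[:, None, None, :]
    dist = np.linalg.norm(disp, axis=-1)
    mask = (dist < r_cut) & (dist > r_min)
    i_idx, j_idx, s_idx = np.nonzero(mask)
    return i_idx, j_idx, disp[i_idx, j_idx, s_idx], dist[i_idx, j_idx, s_idx]


def _bond_cutoff(table: Dict[frozenset, float], a: str, b: str) -> float:
    return table.get(frozenset((a, b)), 0.0)


def identify_molecules(
    config: AtomicConfiguration,
    bonding_cutoffs: Optional[Dict[frozenset, float]] = None,
) -> np.ndarray:
    """Molecule index per atom from minimum-image bond connectivity."""
    table = bonding_cutoffs or DEFAULT_BONDING_CUTOFFS
    r_max = max(table.values()) if table else 0.0
    i_idx, j_idx, _, dist = neighbor_list(config, r_max + 1e-9)
    adj: Dict[int, list] = {i: [] for i in range(config.n_atoms)}
    for i, j, d in zip(i_idx, j_idx, dist):
        if i != j and d <= _bond_cutoff(table, config.species[i], config.species[j]):
            adj[int(i)].append(int(j))
    mol = -np.ones(config.n_atoms, dtype=int)
    current = 0
    for start in range(config.n_atoms):
        if mol[start] >= 0:
            continue
        stack = [start]
        mol[start] = current
        while stack:
            a = stack.pop()
            for b in adj[a]:
                if mol[b] < 0:
                    mol[b] = current
                    stack.append(b)
        current += 1
    return mol


def make_molecules_whole(
    config: AtomicConfiguration,
    bonding_cutoffs: Optional[Dict[frozenset, float]] = None,
) -> Tuple[AtomicConfiguration, np.ndarray]:
    """Translate atoms by lattice vectors so no molecule crosses the boundary.

    Returns the reassembled configuration and the molecule index per atom.
    Intramolecular connectivity is resolved with minimum-image vectors; a
    molecule whose reassembled extent exceeds half the smallest box height is
    rejected as ambiguous.
    """
    if not config.periodic:
        return config.copy(), identify_molecules(config, bonding_cutoffs)
    table = bonding_cutoffs or DEFAULT_BONDING_CUTOFFS
    mol = identify_molecules(config, table)
    r_max = max(table.values()) if table else 0.0
    i_idx, j_idx, rvec, dist = neighbor_list(config, r_max + 1e-9)
    bonds: Dict[int, list] = {i: [] for i in range(config.n_atoms)}
    for i, j, v, d in zip(i_idx, j_idx, rvec, dist):
        if i != j and d <= _bond_cutoff(table, config.species[i], config.species[j]):
            bonds[int(i)].append((int(j), v))
    new_pos = config.positions.copy()
    placed = np.zeros(config.n_atoms, dtype=bool)
    for start in range(config.n_atoms):
        if placed[start]:
            continue
        placed[start] = True
        stack = [start]
        while stack:
            a = stack.pop()
            for b, v in bonds[a]:
                if not placed[b]:
                    new_pos[b] = new_pos[a] + v
                    placed[b] = True
                    stack.append(b)
    out = config.with_positions(new_pos)
    # sanity: molecules must stay compact
    vol = config.volume
    heights = [
        vol / np.linalg.norm(np.cross(config.cell[(a + 1) % 3], config.cell[(a + 2) % 3]))
        for a in range(3)
        if config.pbc[a]
    ]
    half_min = 0.5 * min(heights) if heights else np.inf
    for m in range(mol.max() + 1):
        sel = new_pos[mol == m]
        if len(sel) > 1 and np.max(sel.max(axis=0) - sel.min(axis=0)) > half_min:
            raise ValueError(
                f"molecule {m} spans more than half the box; minimum-image "
                "reconstruction is ambiguous"
            )
    return out, mol


def molecule_formula(config: AtomicConfiguration, mol: np.ndarray, m: int) -> str:
    symbols, counts = np.unique(config.species[mol == m], return_counts=True)
    return "".join(f"{s}{c}" for s, c in zip(symbols, counts))
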