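"""Readers and writers: extended XYZ, HDF5 labeled datasets, RuNNer imports.

Extended XYZ follows the de-facto convention: a ``Lattice="ax ay az ..."``
key, a ``Properties=species:S:1:pos:R:3[:charge:R:1][:forces:R:3][:vel:R:3]``
column descriptor, and free ``key=value`` pairs (energy, time, pbc,
total_charge) in the comment line.
"""

from __future__ import annotations

import shlex
from pathlib import Path
from typing import List, Optional, Sequence, Union

import h5py
import numpy as np

from .core_types import AtomicConfiguration, LabeledConfiguration, TrajectoryFrame

__all__ = [
    "read_extxyz",
    "write_extxyz",
    "save_dataset",
    "load_dataset",
    "read_runner_data",
    "labeled_to_frame",
    "frame_to_labeled",
]

BOHR = 0.529177210903  # A
HARTREE = 27.211386245988  # eV


class ExtxyzParseError(ValueError):
    pass


def _parse_comment(line: str) -> dict:
    out = {}
    for token in shlex.split(line):
        if "=" not in token:
            out[token] = True
            continue
        key, val = token.split("=", 1)
        out[key] = val
    return out


def _parse_properties(spec: str):
    fields = spec.split(":")
    if len(fields) % 3 != 0:
        raise ExtxyzParseError(f"malformed Properties spec {spec!r}")
    cols = []
    for name, kind, width in zip(fields[0::3], fields[1::3], fields[2::3]):
        cols.append((name, kind, int(width)))
    return cols


def _parse_bool_triplet(text: str) -> np.ndarray:
    vals = text.replace('"', "").split()
    return np.array([v.upper().startswith("T") or v == "1" for v in vals], dtype=bool)


def read_extxyz(path: Union[str, Path]) -> List[TrajectoryFrame]:
    """Parse an extended-XYZ file into trajectory frames.

    A missing ``Lattice`` key gives an open-boundary configuration with all
    periodic flags false.  Per-atom ``charge``/``forces``/``vel`` columns are
    attached to the frame when present.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: List[TrajectoryFrame] = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise ExtxyzParseError(
                f"{path}:{ln + 1}: expected an atom count, got {lines[ln]!r}"
            ) from None
        if ln + 1 + natoms >= len(lines) + 1 and natoms > 0:
            pass
        if ln + 1 >= len(lines):
            raise ExtxyzParseError(f"{path}:{ln + 1}: missing comment line")
        meta = _parse_comment(lines[ln + 1])
        props = _parse_properties(meta.get("Properties", "species:S:1:pos:R:3"))
        body = lines[ln + 2 : ln + 2 + natoms]
        if len(body) < natoms:
            raise ExtxyzParseError(
                f"{path}:{ln + 1}: frame declares {natoms} atoms but only "
                f"{len(body)} atom lines follow"
            )
        ncols = sum(w for _, _, w in props)
        table = []
        for k, row in enumerate(body):
            parts = row.split()
            if len(parts) != ncols:
                raise ExtxyzParseError(
                    f"{path}:{ln + 3 + k}: expected {ncols} columns, got {len(parts)}"
                )
            table.append(parts)
        columns = {}
        ofs = 0
        for name, kind, width in props:
            block = [row[ofs : ofs + width] for row in table]
            if kind == "S":
                columns[name] = np.array([b[0] for b in block], dtype="U4")
            else:
                columns[name] = np.array(block, dtype=float)
                if width == 1:
                    columns[name] = columns[name].ravel()
            ofs += width
        cell = None
        pbc = np.zeros(3, dtype=bool)
        if "Lattice" in meta:
            vals = np.fromstring(meta["Lattice"].replace('"', ""), sep=" ")
            if vals.size != 9:
                raise ExtxyzParseError(f"{path}:{ln + 2}: bad Lattice entry")
            cell = vals.reshape(3, 3)
            pbc = (
                _parse_bool_triplet(meta["pbc"])
                if "pbc" in meta
                else np.ones(3, dtype=bool)
            )
        config = AtomicConfiguration(
            species=columns["species"],
            positions=columns["pos"],
            cell=cell,
            pbc=pbc,
            total_charge=float(meta.get("total_charge", 0.0)),
        )
        charges = columns.get("charge")
        if charges is not None:
            if abs(charges.sum() - config.total_charge) > 1e-6:
                raise ExtxyzParseError(
                    f"{path}:{ln + 2}: per-atom charges sum to {charges.sum():.6f}"
                    f" but total_charge={config.total_charge:.6f}"
                )
        frames.append(
            TrajectoryFrame(
                configuration=config,
                time=float(meta.get("time", len(frames))),
                velocities=columns.get("vel"),
                charges=charges,
                forces=columns.get("forces"),
                energy=float(meta["energy"]) if "energy" in meta else None,
            )
        )
        ln += 2 + natoms
    return frames


def _fmt(x: float) -> str:
    return f"{x:.12f}"


def write_extxyz(
    frames: Sequence[Union[TrajectoryFrame, AtomicConfiguration]],
    path: Union[str, Path],
) -> None:
    """Write frames as concatenated extended-XYZ blocks (re-readable round trip)."""
    if len(frames) == 0:
        raise ValueError("refusing to write an empty frame list")
    out_lines: List[str] = []
    for frame in frames:
        if isinstance(frame, AtomicConfiguration):
            frame = TrajectoryFrame(configuration=frame)
        cfg = frame.configuration
        props = "species:S:1:pos:R:3"
        cols: List[np.ndarray] = [cfg.positions]
        if frame.charges is not None:
            props += ":charge:R:1"
            cols.append(frame.charges.reshape(-1, 1))
        if frame.forces is not None:
            props += ":forces:R:3"
            cols.append(frame.forces)
        if frame.velocities is not None:
            props += ":vel:R:3"
            cols.append(frame.velocities)
        meta = [f"Properties={props}"]
        if cfg.cell is not None:
            lat = " ".join(_fmt(v) for v in cfg.cell.ravel())
            meta.insert(0, f'Lattice="{lat}"')
            meta.append(
                'pbc="%s"' % " ".join("T" if b else "F" for b in cfg.pbc)
            )
        meta.append(f"time={frame.time:.6f}")
        meta.append(f"total_charge={cfg.total_charge:.10f}")
        if frame.energy is not None:
            meta.append(f"energy={frame.energy:.12f}")
        out_lines.append(str(cfg.n_atoms))
        out_lines.append(" ".join(meta))
        data = np.hstack(cols)
        for sym, row in zip(cfg.species, data):
            out_lines.append(sym + " " + " ".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(out_lines) + "\n")


def labeled_to_frame(labeled: LabeledConfiguration, time: float = 0.0) -> TrajectoryFrame:
    return TrajectoryFrame(
        configuration=labeled.configuration,
        time=time,
        charges=labeled.charges,
        forces=labeled.forces,
        energy=labeled.energy,
    )


def frame_to_labeled(frame: TrajectoryFrame) -> LabeledConfiguration:
    if frame.energy is None or frame.forces is None or frame.charges is None:
        raise ValueError("frame lacks energy/forces/charges labels")
    return LabeledConfiguration(
        configuration=frame.configuration,
        energy=frame.energy,
        forces=frame.forces,
        charges=frame.charges,
    )


def save_dataset(
    labeled: Sequence[LabeledConfiguration], path: Union[str, Path]
) -> None:
    """Store a labeled dataset in an HDF5 container, one group per frame."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "qeqnn-dataset-1"
        for k, lab in enumerate(labeled):
            g = fh.create_group(f"frame_{k:06d}")
            cfg = lab.configuration
            g.create_dataset("species", data=cfg.species.astype("S4"))
            g.create_dataset("positions", data=cfg.positions)
            if cfg.cell is not None:
                g.create_dataset("cell", data=cfg.cell)
            g.create_dataset("pbc", data=cfg.pbc)
            g.attrs["total_charge"] = cfg.total_charge
            g.attrs["energy"] = lab.energy
            g.create_dataset("forces", data=lab.forces)
            g.create_dataset("charges", data=lab.charges)


def load_dataset(path: Union[str, Path]) -> List[LabeledConfiguration]:
    out: List[LabeledConfiguration] = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            g = fh[key]
            cfg = AtomicConfiguration(
                species=np.array([s.decode() for s in g["species"][()]]),
                positions=g["positions"][()],
                cell=g["cell"][()] if "cell" in g else None,
                pbc=g["pbc"][()],
                total_charge=float(g.attrs["total_charge"]),
            )
            out.append(
                LabeledConfiguration(
                    configuration=cfg,
                    energy=float(g.attrs["energy"]),
                    forces=g["forces"][()],
                    charges=g["charges"][()],
                )
            )
    return out


def read_runner_data(path: Union[str, Path]) -> List[LabeledConfiguration]:
    """Read RuNNer/n2p2-style ``input.data`` blocks (read-only convenience).

    RuNNer files are in Bohr and Hartree; values are converted to A and eV.
    """
    out: List[LabeledConfiguration] = []
    species: List[str] = []
    pos: List[List[float]] = []
    forces: List[List[float]] = []
    charges: List[float] = []
    lattice: List[List[float]] = []
    energy: Optional[float] = None
    total_charge = 0.0
    f_conv = HARTREE / BOHR
    for raw in Path(path).read_text().splitlines():
        parts = raw.split()
        if not parts:
            continue
        tag = parts[0].lower()
        if tag == "begin":
            species, pos, forces, charges, lattice = [], [], [], [], []
            energy, total_charge = None, 0.0
        elif tag == "lattice":
            lattice.append([float(x) * BOHR for x in parts[1:4]])
        elif tag == "atom":
            pos.append([float(x) * BOHR for x in parts[1:4]])
            species.append(parts[4])
            charges.append(float(parts[5]))
            forces.append([float(x) * f_conv for x in parts[7:10]])
        elif tag == "energy":
            energy = float(parts[1]) * HARTREE
        elif tag == "charge":
            total_charge = float(parts[1])
        elif tag == "end":
            cell = np.array(lattice) if lattice else None
            cfg = AtomicConfiguration(
                species=species,
                positions=np.array(pos),
                cell=cell,
                pbc=np.array([cell is not None] * 3),
                total_charge=total_charge,
            )
            out.append(
                LabeledConfiguration(
                    configuration=cfg,
                    energy=energy if energy is not None else 0.0,
                    forces=np.array(forces),
                    charges=np.array(charges),
                )
            )
    return out
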