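"""Structure and trajectory I/O.

PDB files (single- and multi-model) are read through :mod:`gemmi` and written by a
fixed-column formatter.  A whitespace XYZ-per-frame text format is provided for
synthetic fixtures.  Coordinates are Å throughout; frame times default to
``index * stride`` (ns).
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import yaml

from .exceptions import ConfigurationError, IntegrityError, PDBParseError
from .model import AtomTable, Frame, Trajectory

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "write_xyz",
    "read_xyz",
    "load_config",
]


def _model_to_frame(model: gemmi.Model, time: float = 0.0) -> Frame:
    names, res_names, res_seqs, chains, elements, serials, xyz = [], [], [], [], [], [], []
    dropped_altloc = 0
    for chain in model:
        for residue in chain:
            if residue.seqid.icode not in ("", " "):
                raise PDBParseError(
                    f"insertion code {residue.seqid.icode!r} at {chain.name} {residue.seqid.num}: "
                    "insertion codes are not supported; renumber the input"
                )
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    dropped_altloc += 1
                    continue
                names.append(atom.name)
                res_names.append(residue.name)
                res_seqs.append(residue.seqid.num)
                chains.append(chain.name)
                elements.append(atom.element.name if atom.element else "X")
                serials.append(atom.serial)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if dropped_altloc:
        warnings.warn(f"dropped {dropped_altloc} alternate-location atoms (kept altloc '' or 'A')")
    if not names:
        raise PDBParseError("model contains no atoms")
    table = AtomTable(names, res_names, res_seqs, chains, element=elements, serial=serials)
    return Frame(table, np.asarray(xyz), time=time)


def _read_gemmi(path: str | os.PathLike) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    return st


def read_structure(path: str | os.PathLike, model: int = 0) -> Frame:
    """Read one model of a PDB file as a :class:`Frame`.

    All ATOM and HETATM records are retained; alternate locations other than
    '' / 'A' are dropped with a warning; insertion codes are rejected.
    """
    st = _read_gemmi(path)
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models")
    return _model_to_frame(st[model])


def read_trajectory(
    paths: str | os.PathLike | Sequence[str | os.PathLike],
    stride: float = 0.1,
    times: Sequence[float] | None = None,
) -> Trajectory:
    """Read a multi-model PDB file, or a sequence of frame-per-file paths, as a trajectory.

    Frames are time-stamped ``i * stride`` ns unless explicit ``times`` are given.
    All frames must share an identical atom table.
    """
    if isinstance(paths, (str, os.PathLike)):
        st = _read_gemmi(paths)
        frames = [_model_to_frame(m) for m in st]
    else:
        frames = [read_structure(p) for p in paths]
    if not frames:
        raise PDBParseError("no frames found")
    traj = Trajectory.from_frames(frames, stride=stride)
    if times is not None:
        traj = Trajectory(traj.table, traj.coords, times=np.asarray(times, float), stride=stride)
    return traj


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: names of 1-3 chars start in column 14 unless a 2-char element.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def _pdb_atom_line(serial, name, res_name, chain, res_seq, element, x, y, z, het: bool) -> str:
    record = "HETATM" if het else "ATOM  "
    return (
        f"{record}{serial % 100000:5d} {_format_atom_name(name, element)} "
        f"{res_name:>3.3s} {chain[:1]:1s}{res_seq % 10000:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2.2s}\n"
    )


def write_pdb(
    obj: Frame | Trajectory,
    path: str | os.PathLike,
    bfactors: np.ndarray | None = None,
) -> None:
    """Write a frame (single model) or trajectory (MODEL/ENDMDL blocks) as fixed-column PDB.

    ``bfactors`` (per atom) replaces the B-factor column when given — used by the
    essential-dynamics CLI to colour extreme structures by displacement magnitude.
    """
    frames = [obj] if isinstance(obj, Frame) else list(obj)
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for imodel, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL {imodel:8d}\n")
            t = frame.table
            for i in range(frame.n_atoms):
                het = str(t.res_name[i]) not in _PROTEIN_AND_NUC
                line = _pdb_atom_line(
                    int(t.serial[i]), str(t.name[i]), str(t.res_name[i]), str(t.chain[i]),
                    int(t.res_seq[i]), str(t.element[i]), *frame.coords[i], het,
                )
                if bfactors is not None:
                    line = line[:60] + f"{float(bfactors[i]):6.2f}" + line[66:]
                fh.write(line)
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


_PROTEIN_AND_NUC = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


def write_xyz(traj: Trajectory, path: str | os.PathLike) -> None:
    """Whitespace XYZ-per-frame text format (synthetic-fixture convenience)."""
    t = traj.table
    with open(path, "w") as fh:
        fh.write(f"{traj.n_atoms} {traj.n_frames}\n")
        for i in range(traj.n_atoms):
            fh.write(
                f"{int(t.serial[i])} {t.name[i]} {t.res_name[i]} {int(t.res_seq[i])} "
                f"{t.chain[i]} {t.element[i]}\n"
            )
        for k in range(traj.n_frames):
            fh.write(f"frame {traj.times[k]:.6f}\n")
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[k, i]
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | os.PathLike) -> Trajectory:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise PDBParseError(f"{path}: bad XYZ header")
        n_atoms, n_frames = int(header[0]), int(header[1])
        serial, name, res_name, res_seq, chain, element = [], [], [], [], [], []
        for _ in range(n_atoms):
            parts = fh.readline().split()
            if len(parts) != 6:
                raise PDBParseError(f"{path}: bad atom-table line {parts}")
            serial.append(int(parts[0]))
            name.append(parts[1])
            res_name.append(parts[2])
            res_seq.append(int(parts[3]))
            chain.append(parts[4])
            element.append(parts[5])
        table = AtomTable(name, res_name, res_seq, chain, element=element, serial=serial)
        coords = np.empty((n_frames, n_atoms, 3))
        times = np.empty(n_frames)
        for k in range(n_frames):
            tag = fh.readline().split()
            if len(tag) != 2 or tag[0] != "frame":
                raise PDBParseError(f"{path}: expected frame header, got {tag}")
            times[k] = float(tag[1])
            for i in range(n_atoms):
                coords[k, i] = [float(v) for v in fh.readline().split()]
    return Trajectory(table, coords, times=times)


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML config with optional [bwmap], [selections], [thresholds] sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config root must be a mapping")
    for key in cfg:
        if key not in {"bwmap", "selections", "thresholds"}:
            raise ConfigurationError(f"{path}: unknown config section {key!r}")
    return cfg
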