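"""Structures and trajectories: the uniform in-memory model and its text formats.

Everything downstream (leaflet geometry, salt bridges, domain derivation,
threading) consumes the :class:`Structure` / :class:`Trajectory` pair defined
here.  Coordinates are always Ångström internally; GRO files (nm) are
converted on read.  Residue numbering is taken verbatim from the file and is
never renumbered, so author numbering such as K568 or I371 survives a round
trip.

Supported formats
-----------------
* PDB (``ATOM``/``HETATM``/``MODEL``/``ENDMDL``/``CRYST1``), read and write,
  including multi-model files as trajectories.  A fixed-width codec with the
  GROMACS convention for residue names (columns 18-21) is used so that
  four-character lipid codes like ``POPC`` survive intact.
* GRO, read only, via :mod:`biotite` (nm converted to Å).
* Extended XYZ with a ``Lattice="..."``/``Time=...`` comment line, read and
  write, as the lightweight trajectory interchange format.

Binary MD containers (XTC/DCD) are deliberately not handled here.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Particle",
    "Structure",
    "Frame",
    "Trajectory",
    "StructureError",
    "ParseError",
    "TopologyError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
]


class StructureError(ValueError):
    """Invalid structure/trajectory content (duplicates, count mismatches...)."""


class ParseError(StructureError):
    """A file could not be parsed; the message names the offending line."""


class TopologyError(StructureError):
    """A frame is inconsistent with the topology it claims to instantiate."""


@dataclass(frozen=True)
class Particle:
    """One atom or coarse-grained bead.

    ``name`` is the particle name as written in the file (``CA``, ``PO4``,
    ``NC3``, ``BB`` ...); ``residue_name`` a 3-letter amino-acid code or a
    lipid code such as ``POPC``.
    """

    particle_id: int
    name: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(
                f"particle {self.chain_id}/{self.residue_number}/{self.name}: "
                f"position must be a finite 3-vector, got {self.position!r}"
            )
        object.__setattr__(self, "position", pos)


class Structure:
    """An ordered list of particles plus an optional orthorhombic box (Å).

    The particle order is canonical: every :class:`Frame` of a trajectory
    indexes positions in exactly this order.  ``(chain_id, residue_number,
    name)`` must be unique.
    """

    def __init__(self, particles: Sequence[Particle], box: np.ndarray | None = None):
        self.particles: list[Particle] = list(particles)
        self.box = None if box is None else np.asarray(box, dtype=float)
        if self.box is not None and self.box.shape != (3,):
            raise StructureError(f"box must be a 3-vector of lengths, got {box!r}")
        seen: set[tuple[str, int, str]] = set()
        for p in self.particles:
            key = (p.chain_id, p.residue_number, p.name)
            if key in seen:
                raise StructureError(f"duplicate particle key {key}")
            seen.add(key)
        self._residue_index: dict[tuple[str, int], list[int]] | None = None

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of positions in canonical order."""
        return np.array([p.position for p in self.particles], dtype=float)

    def residue_particle_indices(self) -> dict[tuple[str, int], list[int]]:
        """Map (chain_id, residue_number) -> particle indices, cached."""
        if self._residue_index is None:
            idx: dict[tuple[str, int], list[int]] = {}
            for i, p in enumerate(self.particles):
                idx.setdefault((p.chain_id, p.residue_number), []).append(i)
            self._residue_index = idx
        return self._residue_index

    def particles_of(self, chain_id: str, residue_number: int) -> list[int]:
        try:
            return self.residue_particle_indices()[(chain_id, residue_number)]
        except KeyError:
            raise StructureError(
                f"residue {chain_id}/{residue_number} not present in structure"
            ) from None

    def index_of(self, chain_id: str, residue_number: int, name: str) -> int:
        for i in self.particles_of(chain_id, residue_number):
            if self.particles[i].name == name:
                return i
        raise StructureError(
            f"particle {name} of residue {chain_id}/{residue_number} not found"
        )

    def residue_name_of(self, chain_id: str, residue_number: int) -> str:
        return self.particles[self.particles_of(chain_id, residue_number)[0]].residue_name

    def with_positions(self, positions: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (same topology)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self), 3):
            raise StructureError(
                f"expected positions of shape ({len(self)}, 3), got {positions.shape}"
            )
        parts = [
            Particle(p.particle_id, p.name, p.residue_number, p.residue_name,
                     p.chain_id, positions[i])
            for i, p in enumerate(self.particles)
        ]
        return Structure(parts, box=self.box)


@dataclass
class Frame:
    """Per-frame coordinate set, in the topology's canonical particle order."""

    time_ns: float
    positions: np.ndarray  # (N, 3), Å
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise StructureError(f"frame positions must be (N, 3), got {self.positions.shape}")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)


class Trajectory:
    """A topology plus an ordered list of frames with strictly increasing times."""

    def __init__(self, topology: Structure, frames: Sequence[Frame]):
        self.topology = topology
        self.frames: list[Frame] = list(frames)
        n = len(topology)
        for i, fr in enumerate(self.frames):
            if fr.positions.shape[0] != n:
                raise TopologyError(
                    f"frame {i} has {fr.positions.shape[0]} particles, topology has {n}"
                )
        times = [fr.time_ns for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise StructureError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times_ns(self) -> np.ndarray:
        return np.array([fr.time_ns for fr in self.frames], dtype=float)

    def position_stack(self) -> np.ndarray:
        """(n_frames, N, 3) array; the workhorse layout for vectorised analysis."""
        return np.stack([fr.positions for fr in self.frames])


# ---------------------------------------------------------------------------
# PDB codec.  Fixed-width per the PDB v3 ATOM record, with the GROMACS
# convention of letting 4-character residue names occupy columns 18-21.
# ---------------------------------------------------------------------------

def _parse_pdb_atom(line: str, lineno: int) -> tuple[str, int, str, str, np.ndarray]:
    try:
        name = line[12:16].strip()
        res_name = line[17:21].strip()
        chain_id = line[21].strip() or " "
        res_num = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM/HETATM record: {line.rstrip()!r}") from exc
    return name, res_num, res_name, chain_id, np.array([x, y, z])


def _parse_pdb_models(text: str) -> tuple[list[list[tuple]], np.ndarray | None]:
    """Return per-model atom tuples and the CRYST1 box lengths if present."""
    models: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    box = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: malformed CRYST1 record") from exc
        elif rec == "MODEL":
            if current:
                models.append(current)
                current = []
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_pdb_atom(line, lineno))
    if current or not models:
        models.append(current)
    del in_model
    return models, box


def _structure_from_atoms(atoms: list[tuple], box: np.ndarray | None) -> Structure:
    particles = [
        Particle(i, name, res_num, res_name, chain_id, pos)
        for i, (name, res_num, res_name, chain_id, pos) in enumerate(atoms)
    ]
    return Structure(particles, box=box)


_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _pdb_atom_line(serial: int, p: Particle, pos: np.ndarray) -> str:
    rec = "ATOM  " if p.residue_name in _AMINO3 else "HETATM"
    name = p.name if len(p.name) >= 4 else f" {p.name:<3s}"
    return (
        f"{rec}{min(serial, 99999):5d} {name:<4.4s} {p.residue_name:<4.4s}"
        f"{p.chain_id[:1]}{p.residue_number:4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00"
    )


def _write_pdb(structure: Structure, frames: Iterable[Frame] | None, fh: io.TextIOBase) -> None:
    box = structure.box
    if frames is not None:
        frames = list(frames)
        if frames and frames[0].box is not None:
            box = frames[0].box
    if box is not None:
        fh.write(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            "  90.00  90.00  90.00 P 1           1\n"
        )
    if frames is None:
        for i, p in enumerate(structure.particles):
            fh.write(_pdb_atom_line(i + 1, p, p.position) + "\n")
        fh.write("END\n")
        return
    for m, frame in enumerate(frames, start=1):
        fh.write(f"MODEL     {m:4d}\n")
        for i, p in enumerate(structure.particles):
            fh.write(_pdb_atom_line(i + 1, p, frame.positions[i]) + "\n")
        fh.write("ENDMDL\n")
    fh.write("END\n")


# ---------------------------------------------------------------------------
# Extended XYZ codec.  Frame header: particle count, then a comment line
#   Lattice="ax 0 0 0 by 0 0 0 cz" Time=<ns>
# followed by one "name x y z" line per particle in topology order.
# ---------------------------------------------------------------------------

def _xyz_comment(time_ns: float, box: np.ndarray | None) -> str:
    parts = []
    if box is not None:
        parts.append(
            f'Lattice="{box[0]:.6f} 0 0 0 {box[1]:.6f} 0 0 0 {box[2]:.6f}"'
        )
    parts.append(f"Time={time_ns:.6f}")
    return " ".join(parts)


def _parse_xyz_comment(line: str) -> tuple[float | None, np.ndarray | None]:
    time_ns = None
    box = None
    if 'Lattice="' in line:
        inner = line.split('Lattice="', 1)[1].split('"', 1)[0]
        vals = [float(v) for v in inner.split()]
        if len(vals) == 9:
            box = np.array([vals[0], vals[4], vals[8]])
        elif len(vals) == 3:
            box = np.array(vals)
    for tok in line.replace('"', " ").split():
        if tok.startswith("Time="):
            try:
                time_ns = float(tok[5:])
            except ValueError:
                pass
    return time_ns, box


def _read_xyz_frames(text: str) -> list[tuple[float | None, np.ndarray | None, list[str], np.ndarray]]:
    lines = text.splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected particle count, got {lines[i]!r}")
        if i + 1 + n >= len(lines) + 1 and i + 1 + n > len(lines):
            raise ParseError(f"line {i + 1}: frame declares {n} particles but file is truncated")
        time_ns, box = _parse_xyz_comment(lines[i + 1] if i + 1 < len(lines) else "")
        names: list[str] = []
        coords = np.empty((n, 3))
        for k in range(n):
            lineno = i + 2 + k
            try:
                toks = lines[lineno].split()
                names.append(toks[0])
                coords[k] = [float(toks[1]), float(toks[2]), float(toks[3])]
            except (IndexError, ValueError) as exc:
                raise ParseError(f"line {lineno + 1}: malformed XYZ particle record") from exc
        frames.append((time_ns, box, names, coords))
        i += 2 + n
    return frames


def _write_xyz(structure: Structure, frames: Iterable[Frame], fh: io.TextIOBase) -> None:
    names = [p.name for p in structure.particles]
    for frame in frames:
        fh.write(f"{len(names)}\n")
        fh.write(_xyz_comment(frame.time_ns, frame.box if frame.box is not None else structure.box) + "\n")
        for name, pos in zip(names, frame.positions):
            fh.write(f"{name} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}\n")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fallback: str | None) -> str:
    if fallback is not None:
        return fallback
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "gro", "xyz"):
        return suffix
    raise StructureError(f"cannot infer format from {path.name!r}; pass format=...")


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a single structure from a PDB or GRO file.

    Coordinates are returned in Å (GRO nm values converted); residue
    numbering and names are preserved verbatim.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        models, box = _parse_pdb_models(path.read_text())
        if not models or not models[0]:
            raise ParseError(f"{path}: no ATOM/HETATM records found")
        return _structure_from_atoms(models[0], box)
    if fmt == "gro":
        from biotite.structure.io.gro import GROFile

        gro = GROFile.read(str(path))
        arr = gro.get_structure(model=1)
        particles = []
        for i in range(arr.array_length()):
            chain = str(arr.chain_id[i]).strip() or " "
            particles.append(
                Particle(i, str(arr.atom_name[i]), int(arr.res_id[i]),
                         str(arr.res_name[i]), chain, arr.coord[i])
            )
        box = None
        if arr.box is not None:
            box = np.array([arr.box[0, 0], arr.box[1, 1], arr.box[2, 2]])
        return Structure(particles, box=box)
    raise StructureError(f"unsupported structure format {fmt!r}")


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file."""
    path = Path(path)
    with path.open("w") as fh:
        _write_pdb(structure, None, fh)


def read_trajectory(
    path: str | Path,
    topology: Structure,
    format: str | None = None,
    stride_ns: float = 5.0,
) -> Trajectory:
    """Read a multi-model PDB or extended-XYZ trajectory against a topology.

    Frames missing time metadata are numbered 0, ``stride_ns``,
    2 × ``stride_ns``, ... (the default stride mirrors a 5 ns save interval).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    frames: list[Frame] = []
    n_top = len(topology)
    if fmt == "pdb":
        models, box = _parse_pdb_models(path.read_text())
        for i, atoms in enumerate(models):
            if len(atoms) != n_top:
                raise TopologyError(
                    f"frame {i}: {len(atoms)} particles, topology has {n_top}"
                )
            coords = np.array([a[4] for a in atoms])
            frames.append(Frame(time_ns=i * stride_ns, positions=coords, box=box))
    elif fmt == "xyz":
        for i, (time_ns, box, names, coords) in enumerate(_read_xyz_frames(path.read_text())):
            if len(names) != n_top:
                raise TopologyError(
                    f"frame {i}: {len(names)} particles, topology has {n_top}"
                )
            t = time_ns if time_ns is not None else i * stride_ns
            frames.append(Frame(time_ns=t, positions=coords, box=box))
    else:
        raise StructureError(f"unsupported trajectory format {fmt!r}")
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(topology, frames)


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or extended XYZ.

    Positions survive the round trip to <= 1e-3 Å (PDB) / 1e-6 Å (XYZ).
    """
    if len(traj) == 0:
        raise StructureError("cannot write an empty trajectory")
    path = Path(path)
    fmt = _infer_format(path, format)
    with path.open("w") as fh:
        if fmt == "pdb":
            _write_pdb(traj.topology, traj.frames, fh)
        elif fmt == "xyz":
            _write_xyz(traj.topology, traj.frames, fh)
        else:
            raise StructureError(f"unsupported trajectory format {fmt!r}")
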