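"""Structure, trajectory and sequence I/O plus an atom-selection mini-language.

The package works on a deliberately small slice of the PDB format: ATOM/HETATM
records with MODEL/ENDMDL for multi-frame files.  Coordinates are in Å, residue
numbering is 1-based, insertion codes are rejected, and for multi-model files
only the first model is kept (trajectories are read separately with
:func:`read_trajectory`).  Hydrogens are optional everywhere: all downstream
geometric criteria are defined on heavy atoms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Atom",
    "Structure",
    "Complex",
    "Trajectory",
    "SequenceRecord",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "read_fasta",
    "write_fasta",
    "select",
    "PDBParseError",
    "SelectionError",
]

WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL"})

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class PDBParseError(ValueError):
    """Raised for malformed PDB/XYZ input; message carries the line number."""


class SelectionError(ValueError):
    """Raised when a selection expression cannot be parsed or resolved."""


@dataclass
class Atom:
    """A single atom record (PDB naming conventions, coordinates in Å)."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resid, self.name)


class Structure:
    """An ordered list of atoms with a chain → residue index.

    Residues are expected to be contiguous per chain in file order; the
    ``(chain, resid, name)`` triple is unique.
    """

    def __init__(self, atoms: Iterable[Atom], title: str = "") -> None:
        self.atoms: list[Atom] = list(atoms)
        self.title = title
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            k = a.key()
            if k in seen:
                raise ValueError(f"duplicate atom record {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å (a copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {xyz.shape} does not match atom count {len(self.atoms)}")
        for a, row in zip(self.atoms, xyz):
            a.coords = row.copy()

    def with_coords(self, xyz: np.ndarray, title: str | None = None) -> "Structure":
        """A deep-ish copy of the structure carrying new coordinates."""
        xyz = np.asarray(xyz, dtype=float)
        atoms = [
            Atom(a.serial, a.name, a.element, a.resname, a.resid, a.chain, row, a.occupancy, a.bfactor)
            for a, row in zip(self.atoms, xyz)
        ]
        return Structure(atoms, title if title is not None else self.title)

    def copy(self) -> "Structure":
        return self.with_coords(self.coords)

    @property
    def chains(self) -> dict[str, dict[int, list[int]]]:
        """chain → resid → atom index list, in file order."""
        out: dict[str, dict[int, list[int]]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.chain, {}).setdefault(a.resid, []).append(i)
        return out

    def residues(self, chain: str | None = None) -> list[tuple[str, int, str]]:
        """(chain, resid, resname) triples in file order."""
        out: list[tuple[str, int, str]] = []
        last: tuple[str, int] | None = None
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if (a.chain, a.resid) != last:
                out.append((a.chain, a.resid, a.resname))
                last = (a.chain, a.resid)
        return out

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.resid == resid and a.name == name:
                return i
        raise KeyError(f"no atom ({chain}, {resid}, {name})")

    def extend(self, atoms: Iterable[Atom]) -> None:
        for a in atoms:
            if a.key() in {b.key() for b in self.atoms}:
                raise ValueError(f"duplicate atom record {a.key()}")
            self.atoms.append(a)


@dataclass
class Complex:
    """A receptor/ligand partition of a structure; waters belong to neither."""

    structure: Structure
    receptor_chains: frozenset
    ligand_chains: frozenset
    water_resnames: frozenset = WATER_RESNAMES

    def __post_init__(self) -> None:
        self.receptor_chains = frozenset(self.receptor_chains)
        self.ligand_chains = frozenset(self.ligand_chains)
        self.water_resnames = frozenset(self.water_resnames)
        if not self.receptor_chains or not self.ligand_chains:
            raise ValueError("receptor and ligand chain sets must be non-empty")
        if self.receptor_chains & self.ligand_chains:
            raise ValueError("receptor and ligand chain sets must be disjoint")

    def _side_indices(self, chains: frozenset, heavy_only: bool = False) -> list[int]:
        return [
            i
            for i, a in enumerate(self.structure.atoms)
            if a.chain in chains
            and a.resname not in self.water_resnames
            and (a.is_heavy or not heavy_only)
        ]

    def receptor_indices(self, heavy_only: bool = False) -> list[int]:
        return self._side_indices(self.receptor_chains, heavy_only)

    def ligand_indices(self, heavy_only: bool = False) -> list[int]:
        return self._side_indices(self.ligand_chains, heavy_only)

    def water_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.structure.atoms) if a.resname in self.water_resnames]

    def swapped(self) -> "Complex":
        return Complex(self.structure, self.ligand_chains, self.receptor_chains, self.water_resnames)


@dataclass
class Trajectory:
    """Fixed-topology multi-frame coordinates; times in ns."""

    topology: Structure
    frames: list[np.ndarray]
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.topology)
        for k, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(f"frame {k}: atom count {f.shape[0]} does not match topology ({n})")
            self.frames[k] = f
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.frames):
                raise ValueError("times length does not match frame count")
            if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
                raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def frame_times(self, dt: float = 0.1) -> np.ndarray:
        """Per-frame times in ns; ``dt × index`` when no explicit times exist."""
        if self.times is not None:
            return self.times
        return dt * np.arange(len(self.frames), dtype=float)


@dataclass
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - AMINO_ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id!r} contains non-amino-acid characters: {sorted(bad)}")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


# --------------------------------------------------------------------------
# PDB reading / writing


def _parse_atom_line(line: str, lineno: int) -> Atom:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record too short")
    if line[26].strip():
        raise PDBParseError(f"line {lineno}: insertion codes are not supported ({line[26]!r})")
    try:
        serial = int(line[6:11])
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed numeric field ({exc})") from None
    occ = 1.0
    bfac = 0.0
    try:
        if line[54:60].strip():
            occ = float(line[54:60])
        if line[60:66].strip():
            bfac = float(line[60:66])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed occupancy/B-factor field ({exc})") from None
    name = line[12:16].strip()
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the first alphabetic character of the atom name
        m = re.search(r"[A-Za-z]", name)
        element = m.group(0).upper() if m else "X"
        if name[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE") and len(name) > 1:
            element = name[:2].capitalize()
    return Atom(
        serial=serial,
        name=name,
        element=element,
        resname=line[17:20].strip(),
        resid=resid,
        chain=line[21].strip() or " ",
        coords=np.array([x, y, z]),
        occupancy=occ,
        bfactor=bfac,
    )


def read_pdb(path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Multi-model files contribute MODEL 1 only; alternate locations keep
    blank/'A' records; insertion codes raise :class:`PDBParseError`.
    """
    path = Path(path)
    atoms: list[Atom] = []
    title = ""
    model_seen = 0
    in_first_model = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "TITLE":
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "MODEL":
                model_seen += 1
                in_first_model = model_seen == 1
            elif rec == "ENDMDL":
                in_first_model = False
            elif rec in ("ATOM", "HETATM") and in_first_model:
                altloc = line[16]
                if altloc not in (" ", "A"):
                    continue
                atoms.append(_parse_atom_line(line, lineno))
    if not atoms:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms, title=title)


def _format_atom_line(a: Atom, serial: int) -> str:
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    record = "ATOM  " if a.resname not in WATER_RESNAMES else "HETATM"
    return (
        f"{record}{serial:>5d} {name:4s} {a.resname:>3s} {a.chain:1s}"
        f"{a.resid:>4d}    {a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
    )


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure as PDB; round-trips coordinates to 0.001 Å."""
    path = Path(path)
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    for i, a in enumerate(structure.atoms, start=1):
        lines.append(_format_atom_line(a, i))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB."""
    path = Path(path)
    lines = []
    for k, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {k:>4d}")
        for i, (a, row) in enumerate(zip(traj.topology.atoms, frame), start=1):
            tmp = Atom(a.serial, a.name, a.element, a.resname, a.resid, a.chain, row, a.occupancy, a.bfactor)
            lines.append(_format_atom_line(tmp, i))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _read_trajectory_pdb(path: Path, topology: Structure) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    current: list[list[float]] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(np.asarray(current))
                    current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:  # single implicit model
                    current = []
                a = _parse_atom_line(line, lineno)
                current.append(list(a.coords))
    if current:
        frames.append(np.asarray(current))
    return frames


def _read_trajectory_xyz(path: Path) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise PDBParseError(f"line {i + 1}: expected atom count in XYZ header") from None
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise PDBParseError(f"line {i + 1}: truncated XYZ frame")
        coords = []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise PDBParseError(f"line {i + 3 + j}: malformed XYZ atom line")
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise PDBParseError(f"line {i + 3 + j}: malformed coordinate ({exc})") from None
        frames.append(np.asarray(coords))
        i += 2 + n
    return frames


def read_trajectory(path, topology: Structure, dt: float | None = None) -> Trajectory:
    """Read a multi-model PDB or XYZ trajectory against a fixed topology.

    ``dt`` (ns) synthesizes uniformly spaced times when the formats carry none.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        frames = _read_trajectory_xyz(path)
    else:
        frames = _read_trajectory_pdb(path, topology)
    if not frames:
        raise PDBParseError(f"{path}: no frames found")
    n = len(topology)
    for k, f in enumerate(frames):
        if f.shape != (n, 3):
            raise PDBParseError(f"frame {k}: atom count {f.shape[0]} does not match topology ({n})")
    times = None
    if dt is not None:
        times = dt * np.arange(len(frames), dtype=float)
    return Trajectory(topology=topology, frames=frames, times=times)


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# --------------------------------------------------------------------------
# Selection mini-language
#
# Grammar:  expr := term ('or' term)* ; term := factor ('and' factor)* ;
#           factor := 'not' factor | '(' expr ')' | primary
#           primary := 'chain' ID | 'resid' N[-M] | 'resname' ID
#                    | 'name' ID | 'water'

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _SelParser:
    def __init__(self, expr: str) -> None:
        self.tokens = _TOKEN_RE.findall(expr)
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() == "or":
            self.take()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == "and":
            self.take()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        tok = self.peek()
        if tok == "not":
            self.take()
            return ("not", self.factor())
        if tok == "(":
            self.take()
            node = self.expr()
            if self.take() != ")":
                raise SelectionError("missing closing parenthesis")
            return node
        return self.primary()

    def primary(self):
        tok = self.take()
        if tok == "water":
            return ("water",)
        if tok in ("chain", "resname", "name"):
            return (tok, self.take())
        if tok == "resid":
            arg = self.take()
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", arg)
            if not m:
                raise SelectionError(f"bad resid range {arg!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            return ("resid", lo, hi)
        raise SelectionError(f"unknown selection token {tok!r}")


def _eval_sel(node, atom: Atom) -> bool:
    op = node[0]
    if op == "or":
        return _eval_sel(node[1], atom) or _eval_sel(node[2], atom)
    if op == "and":
        return _eval_sel(node[1], atom) and _eval_sel(node[2], atom)
    if op == "not":
        return not _eval_sel(node[1], atom)
    if op == "water":
        return atom.resname in WATER_RESNAMES
    if op == "chain":
        return atom.chain == node[1]
    if op == "resname":
        return atom.resname == node[1]
    if op == "name":
        return atom.name == node[1]
    if op == "resid":
        return node[1] <= atom.resid <= node[2]
    raise SelectionError(f"unknown node {op!r}")


def select(structure: Structure, expr: str) -> list[int]:
    """Evaluate a selection expression; returns atom indices in structure order."""
    tree = _SelParser(expr).parse()
    return [i for i, a in enumerate(structure.atoms) if _eval_sel(tree, a)]
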