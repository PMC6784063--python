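"""Reading, writing and selecting atoms from PDB coordinate files.

Structures are held as flat, ordered lists of :class:`AtomRecord` so that
every analysis module can address atoms by (chain, residue number, atom
name) without caring about the hierarchy of the source file.  Carbohydrate
residues (the Fc N-glycan sugars NAG, FUC, BMA, MAN, GAL and their
anomeric variants) arrive as HETATM records and are kept, flagged with
``is_hetero``.

Parsing is backed by gemmi; writing emits fixed-column PDB directly so
the read/write round trip is the identity on every typed field at format
precision (coordinates to three decimals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "ConformerEnsemble",
    "Selection",
    "PDBError",
    "PDBParseError",
    "EmptyStructureError",
    "TopologyMismatchError",
    "CARBOHYDRATE_RESNAMES",
    "read_pdb",
    "read_multimodel",
    "select_atoms",
    "write_pdb",
]

#: Residue names treated as carbohydrates (Fc N-glycan vocabulary plus
#: common anomeric variants).  Modules take this as a default; callers may
#: pass their own set.
CARBOHYDRATE_RESNAMES = frozenset(
    {"NAG", "FUC", "BMA", "MAN", "GAL", "NDG", "FUL", "GLA"}
)


class PDBError(Exception):
    """Base class for coordinate-file errors."""


class PDBParseError(PDBError):
    """A line of the file could not be parsed as fixed-column PDB."""


class EmptyStructureError(PDBError):
    """The file contains no ATOM or HETATM record."""


class TopologyMismatchError(PDBError):
    """Models of a multi-model file do not share one atom set."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one conformer, with author numbering from the file."""

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    xyz: tuple[float, float, float]
    occupancy: float
    b_factor: float
    is_hetero: bool

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.xyz):
            raise ValueError(f"non-finite coordinates for atom {self.key}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"empty element for atom serial {self.serial}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chain_id, res_seq, i_code, name) — identity within a conformer."""
        return (self.chain_id, self.res_seq, self.i_code, self.name)

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.i_code)


@dataclass
class Structure:
    """An ordered list of atoms of a single conformer."""

    atoms: list[AtomRecord]
    id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """N×3 coordinate array in file order (Å)."""
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        """Copy of this structure with coordinates replaced (topology kept)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {xyz.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, xyz=tuple(map(float, row))) for a, row in zip(self.atoms, xyz)]
        return Structure(atoms=atoms, id=self.id)

    def find_atom(self, chain_id: str, res_seq: int, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.chain_id == chain_id and a.res_seq == res_seq and a.name == name:
                return a
        raise KeyError(f"atom ({chain_id}, {res_seq}, {name}) not found")

    def topology_key(self) -> tuple[tuple[str, int, str, str, str], ...]:
        return tuple((a.chain_id, a.res_seq, a.i_code, a.name, a.res_name) for a in self.atoms)


@dataclass
class ConformerEnsemble:
    """Ordered conformers sharing one topology."""

    conformers: list[Structure]

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        key = self.conformers[0].topology_key()
        for i, conf in enumerate(self.conformers[1:], start=2):
            k = conf.topology_key()
            if k != key:
                offender = _first_topology_difference(key, k)
                raise TopologyMismatchError(
                    f"model {i} does not share the ensemble topology; "
                    f"first difference at atom {offender}"
                )

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i: int) -> Structure:
        return self.conformers[i]

    @property
    def topology_key(self):
        return self.conformers[0].topology_key()

    def coords(self) -> np.ndarray:
        """(n_conformers, n_atoms, 3) coordinate array."""
        return np.stack([c.coords() for c in self.conformers])


def _first_topology_difference(a: tuple, b: tuple):
    for x, y in zip(a, b):
        if x != y:
            return y
    return a[len(b)] if len(a) > len(b) else b[len(a)]


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection.

    ``None`` fields mean "no constraint".  ``hetero`` is one of
    ``"include"`` (default: both ATOM and HETATM), ``"exclude"`` or
    ``"only"``.
    """

    chain_ids: frozenset[str] | None = None
    res_range: tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None
    hetero: str = "include"

    def __post_init__(self) -> None:
        if self.res_range is not None and self.res_range[0] > self.res_range[1]:
            raise ValueError(f"res_range lo {self.res_range[0]} > hi {self.res_range[1]}")
        if self.hetero not in ("include", "exclude", "only"):
            raise ValueError(f"hetero must be include|exclude|only, got {self.hetero!r}")
        if self.chain_ids is not None and not isinstance(self.chain_ids, frozenset):
            object.__setattr__(self, "chain_ids", frozenset(self.chain_ids))
        if self.atom_names is not None and not isinstance(self.atom_names, frozenset):
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))

    def matches(self, a: AtomRecord) -> bool:
        if self.chain_ids is not None and a.chain_id not in self.chain_ids:
            return False
        if self.res_range is not None and not (self.res_range[0] <= a.res_seq <= self.res_range[1]):
            return False
        if self.atom_names is not None and a.name not in self.atom_names:
            return False
        if self.hetero == "exclude" and a.is_hetero:
            return False
        if self.hetero == "only" and not a.is_hetero:
            return False
        return True


#: Selection of all Cα atoms (the fitting set used throughout).
CA_SELECTION = Selection(atom_names=frozenset({"CA"}), hetero="exclude")


# ---------------------------------------------------------------------------
# reading

def _atom_from_gemmi(atom: gemmi.Atom, res: gemmi.Residue, chain_name: str) -> AtomRecord:
    el = atom.element.name.strip()
    return AtomRecord(
        serial=atom.serial,
        name=atom.name,
        element=el if el else atom.name[:1],
        alt_loc=atom.altloc.strip() if atom.altloc != "\x00" else "",
        res_name=res.name,
        chain_id=chain_name,
        res_seq=res.seqid.num,
        i_code=res.seqid.icode.strip(),
        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
        occupancy=float(min(max(atom.occ, 0.0), 1.0)),
        b_factor=float(atom.b_iso),
        is_hetero=res.het_flag == "H",
    )


def _model_atoms(model: gemmi.Model) -> list[AtomRecord]:
    out: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            for atom in res:
                out.append(_atom_from_gemmi(atom, res, chain.name))
    return out


def resolve_alt_locs(atoms: Sequence[AtomRecord]) -> list[AtomRecord]:
    """Keep one record per (chain, res_seq, i_code, name).

    Among alternative locations the highest-occupancy copy wins; ties go to
    the lexicographically smallest alt_loc character ('' sorts first).
    Order of first appearance is preserved.
    """
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        k = a.key
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            cur = best[k]
            if (a.occupancy, _altloc_rank(cur.alt_loc)) > (cur.occupancy, _altloc_rank(a.alt_loc)):
                best[k] = a
    return [best[k] for k in order]


def _altloc_rank(c: str) -> int:
    # smaller is preferred; '' before 'A' before 'B' ...
    return -1 if c == "" else ord(c)


def _read_gemmi_structure(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise PDBError(f"cannot read {path}: no such file")
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    return st


def read_pdb(path: str | Path) -> Structure:
    """Read the first model of a PDB file, alt-locs resolved.

    Carbohydrate HETATM residues are retained with ``is_hetero=True``.
    Raises :class:`EmptyStructureError` if the file holds no coordinates.
    """
    st = _read_gemmi_structure(path)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no ATOM or HETATM records")
    atoms = _model_atoms(st[0])
    if not atoms:
        raise EmptyStructureError(f"{path}: no ATOM or HETATM records")
    return Structure(atoms=resolve_alt_locs(atoms), id=Path(path).stem)


def read_multimodel(path: str | Path) -> ConformerEnsemble:
    """Read every MODEL of a PDB file as one conformer ensemble.

    A single-model file yields an ensemble of length 1.  Models whose atom
    sets differ raise :class:`TopologyMismatchError` naming the first
    offending atom.
    """
    st = _read_gemmi_structure(path)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no ATOM or HETATM records")
    conformers = []
    stem = Path(path).stem
    for i, model in enumerate(st, start=1):
        atoms = resolve_alt_locs(_model_atoms(model))
        if not atoms:
            raise EmptyStructureError(f"{path}: model {i} has no atoms")
        conformers.append(Structure(atoms=atoms, id=f"{stem}/{i}"))
    return ConformerEnsemble(conformers=conformers)


# ---------------------------------------------------------------------------
# selection

def select_atoms(s: Structure, sel: Selection) -> Structure:
    """Subset of ``s`` matching ``sel``, order preserved; may be empty."""
    return Structure(atoms=[a for a in s.atoms if sel.matches(a)], id=s.id)


def select_ensemble(e: ConformerEnsemble, sel: Selection) -> ConformerEnsemble:
    return ConformerEnsemble(conformers=[select_atoms(c, sel) for c in e])


def selection_indices(s: Structure, sel: Selection) -> np.ndarray:
    """Integer indices into ``s.atoms`` matching ``sel``."""
    return np.array([i for i, a in enumerate(s.atoms) if sel.matches(a)], dtype=int)


# ---------------------------------------------------------------------------
# writing

def _format_atom_line(a: AtomRecord) -> str:
    record = "HETATM" if a.is_hetero else "ATOM  "
    # PDB v3.3 atom-name justification: element symbols of one character
    # start in column 14 unless the name is four characters long.
    name = a.name
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    name = name.ljust(4)
    x, y, z = a.xyz
    return (
        f"{record}{a.serial % 100000:5d} {name}{a.alt_loc or ' '}"
        f"{a.res_name:>3s} {a.chain_id:1s}{a.res_seq:4d}{a.i_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
        f"          {a.element:>2s}"
    )


def write_pdb(obj: Structure | ConformerEnsemble, path: str | Path) -> None:
    """Write a structure (or multi-model ensemble) as fixed-column PDB."""
    path = Path(path)
    lines: list[str] = []
    if isinstance(obj, ConformerEnsemble):
        for i, conf in enumerate(obj, start=1):
            lines.append(f"MODEL     {i:4d}")
            lines.extend(_format_atom_line(a) for a in conf.atoms)
            lines.append("ENDMDL")
    else:
        lines.extend(_format_atom_line(a) for a in obj.atoms)
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise PDBError(f"cannot write {path}: {exc}") from exc
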