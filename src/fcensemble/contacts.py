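"""Glycan–protein contact pairs and their incidence across an ensemble.

A residue pair is "in contact" in a conformer when any heavy-atom pair
across the two groups lies strictly within the cutoff (4 Å by default).
Counting the conformers in which each pair is present gives the
incidence table; pairs are then classed by incidence fraction, mirroring
the three line weights of the glycan interaction-network figure style
(thick: > 24,000 of 25,600 conformers, i.e. > 0.9375; thin:
(0.625, 0.9375]; dashed: (0.3125, 0.625]).  Thresholds are stored as
fractions so the classification applies to ensembles of any size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    CARBOHYDRATE_RESNAMES,
    ConformerEnsemble,
    Selection,
    Structure,
)

__all__ = [
    "ResidueKey",
    "ContactIncidenceTable",
    "IncidenceClass",
    "INCIDENCE_CLASSES",
    "contact_pairs",
    "ensemble_incidence",
    "classify_incidence",
    "pair_type",
    "export_network",
    "read_network",
]


@dataclass(frozen=True, order=True)
class ResidueKey:
    """A residue node of the contact network."""

    chain_id: str
    res_seq: int
    res_name: str

    @property
    def kind(self) -> str:
        return "carbohydrate" if self.res_name in CARBOHYDRATE_RESNAMES else "protein"


@dataclass(frozen=True)
class IncidenceClass:
    """One band of the incidence classification, as fractions of total."""

    label: str
    lo: float  # exclusive
    hi: float  # inclusive


#: Fraction bands derived from the 25,600-conformer absolute thresholds
#: (> 24,000; 24,000–16,000; 16,000–8,000). Lower edges exclusive, upper
#: inclusive; together with below_threshold they partition [0, 1].
INCIDENCE_CLASSES = (
    IncidenceClass("thick", 24000 / 25600, 1.0),
    IncidenceClass("thin", 16000 / 25600, 24000 / 25600),
    IncidenceClass("dashed", 8000 / 25600, 16000 / 25600),
    IncidenceClass("below_threshold", 0.0, 8000 / 25600),
)


def pair_type(a: ResidueKey, b: ResidueKey) -> str:
    """'carbohydrate-carbohydrate' or 'carbohydrate-protein'.

    Protein–protein pairs are outside the network's scope and raise.
    """
    kinds = {a.kind, b.kind}
    if "carbohydrate" not in kinds:
        raise ValueError(f"protein–protein pair out of scope: {a} – {b}")
    return "carbohydrate-carbohydrate" if kinds == {"carbohydrate"} else "carbohydrate-protein"


@dataclass
class ContactIncidenceTable:
    """Unordered residue pair → conformer count, over ``total`` conformers."""

    counts: dict[tuple[ResidueKey, ResidueKey], int]
    total: int

    def __post_init__(self) -> None:
        for (a, b), c in self.counts.items():
            if a == b:
                raise ValueError(f"self-pair {a}")
            if not 0 <= c <= self.total:
                raise ValueError(f"count {c} outside [0, {self.total}] for {a}–{b}")

    def fraction(self, pair: tuple[ResidueKey, ResidueKey]) -> float:
        return self.counts[_canonical(*pair)] / self.total

    def rows(self) -> list[dict]:
        out = []
        for (a, b), count in self.counts.items():
            frac = count / self.total
            out.append(
                {
                    "chain_a": a.chain_id, "res_seq_a": a.res_seq, "res_name_a": a.res_name,
                    "chain_b": b.chain_id, "res_seq_b": b.res_seq, "res_name_b": b.res_name,
                    "count": count, "fraction": frac,
                    "class": classify_incidence(count, self.total).label,
                    "pair_type": pair_type(a, b),
                }
            )
        return out


def _canonical(a: ResidueKey, b: ResidueKey) -> tuple[ResidueKey, ResidueKey]:
    return (a, b) if a <= b else (b, a)


def _heavy_residues(s: Structure, sel: Selection):
    """Residue keys and heavy-atom coordinates within a selection."""
    keys, coords, owner = [], [], []
    index: dict[tuple, int] = {}
    for a in s.atoms:
        if not sel.matches(a) or a.element.upper() == "H":
            continue
        rid = (a.chain_id, a.res_seq, a.res_name)
        if rid not in index:
            index[rid] = len(keys)
            keys.append(ResidueKey(*rid))
        coords.append(a.xyz)
        owner.append(index[rid])
    return keys, np.asarray(coords, dtype=float).reshape(-1, 3), np.asarray(owner, dtype=int)


def contact_pairs(
    s: Structure,
    group_a: Selection,
    group_b: Selection,
    cutoff: float = 4.0,
) -> set[tuple[ResidueKey, ResidueKey]]:
    """Residue pairs with any cross-group heavy-atom distance < cutoff.

    The two selections must not share residues.  Pairs are residue-level
    and unordered; multiple qualifying atom pairs inside one residue pair
    still yield a single pair.
    """
    keys_a, xyz_a, owner_a = _heavy_residues(s, group_a)
    keys_b, xyz_b, owner_b = _heavy_residues(s, group_b)
    overlap = {(k.chain_id, k.res_seq) for k in keys_a} & {(k.chain_id, k.res_seq) for k in keys_b}
    if overlap:
        raise ValueError(f"selections overlap at residues {sorted(overlap)}")
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return set()
    tree_b = cKDTree(xyz_b)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    # strict inequality: shrink the radius by a hair below the cutoff
    hits = cKDTree(xyz_a).query_ball_tree(tree_b, r=cutoff)
    for ia, neighbours in enumerate(hits):
        for ib in neighbours:
            if np.linalg.norm(xyz_a[ia] - xyz_b[ib]) < cutoff:
                pairs.add(_canonical(keys_a[owner_a[ia]], keys_b[owner_b[ib]]))
    return pairs


def ensemble_incidence(
    e: ConformerEnsemble,
    group_a: Selection,
    group_b: Selection,
    cutoff: float = 4.0,
) -> ContactIncidenceTable:
    """Count, per residue pair, the conformers in which the contact holds."""
    counts: dict[tuple[ResidueKey, ResidueKey], int] = {}
    for conf in e:
        for pair in contact_pairs(conf, group_a, group_b, cutoff):
            counts[pair] = counts.get(pair, 0) + 1
    return ContactIncidenceTable(counts=counts, total=len(e))


def classify_incidence(count: int, total: int) -> IncidenceClass:
    """Incidence band of a contact: fraction-based, lower-exclusive."""
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    frac = count / total
    for cls in INCIDENCE_CLASSES:
        if cls.lo < frac <= cls.hi:
            return cls
    return INCIDENCE_CLASSES[-1]  # frac == 0


_CLASS_ORDER = {c.label: i for i, c in enumerate(INCIDENCE_CLASSES)}
_COLUMNS = [
    "chain_a", "res_seq_a", "res_name_a",
    "chain_b", "res_seq_b", "res_name_b",
    "count", "fraction", "class", "pair_type",
]


def export_network(table: ContactIncidenceTable, path: str | Path) -> None:
    """Write the incidence table as a deterministic edge-list TSV.

    Rows sort by class (thick first), then lexicographically by the pair
    keys, so repeated runs are byte-identical.
    """
    rows = table.rows()
    rows.sort(
        key=lambda r: (
            _CLASS_ORDER[r["class"]],
            r["chain_a"], r["res_seq_a"], r["res_name_a"],
            r["chain_b"], r["res_seq_b"], r["res_name_b"],
        )
    )
    with open(path, "w") as fh:
        fh.write(f"# total_conformers\t{table.total}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    f"{r[c]:.6f}" if c == "fraction" else str(r[c]) for c in _COLUMNS
                )
                + "\n"
            )


def read_network(path: str | Path) -> ContactIncidenceTable:
    """Read an edge-list TSV written by :func:`export_network`."""
    counts: dict[tuple[ResidueKey, ResidueKey], int] = {}
    total = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# total_conformers"):
                total = int(line.split("\t")[1])
                continue
            if not line or line.startswith("chain_a"):
                continue
            f = line.split("\t")
            a = ResidueKey(f[0], int(f[1]), f[2])
            b = ResidueKey(f[3], int(f[4]), f[5])
            counts[_canonical(a, b)] = int(f[6])
    if total is None:
        raise ValueError(f"{path}: missing total_conformers header")
    return ContactIncidenceTable(counts=counts, total=total)
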