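"""Scalar geometric observables of an Fc conformer.

Two observables summarize each conformer: the intra-chain C_H2–C_H3
domain-orientation angle, defined by three Cα atoms (by default the
Tyr300 / Met428 / Gln362 triple with the vertex at Met428), and the
side-chain χ1 torsion (N–CA–CB–Cγ) of a residue of interest such as
Tyr296, whose flipped-in (~80°) and flipped-out (~180°) rotamers track
the core-fucose microenvironment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import ConformerEnsemble, Structure

__all__ = [
    "AngleTriple",
    "AnglePair",
    "DihedralSeries",
    "DEFAULT_ANGLE_TRIPLE",
    "GAMMA_ATOM",
    "point_angle",
    "domain_angle",
    "domain_angle_pairs",
    "dihedral",
    "chi1",
    "chi1_series",
    "angle_histogram",
    "to_0_360",
]


@dataclass(frozen=True)
class AngleTriple:
    """Three (res_seq, atom name) keys defining a planar angle; the chain
    is supplied at evaluation time so one triple serves both Fc chains."""

    keys: tuple[tuple[int, str], tuple[int, str], tuple[int, str]]
    vertex_index: int = 1

    def __post_init__(self) -> None:
        if len(set(self.keys)) != 3:
            raise ValueError("angle triple keys must be distinct")
        if self.vertex_index not in (0, 1, 2):
            raise ValueError("vertex_index must be 0, 1 or 2")


#: Cα atoms of Tyr300 and Gln362 with the vertex at Met428's Cα.
DEFAULT_ANGLE_TRIPLE = AngleTriple(keys=((300, "CA"), (428, "CA"), (362, "CA")), vertex_index=1)


@dataclass(frozen=True)
class AnglePair:
    """Per-conformer domain angles of the two chains, degrees."""

    chain_a_deg: float
    chain_b_deg: float

    def __post_init__(self) -> None:
        for v in (self.chain_a_deg, self.chain_b_deg):
            if not 0.0 <= v <= 180.0:
                raise ValueError(f"domain angle {v} outside [0, 180]")


@dataclass
class DihedralSeries:
    """Conformer-indexed χ1 values (degrees, (−180, 180]) for one residue."""

    chain_id: str
    res_seq: int
    values_deg: np.ndarray

    def to_0_360(self) -> np.ndarray:
        return to_0_360(self.values_deg)


def to_0_360(deg) -> np.ndarray:
    """Map angles from (−180, 180] to [0, 360)."""
    return np.mod(np.asarray(deg, dtype=float), 360.0)


def point_angle(p1, p2, p3) -> float:
    """Planar angle in degrees at the vertex ``p2``, in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u, v = p1 - p2, p3 - p2
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("zero-length arm: vertex coincides with an endpoint")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def domain_angle(
    s: Structure,
    chain: str,
    triple: AngleTriple = DEFAULT_ANGLE_TRIPLE,
) -> float:
    """C_H2–C_H3 orientation angle of one chain, degrees in [0, 180]."""
    pts = []
    for res_seq, name in triple.keys:
        try:
            pts.append(np.array(s.find_atom(chain, res_seq, name).xyz))
        except KeyError as exc:
            raise KeyError(f"domain-angle atom missing: chain {chain}, res {res_seq}, atom {name}") from exc
    order = [triple.vertex_index] + [i for i in (0, 1, 2) if i != triple.vertex_index]
    vertex, a, b = pts[order[0]], pts[order[1]], pts[order[2]]
    return point_angle(a, vertex, b)


def domain_angle_pairs(
    e: ConformerEnsemble,
    chain_a: str = "A",
    chain_b: str = "B",
    triple: AngleTriple = DEFAULT_ANGLE_TRIPLE,
) -> list[AnglePair]:
    """Per-conformer (chain A, chain B) domain angles over an ensemble."""
    return [
        AnglePair(
            chain_a_deg=domain_angle(c, chain_a, triple),
            chain_b_deg=domain_angle(c, chain_b, triple),
        )
        for c in e
    ]


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, IUPAC convention, in (−180, 180].

    cis is 0; the sign follows the right-hand rule about the p2→p3 bond.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or nb2 < 1e-12:
        raise ValueError("degenerate geometry: collinear or coincident points")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


#: γ atom used as the fourth χ1 atom, by residue type.  CB-branched and
#: short side chains that have no χ1 are absent.
GAMMA_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "ILE": "CG1", "VAL": "CG1",
    "SER": "OG", "THR": "OG1", "CYS": "SG",
}


def chi1(s: Structure, chain: str, res_seq: int) -> float:
    """χ1 = dihedral(N, CA, CB, γ) of one residue, degrees in (−180, 180]."""
    res_atoms = {a.name: a for a in s.atoms if a.chain_id == chain and a.res_seq == res_seq}
    if not res_atoms:
        raise KeyError(f"residue ({chain}, {res_seq}) not found")
    res_name = next(iter(res_atoms.values())).res_name
    gamma = GAMMA_ATOM.get(res_name, "CG")
    pts = []
    for name in ("N", "CA", "CB", gamma):
        if name not in res_atoms:
            raise KeyError(f"χ1 atom {name} missing in residue ({chain}, {res_seq}, {res_name})")
        pts.append(res_atoms[name].xyz)
    return dihedral(*pts)


def chi1_series(e: ConformerEnsemble, chain: str, res_seq: int) -> DihedralSeries:
    """Per-conformer χ1 of one residue across an ensemble."""
    vals = np.empty(len(e), dtype=float)
    for i, conf in enumerate(e):
        try:
            vals[i] = chi1(conf, chain, res_seq)
        except (KeyError, ValueError) as exc:
            raise type(exc)(f"conformer {i}: {exc}") from exc
    return DihedralSeries(chain_id=chain, res_seq=res_seq, values_deg=vals)


def angle_histogram(
    values,
    bin_width: float,
    range_convention: str = "signed",
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of angles on a circular range.

    ``range_convention`` is ``"signed"`` for the [−180, 180) axis or
    ``"unsigned"`` for [0, 360); values are wrapped circularly into the
    chosen range before binning.  All bins are lower-inclusive, so the two
    conventions count identically after re-mapping bin centers mod 360
    (a χ1 of exactly +180° falls in the −180° bin under "signed").
    ``bin_width`` must divide 360.  Returns (bin centers, counts); counts
    sum to ``len(values)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = 360.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 360")
    n_bins = int(round(n_bins))
    vals = np.asarray(values, dtype=float)
    if range_convention == "signed":
        lo = -180.0
        wrapped = np.mod(vals + 180.0, 360.0) - 180.0
    elif range_convention == "unsigned":
        lo = 0.0
        wrapped = np.mod(vals, 360.0)
    else:
        raise ValueError("range_convention must be 'signed' or 'unsigned'")
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(wrapped, bins=edges)
    centers = edges[:-1] + bin_width / 2.0
    return centers, counts
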