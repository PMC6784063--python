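"""Rigid-body superposition, RMSD, ensemble-average structure and RMSF.

The average structure is obtained iteratively: every conformer is fitted
(least squares, Cα atoms by default) onto the current mean, the
coordinate-wise mean is recomputed, and the loop stops once the mean moves
by less than a tolerance.  The per-atom root mean square fluctuation
(RMSF) is then the RMS deviation of each atom from its position in the
converged average, after fitting each conformer to that average.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure_io import (
    CA_SELECTION,
    ConformerEnsemble,
    Selection,
    Structure,
    selection_indices,
)

__all__ = [
    "RigidTransform",
    "RMSFProfile",
    "DegenerateInputError",
    "ConvergenceError",
    "kabsch",
    "rmsd",
    "average_structure",
    "rmsf",
    "min_rmsd_to_reference",
]


class DegenerateInputError(ValueError):
    """Point sets too small or too flat for a unique superposition."""


class ConvergenceError(RuntimeError):
    """Iterative mean did not converge within max_iter."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation, x -> R x + t."""

    rotation: np.ndarray  # 3×3, det +1
    translation: np.ndarray  # length 3, Å

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation is not proper (det != +1)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ np.asarray(self.rotation).T + np.asarray(
            self.translation
        )


@dataclass
class RMSFProfile:
    """Per-residue Cα fluctuation: ordered (chain_id, res_seq, rmsf Å)."""

    entries: list[tuple[str, int, float]]

    def values(self) -> np.ndarray:
        return np.array([r for _, _, r in self.entries], dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tres_seq\trmsf_A\n")
            for chain, seq, val in self.entries:
                fh.write(f"{chain}\t{seq}\t{val:.4f}\n")


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean square distance between paired points, no fitting."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 1:
        raise ValueError("need at least one point pair")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal least-squares superposition of ``mobile`` onto ``reference``.

    Returns the rigid transform minimizing RMSD over all proper rotations
    and translations, and the minimum RMSD itself.  Requires N ≥ 3
    non-collinear points.
    """
    P = np.asarray(mobile, dtype=float).reshape(-1, 3)
    Q = np.asarray(reference, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need at least 3 points, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinear (or coincident) points leave the rotation underdetermined
    if np.linalg.matrix_rank(P0, tol=1e-10) < 2 or np.linalg.matrix_rank(Q0, tol=1e-10) < 2:
        raise DegenerateInputError("point set is collinear or degenerate (rank < 2)")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    fitted = P @ R.T + t
    return RigidTransform(rotation=R, translation=t), rmsd(fitted, Q)


def _fit_full(coords: np.ndarray, ref_fit: np.ndarray, fit_idx: np.ndarray) -> np.ndarray:
    """Fit on the fit_idx subset, apply the transform to all atoms."""
    tf, _ = kabsch(coords[fit_idx], ref_fit)
    return tf.apply(coords)


def average_structure(
    e: ConformerEnsemble,
    fit_sel: Selection = CA_SELECTION,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> Structure:
    """Iterative ensemble-average structure on the full topology.

    All conformers are superposed (on ``fit_sel``) to the running mean,
    starting from conformer 1 as the reference; iteration stops when the
    mean coordinates move by less than ``tol`` Å RMSD between rounds.
    """
    fit_idx = selection_indices(e[0], fit_sel)
    if fit_idx.size < 3:
        raise DegenerateInputError(f"fit selection has {fit_idx.size} atoms; need ≥ 3")
    X = e.coords()  # (n_conf, n_atoms, 3)
    mean = X[0].copy()
    if len(e) == 1:
        return e[0].with_coords(mean)
    for _ in range(max_iter):
        fitted = np.stack([_fit_full(x, mean[fit_idx], fit_idx) for x in X])
        new_mean = fitted.mean(axis=0)
        delta = rmsd(new_mean, mean)
        mean = new_mean
        if delta < tol:
            avg = e[0].with_coords(mean)
            avg.id = "average"
            return avg
    raise ConvergenceError(f"average structure not converged after {max_iter} iterations (last delta {delta:.2e} Å)")


def rmsf(
    e: ConformerEnsemble,
    fit_sel: Selection = CA_SELECTION,
    report_sel: Selection = CA_SELECTION,
) -> RMSFProfile:
    """Per-atom RMS fluctuation about the converged average structure.

    Each conformer is superposed onto the average on ``fit_sel``; the RMSF
    of each reported atom is the square root of its mean squared deviation
    from the average position.  Reported per Cα atom by default.
    """
    if len(e) < 2:
        raise ValueError("RMSF needs an ensemble of at least 2 conformers")
    avg = average_structure(e, fit_sel)
    fit_idx = selection_indices(e[0], fit_sel)
    report_idx = selection_indices(e[0], report_sel)
    avg_xyz = avg.coords()
    fitted = np.stack([_fit_full(x, avg_xyz[fit_idx], fit_idx) for x in e.coords()])
    sq_dev = np.sum((fitted[:, report_idx, :] - avg_xyz[report_idx]) ** 2, axis=2)
    vals = np.sqrt(sq_dev.mean(axis=0))
    entries = [
        (e[0].atoms[i].chain_id, e[0].atoms[i].res_seq, float(v))
        for i, v in zip(report_idx, vals)
    ]
    return RMSFProfile(entries=entries)


def min_rmsd_to_reference(
    e: ConformerEnsemble,
    ref: Structure,
    sel: Selection = CA_SELECTION,
    exclude_residues: set[tuple[str, int]] | None = None,
) -> tuple[int, float]:
    """Conformer most resembling a reference structure.

    Atoms are matched between the reference and the ensemble topology by
    (chain_id, res_seq, atom name) within ``sel``; residues listed in
    ``exclude_residues`` as (chain_id, res_seq) are dropped from the match
    (e.g. segments with inconsistent electron-density interpretation).
    Returns (argmin index, minimum fitted RMSD).
    """
    exclude = exclude_residues or set()
    ref_map = {
        (a.chain_id, a.res_seq, a.name): i
        for i, a in enumerate(ref.atoms)
        if sel.matches(a) and (a.chain_id, a.res_seq) not in exclude
    }
    ens_idx, ref_idx = [], []
    for i, a in enumerate(e[0].atoms):
        if not sel.matches(a) or (a.chain_id, a.res_seq) in exclude:
            continue
        j = ref_map.get((a.chain_id, a.res_seq, a.name))
        if j is not None:
            ens_idx.append(i)
            ref_idx.append(j)
    if not ens_idx:
        raise ValueError("no common atoms between reference and ensemble under the selection")
    ref_xyz = ref.coords()[ref_idx]
    best = (0, float("inf"))
    for k, conf in enumerate(e):
        _, r = kabsch(conf.coords()[ens_idx], ref_xyz)
        if r < best[1]:
            best = (k, r)
    return best
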