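"""Theoretical small-angle X-ray scattering via the Debye equation.

For a set of scatterers with form factors f_i(q) at positions r_i the
orientationally averaged intensity is

    I(q) = Σ_i Σ_j f_i(q) f_j(q) sin(q r_ij) / (q r_ij),

with the j = i terms contributing f_i(q)².  Form factors are vacuum atomic
scattering factors in the standard four-Gaussian-plus-constant
(Cromer–Mann) parameterization; no excluded-volume or hydration-layer
term is applied.  An ensemble profile is the unweighted mean of the
per-conformer profiles, and the fit to an experimental curve is the
reduced chi-square

    χ² = 1/(N−1) Σ_j [(I_exp(q_j) − c·I_calc(q_j)) / σ(q_j)]²

minimized analytically over the scaling factor c.

Two granularities are available: ``atomic`` (one scatterer per heavy
atom) and ``residue-bead`` (one scatterer at each residue's heavy-atom
centroid carrying the residue's heavy-atom electron count), the latter
for ensemble-scale runs where the O(n²) atomic sum is too slow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .structure_io import ConformerEnsemble, Structure

__all__ = [
    "SAXSProfile",
    "ChiSquareResult",
    "FormFactorModel",
    "CROMER_MANN",
    "default_q_grid",
    "debye_profile",
    "ensemble_profile",
    "fit_scale",
    "chi_square",
    "regrid",
    "read_experimental_profile",
]

# Cromer–Mann coefficients (a1..a4, b1..b4, c), International Tables for
# Crystallography vol. C; f(q) = Σ a_k exp(−b_k (q/4π)²) + c, f(0) ≈ Z.
CROMER_MANN: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.5290),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080),
          (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
}

#: Electron counts used for residue-bead form factors.
ELECTRONS = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}


@dataclass
class SAXSProfile:
    """Scattering intensity I(q); σ present only for experimental data."""

    q: np.ndarray  # Å⁻¹, strictly increasing, ≥ 0
    intensity: np.ndarray  # arbitrary units
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if np.any(self.q < 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return len(self.q)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            if self.sigma is None:
                fh.write("q_invA\tintensity\n")
                for q, i in zip(self.q, self.intensity):
                    fh.write(f"{q:.6g}\t{i:.8g}\n")
            else:
                fh.write("q_invA\tintensity\tsigma\n")
                for q, i, s in zip(self.q, self.intensity, self.sigma):
                    fh.write(f"{q:.6g}\t{i:.8g}\t{s:.8g}\n")


@dataclass(frozen=True)
class ChiSquareResult:
    """Reduced χ², the fitted scale c, and the number of points."""

    chi2: float
    c: float
    n_points: int

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")
        if self.n_points < 2:
            raise ValueError("need at least 2 points")


class FormFactorModel:
    """Per-element f(q), or a constant point-scatterer form factor.

    ``FormFactorModel()`` is the atomic (Cromer–Mann) model;
    ``FormFactorModel(point=2.0)`` makes every scatterer carry the
    constant form factor 2.0 regardless of element.
    """

    def __init__(self, point: float | None = None):
        self.point = point

    def __call__(self, element: str, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if self.point is not None:
            return np.full_like(q, float(self.point))
        try:
            a, b, c = CROMER_MANN[element.upper()]
        except KeyError:
            raise KeyError(f"no form factor tabulated for element {element!r}")
        s2 = (q / (4.0 * np.pi)) ** 2
        f = np.full_like(q, c)
        for ak, bk in zip(a, b):
            f = f + ak * np.exp(-bk * s2)
        return f

    def f_zero(self, element: str) -> float:
        return float(self(element, np.zeros(1))[0])


def default_q_grid(q_min: float = 0.015, q_max: float = 0.5, n: int = 200) -> np.ndarray:
    """Log-spaced q grid covering the wide measured range, Å⁻¹."""
    return np.geomspace(q_min, q_max, n)


def _scatterers(
    s: Structure, model: FormFactorModel, granularity: str, q: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Scatterer positions, per-scatterer group labels, and the label → f(q)
    table for the chosen granularity.

    Hydrogens are excluded in both modes; in residue-bead mode each
    residue becomes one point at its heavy-atom centroid with a constant
    form factor equal to the residue's heavy-atom electron count.
    """
    heavy = [a for a in s.atoms if a.element.upper() != "H"]
    if not heavy:
        raise ValueError("structure has no heavy atoms to scatter from")
    if granularity == "atomic":
        pos = np.array([a.xyz for a in heavy])
        labels = np.array([a.element.upper() for a in heavy])
        table = {el: model(el, q) for el in np.unique(labels)}
        return pos, labels, table
    if granularity == "residue-bead":
        groups: dict[tuple, list] = {}
        order: list[tuple] = []
        for a in heavy:
            rid = a.residue_id
            if rid not in groups:
                groups[rid] = []
                order.append(rid)
            groups[rid].append(a)
        pos = np.array(
            [np.mean([a.xyz for a in groups[rid]], axis=0) for rid in order]
        )
        if model.point is not None:
            ne = np.full(len(order), float(model.point))
        else:
            ne = np.array(
                [sum(ELECTRONS.get(a.element.upper(), 6) for a in groups[rid]) for rid in order],
                dtype=float,
            )
        labels = np.array([f"{v:.6g}" for v in ne])
        table = {lab: np.full_like(np.asarray(q, dtype=float), float(lab))
                 for lab in np.unique(labels)}
        return pos, labels, table
    raise ValueError(f"granularity must be 'atomic' or 'residue-bead', got {granularity!r}")


def _sinc_sum(r: np.ndarray, qk: float) -> float:
    """Σ sin(q r)/(q r) over a distance vector; the q→0 limit is len(r)."""
    if qk == 0.0:
        return float(len(r))
    s = qk * r
    out = np.sin(s)
    np.divide(out, s, out=out, where=s != 0.0)
    out[s == 0.0] = 1.0
    return float(np.sum(out))


def debye_profile(
    s: Structure,
    q: np.ndarray,
    model: FormFactorModel | None = None,
    granularity: str = "atomic",
) -> SAXSProfile:
    """Debye-equation intensity of one conformer on grid ``q``.

    Pairs are grouped by (element, element) so each group contributes
    2 f_a(q) f_b(q) Σ sinc(q r); exact pairwise O(n²) evaluation.
    """
    q = np.asarray(q, dtype=float)
    model = model or FormFactorModel()
    pos, labels, table = _scatterers(s, model, granularity, q)
    intensity = np.zeros_like(q)
    # self terms
    for lab, f in table.items():
        intensity += np.sum(labels == lab) * f**2
    # cross terms, one distance vector per unordered label pair
    label_list = sorted(table)
    for i, la in enumerate(label_list):
        pa = pos[labels == la]
        for lb in label_list[i:]:
            pb = pos[labels == lb]
            if la == lb:
                if len(pa) < 2:
                    continue
                r = pdist(pa)
            else:
                r = cdist(pa, pb).ravel()
            fafb = table[la] * table[lb]
            for k, qk in enumerate(q):
                intensity[k] += 2.0 * fafb[k] * _sinc_sum(r, qk)
    return SAXSProfile(q=q, intensity=intensity)


def ensemble_profile(
    e: ConformerEnsemble,
    q: np.ndarray,
    model: FormFactorModel | None = None,
    granularity: str = "atomic",
) -> SAXSProfile:
    """Unweighted mean of per-conformer Debye profiles."""
    q = np.asarray(q, dtype=float)
    acc = np.zeros_like(q)
    for conf in e:
        acc += debye_profile(conf, q, model, granularity).intensity
    return SAXSProfile(q=q, intensity=acc / len(e))


def fit_scale(exp: SAXSProfile, calc: SAXSProfile) -> float:
    """Least-squares scaling factor c minimizing χ² on a shared grid.

    c = [Σ I_exp I_calc / σ²] / [Σ I_calc² / σ²].
    """
    _check_shared_grid(exp, calc)
    if exp.sigma is None:
        raise ValueError("experimental profile must carry errors (sigma)")
    w = 1.0 / exp.sigma**2
    denom = np.sum(w * calc.intensity**2)
    if denom == 0.0:
        raise ZeroDivisionError("calculated intensity is identically zero; cannot scale")
    return float(np.sum(w * exp.intensity * calc.intensity) / denom)


def chi_square(
    exp: SAXSProfile, calc: SAXSProfile, c: float | None = None
) -> ChiSquareResult:
    """Reduced goodness-of-fit with the 1/(N−1) prefactor.

    If ``c`` is omitted it is set to the analytic optimum from
    :func:`fit_scale`.
    """
    _check_shared_grid(exp, calc)
    if exp.sigma is None:
        raise ValueError("experimental profile must carry errors (sigma)")
    n = len(exp)
    if n < 2:
        raise ValueError("need at least 2 points for a reduced chi-square")
    if c is None:
        c = fit_scale(exp, calc)
    resid = (exp.intensity - c * calc.intensity) / exp.sigma
    chi2 = float(np.sum(resid**2) / (n - 1))
    return ChiSquareResult(chi2=chi2, c=float(c), n_points=n)


def regrid(profile: SAXSProfile, q_target: np.ndarray) -> SAXSProfile:
    """Linear interpolation of a profile onto ``q_target`` (no extrapolation)."""
    q_target = np.asarray(q_target, dtype=float)
    if q_target.min() < profile.q.min() - 1e-12 or q_target.max() > profile.q.max() + 1e-12:
        raise ValueError(
            f"q_target [{q_target.min():.4g}, {q_target.max():.4g}] extends beyond the "
            f"source range [{profile.q.min():.4g}, {profile.q.max():.4g}]"
        )
    intensity = np.interp(q_target, profile.q, profile.intensity)
    sigma = None if profile.sigma is None else np.interp(q_target, profile.q, profile.sigma)
    return SAXSProfile(q=q_target, intensity=intensity, sigma=sigma)


def read_experimental_profile(path: str | Path) -> SAXSProfile:
    """Read a three-column (q, I, σ) text profile; '#' lines are comments.

    Columns may be separated by whitespace or commas.
    """
    qs, Is, sigmas = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns (q, I, sigma), got {len(parts)}")
            try:
                q, i, s = (float(p) for p in parts[:3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            qs.append(q)
            Is.append(i)
            sigmas.append(s)
    if not qs:
        raise ValueError(f"{path}: no data rows")
    return SAXSProfile(q=np.array(qs), intensity=np.array(Is), sigma=np.array(sigmas))


def _check_shared_grid(a: SAXSProfile, b: SAXSProfile) -> None:
    if len(a) != len(b) or not np.allclose(a.q, b.q, rtol=0, atol=1e-9):
        raise ValueError("profiles are not on a shared q grid; regrid first")
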