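"""Closed-loop validation studies of the analysis stack.

Each function runs one self-contained numerical experiment — an oracle
comparison (analytic sphere scattering, Euler-grid superposition search,
brute-force scale scan) or a parameter-recovery loop on synthetic
ensembles — and returns the measured quantities.  The acceptance script
and the acceptance tests both drive these, so what is asserted and what
is reported are the same computations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import chi1_series, domain_angle_pairs
from .saxs import FormFactorModel, chi_square, debye_profile, default_q_grid, ensemble_profile
from .structure_io import AtomRecord, Structure
from .superpose import kabsch, rmsf
from .synthetic import SyntheticEnsembleConfig, build_template, generate_ensemble, make_mock_experiment

__all__ = [
    "sphere_profile_error",
    "kabsch_vs_grid_search",
    "scale_factor_scan_gap",
    "self_fit_chi2",
    "wrong_angle_chi2_pairs",
    "angle_recovery",
    "rotamer_recovery",
    "rmsf_sigma_recovery",
]


def sphere_profile_error(radius_A: float = 20.0, target_beads: int = 4000,
                         qr_max: float = 4.0, n_q: int = 25) -> float:
    """Max relative deviation of the bead-model Debye profile from the
    analytic solid-sphere form factor [3(sin x − x cos x)/x³]², both
    normalized at q → 0, over q·R ≤ qr_max."""
    a = radius_A * (4.0 * np.pi / (3.0 * target_beads)) ** (1.0 / 3.0)
    grid = np.arange(-radius_A, radius_A + a, a)
    pts = np.array([(x, y, z) for x in grid for y in grid for z in grid
                    if x * x + y * y + z * z <= radius_A**2])
    atoms = [AtomRecord(i + 1, "C", "C", "", "SPH", "A", i + 1, "", tuple(p), 1.0, 0.0, False)
             for i, p in enumerate(pts)]
    s = Structure(atoms=atoms, id="sphere")
    q = np.linspace(0.01, qr_max / radius_A, n_q)
    prof = debye_profile(s, q, FormFactorModel(point=1.0))
    normalized = prof.intensity / len(pts) ** 2  # I(0) = n² for unit beads
    x = q * radius_A
    analytic = (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
    return float(np.max(np.abs(normalized - analytic) / analytic))


def _grid_search_rmsd(P: np.ndarray, Q: np.ndarray, step_deg: float) -> float:
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    a = np.arange(0.0, 360.0, step_deg)
    b = np.arange(0.0, 180.0 + step_deg, step_deg)
    euler = np.array(np.meshgrid(a, b, a)).reshape(3, -1).T
    Rs = Rotation.from_euler("zyz", euler, degrees=True).as_matrix()
    fitted = np.einsum("mij,nj->mni", Rs, P0)
    d = np.sqrt(np.mean(np.sum((fitted - Q0) ** 2, axis=2), axis=1))
    return float(d.min())


def kabsch_vs_grid_search(seed: int = 123, n_points: int = 5,
                          step_deg: float = 6.0) -> tuple[float, float]:
    """(closed-form minimum RMSD, Euler-grid-search minimum) on random
    point sets; the closed form can never exceed the grid value."""
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(n_points, 3))
    Q = rng.normal(size=(n_points, 3))
    _, exact = kabsch(P, Q)
    return exact, _grid_search_rmsd(P, Q, step_deg)


def scale_factor_scan_gap(seed: int = 6, n_scan: int = 20001) -> tuple[float, float]:
    """(closed-form c, best c from a log-spaced brute-force scan)."""
    from .saxs import SAXSProfile, fit_scale

    rng = np.random.default_rng(seed)
    q = np.linspace(0.01, 0.5, 40)
    calc = SAXSProfile(q=q, intensity=rng.uniform(0.5, 4.0, q.size))
    exp = SAXSProfile(q=q, intensity=rng.uniform(0.5, 4.0, q.size),
                      sigma=rng.uniform(0.05, 0.2, q.size))
    c_star = fit_scale(exp, calc)
    grid = np.geomspace(0.01, 100.0, n_scan)
    chi2_grid = np.array([chi_square(exp, calc, c).chi2 for c in grid])
    return c_star, float(grid[int(np.argmin(chi2_grid))])


def self_fit_chi2(seeds: list[int], n_conformers: int = 40, n_q: int = 200,
                  noise_frac: float = 0.02) -> list[float]:
    """Reduced χ² of the generating ensemble against its own noisy mock
    experiment, one value per seed; ideally ≈ 1."""
    template = build_template()
    q = default_q_grid(n=n_q)
    out = []
    for seed in seeds:
        e = generate_ensemble(template, SyntheticEnsembleConfig(
            n_conformers=n_conformers, seed=seed))
        mock = make_mock_experiment(e, q, noise_frac=noise_frac, seed=seed + 10_000)
        calc = ensemble_profile(e, q)
        out.append(chi_square(mock, calc).chi2)
    return out


def wrong_angle_chi2_pairs(seeds: list[int], shift_deg: float = 40.0,
                           n_conformers: int = 40, n_q: int = 200,
                           noise_frac: float = 0.02) -> list[tuple[float, float]]:
    """(χ² of the generating ensemble, χ² of an ensemble whose mean domain
    angle is shifted by ``shift_deg``) per seed; the generating ensemble
    should always fit better."""
    template = build_template()
    q = default_q_grid(n=n_q)
    pairs = []
    for seed in seeds:
        cfg_true = SyntheticEnsembleConfig(n_conformers=n_conformers, seed=seed)
        cfg_wrong = SyntheticEnsembleConfig(
            n_conformers=n_conformers, seed=seed,
            angle_mean_deg=(90.0 + shift_deg, 90.0 + shift_deg))
        e_true = generate_ensemble(template, cfg_true)
        e_wrong = generate_ensemble(template, cfg_wrong)
        mock = make_mock_experiment(e_true, q, noise_frac=noise_frac, seed=seed + 10_000)
        chi_true = chi_square(mock, ensemble_profile(e_true, q)).chi2
        chi_wrong = chi_square(mock, ensemble_profile(e_wrong, q)).chi2
        pairs.append((chi_true, chi_wrong))
    return pairs


def angle_recovery(n_conformers: int = 1000, seed: int = 2024,
                   mean_deg: float = 90.0, sd_deg: float = 10.0) -> dict[str, float]:
    """Sample mean and sd of the measured per-chain domain angles of an
    ensemble generated at the given truncated-Normal parameters."""
    template = build_template()
    cfg = SyntheticEnsembleConfig(n_conformers=n_conformers, seed=seed,
                                  angle_mean_deg=(mean_deg, mean_deg),
                                  angle_sd_deg=(sd_deg, sd_deg))
    pairs = domain_angle_pairs(generate_ensemble(template, cfg))
    a = np.array([p.chain_a_deg for p in pairs])
    b = np.array([p.chain_b_deg for p in pairs])
    return {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
    }


def rotamer_recovery(n_conformers: int = 2000, seed: int = 77,
                     p_in: float = 0.7) -> dict[str, float]:
    """Observed flipped-in (χ1 ≈ 80°) and flipped-out (χ1 ≈ 180°)
    fractions of the marker residue, generated at (p_in, 1 − p_in)."""
    template = build_template()
    cfg = SyntheticEnsembleConfig(
        n_conformers=n_conformers, seed=seed, angle_sd_deg=(0.0, 0.0),
        rotamer_states=((80.0, p_in), (180.0, 1.0 - p_in)),
        rotamer_noise_kappa=400.0, jitter_sd_A=0.02)
    series = chi1_series(generate_ensemble(template, cfg), "A", 296)
    vals = np.mod(series.values_deg, 360.0)
    return {
        "frac_in": float(np.mean(np.abs(vals - 80.0) < 50.0)),
        "frac_out": float(np.mean(np.abs(vals - 180.0) < 50.0)),
    }


def rmsf_sigma_recovery(n_conformers: int = 2000, sigma_A: float = 0.15,
                        seed: int = 7) -> dict[str, float]:
    """Mean Cα RMSF of a pure-jitter ensemble versus the σ√3 expectation
    for isotropic per-coordinate Gaussian noise."""
    template = build_template()
    cfg = SyntheticEnsembleConfig(
        n_conformers=n_conformers, seed=seed, angle_sd_deg=(0.0, 0.0),
        rotamer_states=((80.0, 1.0),), rotamer_noise_kappa=0.0,
        jitter_sd_A=sigma_A)
    e = generate_ensemble(template, cfg)
    mean_rmsf = float(rmsf(e).values().mean())
    expected = sigma_A * np.sqrt(3.0)
    return {"mean_rmsf_A": mean_rmsf, "expected_A": float(expected),
            "ratio": mean_rmsf / expected}
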