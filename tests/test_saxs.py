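import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_atom, point_structure
from fcensemble.saxs import (
    FormFactorModel,
    SAXSProfile,
    chi_square,
    debye_profile,
    default_q_grid,
    ensemble_profile,
    fit_scale,
    read_experimental_profile,
    regrid,
)
from fcensemble.structure_io import ConformerEnsemble, Structure

Q = np.linspace(0.01, 0.5, 40)
POINT1 = FormFactorModel(point=1.0)


def two_point_structure(d):
    return point_structure([[0, 0, 0], [d, 0, 0]])


def test_single_scatterer_constant_intensity():
    s = point_structure([[0, 0, 0]])
    prof = debye_profile(s, Q, FormFactorModel(point=2.0))
    np.testing.assert_allclose(prof.intensity, 4.0)


def test_two_point_analytic_profile():
    d = 10.0
    prof = debye_profile(two_point_structure(d), Q, POINT1)
    expected = 2.0 * (1.0 + np.sin(d * Q) / (d * Q))
    np.testing.assert_allclose(prof.intensity, expected, rtol=1e-12)


def test_intensity_at_zero_is_total_scattering_squared():
    s = Structure([make_atom(serial=i, res_seq=i, element=el,
                             xyz=np.random.default_rng(i).normal(size=3))
                   for i, el in enumerate(["C", "N", "O", "S"], start=1)])
    q = np.array([0.0, 0.1])
    m = FormFactorModel()
    prof = debye_profile(s, q, m)
    f0 = sum(m.f_zero(el) for el in ["C", "N", "O", "S"])
    assert prof.intensity[0] == pytest.approx(f0**2, rel=1e-9)


def test_form_factor_zero_equals_electron_count():
    m = FormFactorModel()
    for el, z in [("H", 1), ("C", 6), ("N", 7), ("O", 8), ("P", 15), ("S", 16)]:
        assert m.f_zero(el) == pytest.approx(z, abs=0.01)


def test_debye_rigid_transform_invariance(template):
    s = template.structure
    R = Rotation.from_euler("xyz", [12, 99, -45], degrees=True).as_matrix()
    moved = s.with_coords(s.coords() @ R.T + np.array([100.0, -5.0, 3.0]))
    q = np.linspace(0.02, 0.4, 15)
    np.testing.assert_allclose(
        debye_profile(moved, q).intensity,
        debye_profile(s, q).intensity,
        rtol=1e-9,
    )


def test_ensemble_profile_of_identical_conformers(template):
    e = ConformerEnsemble(conformers=[template.structure] * 3)
    q = np.linspace(0.02, 0.4, 10)
    np.testing.assert_allclose(
        ensemble_profile(e, q).intensity,
        debye_profile(template.structure, q).intensity,
        rtol=1e-12,
    )


def test_ensemble_profile_is_hand_computed_average():
    e = ConformerEnsemble(conformers=[two_point_structure(10.0), two_point_structure(20.0)])
    prof = ensemble_profile(e, Q, POINT1)
    expected = 0.5 * (2 * (1 + np.sin(10 * Q) / (10 * Q)) + 2 * (1 + np.sin(20 * Q) / (20 * Q)))
    np.testing.assert_allclose(prof.intensity, expected, rtol=1e-12)


def test_ensemble_averaging_is_length_weighted():
    e1 = ConformerEnsemble(conformers=[two_point_structure(10.0)])
    e2 = ConformerEnsemble(conformers=[two_point_structure(20.0), two_point_structure(30.0)])
    cat = ConformerEnsemble(conformers=e1.conformers + e2.conformers)
    i1 = ensemble_profile(e1, Q, POINT1).intensity
    i2 = ensemble_profile(e2, Q, POINT1).intensity
    icat = ensemble_profile(cat, Q, POINT1).intensity
    np.testing.assert_allclose(icat, (1 * i1 + 2 * i2) / 3, rtol=1e-12)


def _exp_profile(intensity, sigma=None, q=Q):
    sigma = np.ones_like(q) if sigma is None else sigma
    return SAXSProfile(q=q, intensity=intensity, sigma=sigma)


def test_fit_scale_recovers_known_factor():
    calc = SAXSProfile(q=Q, intensity=np.exp(-Q * 3))
    exp = _exp_profile(2.0 * calc.intensity, sigma=0.1 * calc.intensity + 0.01)
    assert fit_scale(exp, calc) == pytest.approx(2.0, rel=1e-12)


def test_fit_scale_is_scale_equivariant():
    rng = np.random.default_rng(3)
    calc = SAXSProfile(q=Q, intensity=rng.uniform(1, 5, Q.size))
    exp = _exp_profile(rng.uniform(1, 5, Q.size))
    c1 = fit_scale(exp, calc)
    c2 = fit_scale(exp, SAXSProfile(q=Q, intensity=2.0 * calc.intensity))
    assert c2 == pytest.approx(c1 / 2.0, rel=1e-12)


def test_fit_scale_matches_brute_force_scan():
    rng = np.random.default_rng(6)
    calc = SAXSProfile(q=Q, intensity=rng.uniform(0.5, 4, Q.size))
    exp = _exp_profile(rng.uniform(0.5, 4, Q.size), sigma=rng.uniform(0.05, 0.2, Q.size))
    c_star = fit_scale(exp, calc)
    grid = np.geomspace(0.01, 100.0, 20001)
    chi2_grid = [chi_square(exp, calc, c).chi2 for c in grid]
    c_scan = grid[int(np.argmin(chi2_grid))]
    assert c_star == pytest.approx(c_scan, rel=1e-3)
    assert chi_square(exp, calc, c_star).chi2 <= min(chi2_grid) + 1e-12


def test_chi_square_zero_for_proportional_profiles():
    calc = SAXSProfile(q=Q, intensity=np.exp(-Q))
    exp = _exp_profile(3.7 * calc.intensity)
    assert chi_square(exp, calc).chi2 == pytest.approx(0.0, abs=1e-20)


def test_chi_square_hand_arithmetic_two_points():
    q = np.array([0.1, 0.2])
    exp = SAXSProfile(q=q, intensity=np.array([1.0, 3.0]), sigma=np.array([1.0, 1.0]))
    calc = SAXSProfile(q=q, intensity=np.array([1.0, 1.0]))
    res = chi_square(exp, calc)
    assert res.c == pytest.approx(2.0)
    assert res.chi2 == pytest.approx(2.0)
    assert res.n_points == 2


def test_chi_square_invariant_under_calc_rescale_with_refit():
    rng = np.random.default_rng(12)
    calc = SAXSProfile(q=Q, intensity=rng.uniform(1, 2, Q.size))
    exp = _exp_profile(rng.uniform(1, 2, Q.size), sigma=np.full(Q.size, 0.1))
    a = chi_square(exp, calc).chi2
    b = chi_square(exp, SAXSProfile(q=Q, intensity=5.0 * calc.intensity)).chi2
    assert a == pytest.approx(b, rel=1e-12)


def test_chi_square_requires_sigma_and_two_points():
    calc = SAXSProfile(q=Q, intensity=np.ones(Q.size))
    with pytest.raises(ValueError):
        chi_square(calc, calc)


def test_regrid_identity_and_midpoint():
    prof = SAXSProfile(q=np.array([0.1, 0.2, 0.3]), intensity=np.array([1.0, 3.0, 5.0]))
    same = regrid(prof, prof.q)
    np.testing.assert_allclose(same.intensity, prof.intensity)
    mid = regrid(prof, np.array([0.15, 0.25]))
    np.testing.assert_allclose(mid.intensity, [2.0, 4.0])


def test_regrid_round_trip_on_dense_grid():
    q_dense = np.linspace(0.02, 0.4, 200)
    prof = SAXSProfile(q=q_dense, intensity=np.exp(-3 * q_dense) + 0.1 * np.sin(20 * q_dense))
    q_coarse = np.linspace(0.05, 0.35, 40)
    back = regrid(regrid(prof, q_coarse), q_coarse)
    np.testing.assert_allclose(back.intensity, regrid(prof, q_coarse).intensity, rtol=1e-12)


def test_regrid_refuses_extrapolation():
    prof = SAXSProfile(q=np.array([0.1, 0.2]), intensity=np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        regrid(prof, np.array([0.05, 0.15]))


def test_residue_bead_matches_atomic_at_low_q(template):
    s = template.structure
    coords = s.coords()
    rg = np.sqrt(np.mean(np.sum((coords - coords.mean(0)) ** 2, axis=1)))
    q = np.linspace(0.005, 1.0 / rg, 12)
    atomic = debye_profile(s, q, granularity="atomic").intensity
    beads = debye_profile(s, q, granularity="residue-bead").intensity
    rel = np.abs(beads / beads[0] - atomic / atomic[0])
    assert rel.max() < 0.05


def test_read_experimental_profile_formats(tmp_path):
    text = "# q I sigma\n0.01 10.0 0.5\n0.02,9.0,0.4\n\n0.03\t8.0\t0.3\n"
    p = tmp_path / "exp.dat"
    p.write_text(text)
    prof = read_experimental_profile(p)
    assert len(prof) == 3
    np.testing.assert_allclose(prof.q, [0.01, 0.02, 0.03])
    np.testing.assert_allclose(prof.sigma, [0.5, 0.4, 0.3])


def test_read_experimental_profile_rejects_bad_rows(tmp_path):
    p = tmp_path / "bad.dat"
    p.write_text("0.01 1.0\n")
    with pytest.raises(ValueError, match="3 columns"):
        read_experimental_profile(p)


def test_default_q_grid_covers_measured_range():
    q = default_q_grid()
    assert q[0] == pytest.approx(0.015) and q[-1] == pytest.approx(0.5)
    assert len(q) == 200 and np.all(np.diff(q) > 0)
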