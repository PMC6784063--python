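import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_atom, point_structure
from fcensemble.structure_io import ConformerEnsemble, Selection, Structure
from fcensemble.superpose import (
    DegenerateInputError,
    average_structure,
    kabsch,
    min_rmsd_to_reference,
    rmsd,
    rmsf,
)

CA = Selection(atom_names=frozenset({"CA"}))


def grid_search_rmsd(P, Q, step_deg=4.0):
    """Brute-force minimum RMSD over a fine Euler-angle grid (oracle)."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    a = np.arange(0.0, 360.0, step_deg)
    b = np.arange(0.0, 180.0 + step_deg, step_deg)
    euler = np.array(np.meshgrid(a, b, a)).reshape(3, -1).T
    Rs = Rotation.from_euler("zyz", euler, degrees=True).as_matrix()
    fitted = np.einsum("mij,nj->mni", Rs, P0)
    d = np.sqrt(np.mean(np.sum((fitted - Q0) ** 2, axis=2), axis=1))
    return float(d.min())


def test_kabsch_identity():
    P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    tf, r = kabsch(P, P)
    np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(tf.translation, 0.0, atol=1e-12)
    assert r == pytest.approx(0.0, abs=1e-12)


def test_kabsch_recovers_pure_rotation():
    P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    tf, r = kabsch(P, P @ R90.T)
    np.testing.assert_allclose(tf.rotation, R90, atol=1e-8)
    assert r == pytest.approx(0.0, abs=1e-10)


def test_kabsch_matches_scipy_align_vectors():
    rng = np.random.default_rng(5)
    P = rng.normal(size=(8, 3))
    Q = rng.normal(size=(8, 3))
    _, r = kabsch(P, Q)
    rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
    assert r == pytest.approx(rssd / np.sqrt(len(P)), rel=1e-9)


def test_kabsch_never_worse_than_unfitted():
    rng = np.random.default_rng(17)
    for _ in range(20):
        P, Q = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        _, r = kabsch(P, Q)
        assert r <= rmsd(P, Q) + 1e-12


def test_kabsch_degenerate_inputs_raise():
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
    with pytest.raises(DegenerateInputError):
        kabsch(line, line + 1.0)
    with pytest.raises(DegenerateInputError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (np.zeros((3, 3)), np.zeros((3, 3)), 0.0),
        (np.array([[0.0, 0, 0]]), np.array([[2.0, 0, 0]]), 2.0),
        (np.array([[0.0, 0, 0], [0, 0, 0]]), np.array([[0.0, 0, 0], [2.0, 0, 0]]), np.sqrt(2.0)),
    ],
)
def test_rmsd_closed_forms(a, b, expected):
    assert rmsd(a, b) == pytest.approx(expected)


def test_rmsd_shape_mismatch():
    with pytest.raises(ValueError):
        rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


def _jitter_ensemble(base, n, sigma, seed):
    rng = np.random.default_rng(seed)
    confs = [base.with_coords(base.coords() + rng.normal(0, sigma, (len(base), 3)))
             for _ in range(n)]
    return ConformerEnsemble(conformers=confs)


def test_average_of_identical_conformers():
    base = point_structure(np.random.default_rng(0).normal(size=(6, 3)))
    e = ConformerEnsemble(conformers=[base, base, base])
    avg = average_structure(e, CA)
    np.testing.assert_allclose(avg.coords(), base.coords(), atol=1e-12)


def test_average_removes_pure_rotation():
    base = point_structure(np.random.default_rng(1).normal(size=(6, 3)) * 3)
    R = Rotation.from_euler("xyz", [11, 23, 37], degrees=True).as_matrix()
    rotated = base.with_coords(base.coords() @ R.T + np.array([1.0, -2.0, 0.5]))
    e = ConformerEnsemble(conformers=[base, rotated])
    avg = average_structure(e, CA)
    _, r = kabsch(avg.coords(), base.coords())
    assert r < 1e-6


def test_average_of_jittered_ensemble_near_template(template):
    """The iterated mean converges on the template at the σ/√n rate."""
    sigma, n = 0.1, 200
    e = _jitter_ensemble(template.structure, n, sigma, seed=42)
    avg = average_structure(e, Selection(atom_names=frozenset({"CA"}), hetero="exclude"))
    tf, _ = kabsch(avg.coords(), template.structure.coords())
    aligned = tf.apply(avg.coords())
    dev = np.abs(aligned - template.structure.coords())
    se = sigma / np.sqrt(n)
    # per-coordinate Monte-Carlo bound; 4 s.e. covers the max over the
    # ~300 coordinates being checked at once
    assert dev.max() <= 4 * se
    assert np.sqrt(np.mean(dev**2)) <= 1.5 * se


def test_rmsf_identical_conformers_is_zero():
    base = point_structure(np.random.default_rng(3).normal(size=(5, 3)))
    e = ConformerEnsemble(conformers=[base] * 4)
    assert np.all(rmsf(e, CA, CA).values() == pytest.approx(0.0, abs=1e-12))


def test_rmsf_of_alternating_atom_is_half_amplitude():
    """A large rigid anchor plus one atom flipping ±d/2 along x."""
    rng = np.random.default_rng(9)
    anchor = rng.normal(size=(40, 3)) * 5
    d = 1.6
    confs = []
    for k in range(10):
        pts = np.vstack([anchor, [10 + (d / 2) * (-1) ** k, 0, 0]])
        confs.append(point_structure(pts))
    e = ConformerEnsemble(conformers=confs)
    # fit on the noiseless anchors only, so the fit is exactly the identity
    anchors_only = Selection(res_range=(1, 40))
    vals = rmsf(e, anchors_only, CA).values()
    assert vals[-1] == pytest.approx(d / 2, rel=1e-9)
    assert np.all(vals[:-1] == pytest.approx(0.0, abs=1e-9))


def test_rmsf_invariant_under_global_rigid_motion(small_ensemble):
    R = Rotation.from_euler("xyz", [30, -60, 95], degrees=True).as_matrix()
    t = np.array([5.0, -3.0, 8.0])
    moved = ConformerEnsemble(
        conformers=[c.with_coords(c.coords() @ R.T + t) for c in small_ensemble]
    )
    np.testing.assert_allclose(
        rmsf(moved).values(), rmsf(small_ensemble).values(), atol=1e-6
    )


def test_rmsf_requires_two_conformers(template):
    with pytest.raises(ValueError):
        rmsf(ConformerEnsemble(conformers=[template.structure]))


def test_min_rmsd_finds_member_exactly(small_ensemble):
    idx, r = min_rmsd_to_reference(small_ensemble, small_ensemble[3])
    assert idx == 3 and r == pytest.approx(0.0, abs=1e-9)


def test_min_rmsd_matches_exhaustive_kabsch(small_ensemble, template):
    sel = Selection(atom_names=frozenset({"CA"}), hetero="exclude")
    ref = template.structure
    idx, r = min_rmsd_to_reference(small_ensemble, ref, sel)
    ref_xyz = ref.coords()
    ca = [i for i, a in enumerate(ref.atoms) if sel.matches(a)]
    per_conf = []
    for conf in small_ensemble:
        _, d = kabsch(conf.coords()[ca], ref_xyz[ca])
        per_conf.append(d)
    assert idx == int(np.argmin(per_conf))
    assert r == pytest.approx(min(per_conf), rel=1e-12)
    assert all(r <= d + 1e-12 for d in per_conf)


def test_min_rmsd_honours_residue_exclusions(small_ensemble, template):
    excl = {("A", 296), ("B", 296)}
    idx, r = min_rmsd_to_reference(small_ensemble, template.structure,
                                   exclude_residues=excl)
    assert np.isfinite(r)


def test_kabsch_matches_grid_search_oracle():
    rng = np.random.default_rng(123)
    P = rng.normal(size=(5, 3))
    Q = rng.normal(size=(5, 3))
    _, exact = kabsch(P, Q)
    approx = grid_search_rmsd(P, Q, step_deg=6.0)
    assert exact <= approx + 1e-12
    # grid resolution 6° on unit-scale points bounds the oracle gap
    assert approx - exact < 0.15
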