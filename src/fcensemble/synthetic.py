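"""Synthetic Fc-like conformer ensembles for closed-loop testing.

Real Fc ensembles come from molecular dynamics; none are redistributable
here, so this module builds a miniature two-chain template with the same
*statistical* handles the analyses measure — a per-chain C_H2–C_H3
domain-orientation angle, a Tyr-like marker residue with a settable χ1,
and a glycan-like branch of carbohydrate-named residues packed between
the chains — and samples ensembles around it:

* per-chain domain angles drawn from a truncated Normal and realized
  exactly (pre-jitter) by rigidly rotating the C_H2 cluster about the
  hinge pivot;
* a discrete χ1 rotamer state drawn per chain from a categorical
  distribution, with von Mises angular noise;
* isotropic Gaussian jitter on every coordinate.

The distributions are stand-ins chosen for testability, not a physical
model: there are no sterics and no force field.  A fixed seed gives
bit-identical ensembles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from . import geometry
from .geometry import DEFAULT_ANGLE_TRIPLE, AngleTriple, chi1, dihedral, domain_angle
from .saxs import FormFactorModel, SAXSProfile, ensemble_profile
from .structure_io import AtomRecord, ConformerEnsemble, Structure

__all__ = [
    "SyntheticEnsembleConfig",
    "ToyFcTemplate",
    "SamplingPlan",
    "sampling_plan",
    "build_template",
    "generate_ensemble",
    "make_mock_experiment",
]


@dataclass(frozen=True)
class SamplingPlan:
    """Conformer bookkeeping of an extraction scheme.

    ``per_run`` conformers are taken from each production run of
    ``run_length_ns`` at one frame every ``stride_ps``; ``total`` over all
    runs.  The defaults mirror a common long-timescale protocol: eight
    320 ns runs sampled every 100 ps.
    """

    run_length_ns: float
    stride_ps: float
    n_runs: int

    @property
    def per_run(self) -> int:
        return int(round(self.run_length_ns * 1000.0 / self.stride_ps))

    @property
    def total(self) -> int:
        return self.per_run * self.n_runs


def sampling_plan(
    run_length_ns: float = 320.0, stride_ps: float = 100.0, n_runs: int = 8
) -> SamplingPlan:
    return SamplingPlan(run_length_ns, stride_ps, n_runs)


@dataclass(frozen=True)
class SyntheticEnsembleConfig:
    """Distribution parameters and seed for the generator.

    angle_mean_deg / angle_sd_deg: per-chain Gaussian over the domain
    angle (degrees), truncated to (0, 180).  rotamer_states: (χ1 degrees,
    probability) pairs; probabilities must sum to 1.  rotamer_noise_kappa:
    von Mises concentration of the angular noise around the drawn state.
    jitter_sd_A: isotropic Gaussian jitter per coordinate (Å).
    correlate_chains: correlation ρ between the two chains' angle draws
    (0 = independent).
    """

    n_conformers: int = 200
    seed: int = 0
    angle_mean_deg: tuple[float, float] = (90.0, 90.0)
    angle_sd_deg: tuple[float, float] = (10.0, 10.0)
    rotamer_states: tuple[tuple[float, float], ...] = ((80.0, 0.7), (180.0, 0.3))
    rotamer_noise_kappa: float = 50.0
    jitter_sd_A: float = 0.25
    correlate_chains: float = 0.0

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be ≥ 1")
        total_p = sum(p for _, p in self.rotamer_states)
        if abs(total_p - 1.0) > 1e-9:
            raise ValueError(f"rotamer probabilities sum to {total_p}, not 1")
        if any(sd < 0 for sd in self.angle_sd_deg) or self.jitter_sd_A < 0:
            raise ValueError("standard deviations must be non-negative")
        if not -1.0 <= self.correlate_chains <= 1.0:
            raise ValueError("correlate_chains must be a correlation in [-1, 1]")


@dataclass
class ToyFcTemplate:
    """Two-chain miniature Fc with known construction parameters.

    Per chain the template records which atoms form the rigid C_H2
    cluster, the hinge pivot and rotation axis, the indices of the
    angle-triple Cα atoms, and the marker residue's χ1 atoms, so the
    generator can manipulate the geometry without re-searching atoms.
    """

    structure: Structure
    chains: tuple[str, str]
    triple: AngleTriple
    ch2_indices: dict[str, np.ndarray]
    pivot_index: dict[str, int]
    axis: dict[str, np.ndarray]
    triple_indices: dict[str, tuple[int, int, int]]
    marker_indices: dict[str, tuple[int, int, int, int]]  # N, CA, CB, CG
    marker_res_seq: int
    angle_deg: dict[str, float]
    chi1_deg: float
    glycan_contact_distance_A: float


# --- geometric helpers ------------------------------------------------------

def _rotate_about(coords: np.ndarray, idx: np.ndarray, pivot: np.ndarray,
                  axis: np.ndarray, angle_rad: float) -> None:
    """Rotate coords[idx] in place about an axis through pivot."""
    R = Rotation.from_rotvec(axis * angle_rad).as_matrix()
    coords[idx] = pivot + (coords[idx] - pivot) @ R.T


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Extend a→b→c by one atom with given bond, angle and torsion (NeRF)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    theta = math.radians(angle_deg)
    tau = math.radians(torsion_deg)
    d_local = np.array(
        [-bond * math.cos(theta),
         bond * math.sin(theta) * math.cos(tau),
         bond * math.sin(theta) * math.sin(tau)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _angle_vs_rotation(coords: np.ndarray, pivot: np.ndarray, axis: np.ndarray,
                       tri: tuple[int, int, int]):
    """Closed-over scalar θ(δ): the domain angle after rotating the moving
    triple atom by δ about the pivot axis.  Also returns a vectorized form
    for bracket scanning."""
    y_idx, v_idx, q_idx = tri
    y0, V, Q = coords[y_idx], coords[v_idx], coords[q_idx]
    rel = y0 - pivot
    a_par = axis * np.dot(rel, axis)
    u = rel - a_par
    r = np.linalg.norm(u)
    if r < 1e-9:
        raise ValueError("moving triple atom lies on the rotation axis")
    u = u / r
    w = np.cross(axis, u)
    A = (pivot + a_par) - V
    v2 = Q - V
    nv2 = np.linalg.norm(v2)
    alpha, beta, gamma = np.dot(A, v2), r * np.dot(u, v2), r * np.dot(w, v2)
    aa, bb, cc = np.dot(A, A) + r * r, 2 * r * np.dot(A, u), 2 * r * np.dot(A, w)

    def theta(delta):
        cosd, sind = np.cos(delta), np.sin(delta)
        num = alpha + beta * cosd + gamma * sind
        den = nv2 * np.sqrt(aa + bb * cosd + cc * sind)
        return np.degrees(np.arccos(np.clip(num / den, -1.0, 1.0)))

    return theta


def _realize_angle(coords: np.ndarray, ch2_idx: np.ndarray, pivot: np.ndarray,
                   axis: np.ndarray, tri: tuple[int, int, int],
                   target_deg: float) -> None:
    """Rotate the C_H2 cluster so the domain angle equals target exactly."""
    theta = _angle_vs_rotation(coords, pivot, axis, tri)
    grid = np.linspace(-np.pi, np.pi, 1441)
    vals = theta(grid) - target_deg
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        exact = np.nonzero(vals == 0.0)[0]
        if len(exact):
            delta = float(grid[exact[0]])
        else:
            raise ValueError(
                f"domain angle {target_deg:.2f}° is not realizable by a hinge "
                f"rotation (reachable range {theta(grid).min():.1f}–{theta(grid).max():.1f}°)"
            )
    else:
        k = sign_change[0]
        delta = brentq(lambda d: float(theta(d) - target_deg),
                       grid[k], grid[k + 1], xtol=1e-14)
    if abs(delta) > 1e-15:
        _rotate_about(coords, ch2_idx, pivot, axis, delta)


def _set_chi1(coords: np.ndarray, marker: tuple[int, int, int, int],
              target_deg: float) -> None:
    """Rotate Cγ about the CA→CB axis so χ1 equals target exactly."""
    n_i, ca_i, cb_i, cg_i = marker
    current = dihedral(coords[n_i], coords[ca_i], coords[cb_i], coords[cg_i])
    delta = math.radians(target_deg - current)
    axis = coords[cb_i] - coords[ca_i]
    axis = axis / np.linalg.norm(axis)
    _rotate_about(coords, np.array([cg_i]), coords[cb_i], axis, delta)


# --- template construction --------------------------------------------------

def _ca(serial, res_name, chain, res_seq, xyz, hetero=False, name="CA", element="C"):
    return AtomRecord(
        serial=serial, name=name, element=element, alt_loc="",
        res_name=res_name, chain_id=chain, res_seq=res_seq, i_code="",
        xyz=tuple(float(v) for v in xyz), occupancy=1.0, b_factor=0.0,
        is_hetero=hetero,
    )


# C_H2 / C_H3 anchor offsets: small rigid, non-degenerate 3-D clusters.
_CH2_ANCHOR_OFFSETS = [
    (0.0, 0.0, 0.0), (1.5, 0.5, 0.3), (0.5, 1.5, -0.4), (-0.8, 0.9, 0.6),
    (1.1, -0.7, -0.5), (-0.5, -1.2, 0.4), (2.0, 1.6, -0.2), (-1.4, 0.2, -0.7),
]
_CH3_ANCHOR_OFFSETS = [
    (0.0, 0.0, 0.0), (1.4, 0.6, 0.4), (0.4, 1.3, -0.5), (-0.9, 0.8, 0.5),
    (1.2, -0.8, -0.3), (-0.6, -1.1, 0.6), (1.9, 1.4, -0.4), (-1.3, 0.3, -0.6),
]


def build_template(
    angle_deg: tuple[float, float] = (90.0, 90.0),
    chi1_deg: float = 80.0,
    glycan_contact_distance_A: float = 3.5,
    triple: AngleTriple = DEFAULT_ANGLE_TRIPLE,
) -> ToyFcTemplate:
    """Build the two-chain toy template at the requested geometry.

    The construction is self-validating: the measured domain angles and
    marker χ1 must equal the requested values within 1e-6° and at least
    one glycan–protein heavy-atom pair sits at the requested distance,
    otherwise the request is unrealizable and a ValueError is raised.
    """
    (y_key, v_key, q_key) = triple.keys
    marker_res = 296

    # ---- chain A protein, laid out with the angle-triple plane at z = 0.
    # The hinge pivot (residue 236 CA) sits at (5, 7, 0); the moving triple
    # atom circles it with radius 9.5 while the vertex (M428 analogue, at
    # (8, 0, 0)) lies 7.6 from the pivot, i.e. inside the circle, so every
    # domain angle in (0, 180) is reachable by a hinge rotation.
    protein_a: list[tuple[str, int, str, str, np.ndarray]] = []

    def pa(res_name, res_seq, xyz, name="CA", element="C"):
        protein_a.append((res_name, res_seq, name, element, np.asarray(xyz, dtype=float)))

    for rs, xyz in zip((234, 235, 236),
                       [(2.0, 10.0, 0.0), (3.5, 8.5, 0.0), (5.0, 7.0, 0.0)]):
        pa("GLY", rs, xyz)
    for rs, off in zip(range(240, 248), _CH2_ANCHOR_OFFSETS):
        pa("GLY", rs, np.array([6.0, 4.0, 0.8]) + off)
    # marker residue: Tyr-like N/CA/CB/CG with χ1 set by construction
    n_xyz = np.array([4.2, 3.0, 0.6])
    ca_xyz = np.array([5.0, 4.0, 0.2])
    cb_xyz = _place_atom(np.array([4.2, 3.0, 3.0]), n_xyz, ca_xyz, 1.53, 110.5, -65.0)
    cg_xyz = _place_atom(n_xyz, ca_xyz, cb_xyz, 1.52, 114.0, chi1_deg)
    pa("TYR", marker_res, n_xyz, name="N", element="N")
    pa("TYR", marker_res, ca_xyz, name="CA")
    pa("TYR", marker_res, cb_xyz, name="CB")
    pa("TYR", marker_res, cg_xyz, name="CG")
    # moving triple atom (Tyr300 Cα analogue); its radius about the pivot
    # (8.7) exceeds the pivot–vertex distance (7.6), so the vertex lies
    # inside the swept circle and all angles are reachable
    pa("TYR", y_key[0], (7.0, -1.5, 0.0), name=y_key[1])
    for rs, off in zip(range(350, 358), _CH3_ANCHOR_OFFSETS):
        pa("GLY", rs, np.array([8.0, -5.0, -0.5]) + off)
    pa("GLN", q_key[0], (8.0, -8.0, 0.0), name=q_key[1])
    pa("MET", v_key[0], (8.0, 0.0, 0.0), name=v_key[1])

    # chain B protein: chain A rotated 180° about z (proper rotation, so
    # chirality and χ1 are preserved; the triple plane stays at z = 0)
    Rz = np.diag([-1.0, -1.0, 1.0])
    protein: list[tuple[str, str, int, str, str, np.ndarray]] = []
    for ch, transform in (("A", np.eye(3)), ("B", Rz)):
        for res_name, res_seq, name, element, xyz in protein_a:
            protein.append((ch, res_name, res_seq, name, element, transform @ xyz))

    coords = np.array([p[5] for p in protein])

    def find(chain, res_seq, name):
        for i, p in enumerate(protein):
            if p[0] == chain and p[2] == res_seq and p[3] == name:
                return i
        raise KeyError((chain, res_seq, name))

    chains = ("A", "B")
    ch2_lists, pivots, axes, tri_idx = {}, {}, {}, {}
    for ch in chains:
        ch2_lists[ch] = np.array(
            [i for i, p in enumerate(protein) if p[0] == ch and 240 <= p[2] <= 300],
            dtype=int,
        )
        pivots[ch] = find(ch, 236, "CA")
        tri_idx[ch] = (find(ch, y_key[0], y_key[1]),
                       find(ch, v_key[0], v_key[1]),
                       find(ch, q_key[0], q_key[1]))
        y, v, q = (coords[j] for j in tri_idx[ch])
        n = np.cross(y - v, q - v)
        axes[ch] = n / np.linalg.norm(n)

    # realize the requested angles on the protein coordinates
    for ch, target in zip(chains, angle_deg):
        _realize_angle(coords, ch2_lists[ch], coords[pivots[ch]],
                       axes[ch], tri_idx[ch], target)

    # ---- glycans, placed after the hinge rotation so the designated
    # contact distance is exact in the finished template.  Each branch
    # rises along +z from its chain's C_H2 anchor (residue 240 CA) —
    # NAG 501 C1 exactly at the requested distance — and leans toward the
    # dyad axis; the two terminal MAN 504 residues meet near x = y = 0,
    # giving a stable carbohydrate–carbohydrate contact.
    glycans: list[tuple[str, str, int, str, np.ndarray]] = []
    zhat = np.array([0.0, 0.0, 1.0])
    for ch, sign in (("A", 1.0), ("B", -1.0)):
        # anchor on the chain's highest protein atom: every other protein
        # atom then lies at ≥ the designated distance from NAG 501 C1
        chain_idx = [i for i, p in enumerate(protein) if p[0] == ch]
        anchor = coords[max(chain_idx, key=lambda i: coords[i][2])]
        g0 = anchor + glycan_contact_distance_A * zhat
        center_dir = -anchor[:2] / max(np.linalg.norm(anchor[:2]), 1e-9)
        c3 = np.array([center_dir[0], center_dir[1], 0.0])
        man = np.array([sign * 0.8, sign * 1.0, anchor[2] + glycan_contact_distance_A + 3.4])
        sites = [
            ("NAG", 501, g0),
            ("NAG", 502, g0 + 1.0 * c3 + np.array([0.0, 0.0, 1.2])),
            ("BMA", 503, g0 + 2.0 * c3 + np.array([0.0, 0.0, 2.4])),
            ("MAN", 504, man),
        ]
        for res_name, rs, base in sites:
            glycans.append((ch, res_name, rs, "C1", base))
            glycans.append((ch, res_name, rs, "C2", base + np.array([0.3, 0.2, 0.9])))

    # ---- assemble the final structure: per chain, protein then glycan ----
    atoms: list[AtomRecord] = []
    serial = 1
    for ch in chains:
        for i, (c, res_name, res_seq, name, element, _) in enumerate(protein):
            if c != ch:
                continue
            atoms.append(_ca(serial, res_name, ch, res_seq, coords[i],
                             name=name, element=element))
            serial += 1
        for c, res_name, res_seq, name, base in glycans:
            if c != ch:
                continue
            atoms.append(_ca(serial, res_name, ch, res_seq, base,
                             hetero=True, name=name, element="C"))
            serial += 1

    s = Structure(atoms=atoms, id="toy-fc-template")
    final = s.coords()

    def find_final(chain, res_seq, name):
        for i, a in enumerate(atoms):
            if a.chain_id == chain and a.res_seq == res_seq and a.name == name:
                return i
        raise KeyError((chain, res_seq, name))

    ch2_indices, pivot_index, axis, tri_final, marker_idx = {}, {}, {}, {}, {}
    for ch in chains:
        ch2_indices[ch] = np.array(
            [i for i, a in enumerate(atoms)
             if a.chain_id == ch and not a.is_hetero and 240 <= a.res_seq <= 300],
            dtype=int,
        )
        pivot_index[ch] = find_final(ch, 236, "CA")
        tri_final[ch] = (find_final(ch, y_key[0], y_key[1]),
                         find_final(ch, v_key[0], v_key[1]),
                         find_final(ch, q_key[0], q_key[1]))
        y, v, q = (final[j] for j in tri_final[ch])
        n = np.cross(y - v, q - v)
        axis[ch] = n / np.linalg.norm(n)
        marker_idx[ch] = (find_final(ch, marker_res, "N"),
                          find_final(ch, marker_res, "CA"),
                          find_final(ch, marker_res, "CB"),
                          find_final(ch, marker_res, "CG"))

    # ---- self-validation ----
    for ch, target in zip(chains, angle_deg):
        measured = domain_angle(s, ch, triple)
        if abs(measured - target) > 1e-6:
            raise ValueError(
                f"chain {ch}: requested angle {target}° not realized (got {measured}°)")
        measured_chi1 = chi1(s, ch, marker_res)
        if abs(measured_chi1 - chi1_deg) > 1e-6:
            raise ValueError(
                f"chain {ch}: requested χ1 {chi1_deg}° not realized (got {measured_chi1}°)")
    gly_xyz = np.array([a.xyz for a in atoms if a.is_hetero])
    prot_xyz = np.array([a.xyz for a in atoms if not a.is_hetero])
    dmin = np.min(np.linalg.norm(gly_xyz[:, None, :] - prot_xyz[None, :, :], axis=2))
    if abs(dmin - glycan_contact_distance_A) > 1e-6:
        raise ValueError(
            f"closest glycan–protein distance is {dmin:.4f} Å, not the requested "
            f"{glycan_contact_distance_A} Å; geometry not realizable as laid out")

    return ToyFcTemplate(
        structure=s, chains=chains, triple=triple,
        ch2_indices=ch2_indices, pivot_index=pivot_index, axis=axis,
        triple_indices=tri_final, marker_indices=marker_idx,
        marker_res_seq=marker_res, angle_deg={c: a for c, a in zip(chains, angle_deg)},
        chi1_deg=chi1_deg, glycan_contact_distance_A=glycan_contact_distance_A,
    )


# --- sampling ---------------------------------------------------------------

def _draw_angles(rng: np.random.Generator, cfg: SyntheticEnsembleConfig) -> tuple[float, float]:
    """Per-chain domain angles: (possibly correlated) truncated Normal."""
    mu = np.asarray(cfg.angle_mean_deg, dtype=float)
    sd = np.asarray(cfg.angle_sd_deg, dtype=float)
    rho = cfg.correlate_chains
    cov = np.array([[sd[0] ** 2, rho * sd[0] * sd[1]],
                    [rho * sd[0] * sd[1], sd[1] ** 2]])
    for _ in range(1000):
        if np.all(sd == 0):
            return float(mu[0]), float(mu[1])
        a, b = rng.multivariate_normal(mu, cov, method="cholesky")
        if 0.0 < a < 180.0 and 0.0 < b < 180.0:
            return float(a), float(b)
    raise RuntimeError("truncated-normal rejection sampling failed; check angle parameters")


def generate_ensemble(
    template: ToyFcTemplate, cfg: SyntheticEnsembleConfig
) -> ConformerEnsemble:
    """Sample a conformer ensemble around the template.

    Per conformer and chain: realize a truncated-Normal domain angle by a
    rigid hinge rotation of the C_H2 cluster, set the marker χ1 to a drawn
    rotamer state plus von Mises noise, then jitter every coordinate with
    isotropic Gaussian noise.  Fixed seed ⇒ bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    base = template.structure.coords()
    states = np.array([s for s, _ in cfg.rotamer_states], dtype=float)
    probs = np.array([p for _, p in cfg.rotamer_states], dtype=float)
    conformers = []
    for k in range(cfg.n_conformers):
        coords = base.copy()
        targets = _draw_angles(rng, cfg)
        for ch, target in zip(template.chains, targets):
            _realize_angle(coords, template.ch2_indices[ch],
                           coords[template.pivot_index[ch]],
                           template.axis[ch], template.triple_indices[ch], target)
        for ch in template.chains:
            state = states[rng.choice(len(states), p=probs)]
            if cfg.rotamer_noise_kappa > 0:
                state += math.degrees(rng.vonmises(0.0, cfg.rotamer_noise_kappa))
            _set_chi1(coords, template.marker_indices[ch], float(state))
        if cfg.jitter_sd_A > 0:
            coords += rng.normal(0.0, cfg.jitter_sd_A, coords.shape)
        conf = template.structure.with_coords(coords)
        conf.id = f"synthetic/{k}"
        conformers.append(conf)
    return ConformerEnsemble(conformers=conformers)


def make_mock_experiment(
    e: ConformerEnsemble,
    q: np.ndarray,
    noise_frac: float = 0.02,
    seed: int = 0,
    model: FormFactorModel | None = None,
    granularity: str = "atomic",
) -> SAXSProfile:
    """Synthetic "experimental" SAXS curve from an ensemble.

    The ensemble-average profile is perturbed with multiplicative Gaussian
    noise of relative sd ``noise_frac``; σ is set to ``noise_frac·I`` of
    the noiseless curve, so refitting the generating ensemble yields a
    reduced χ² near 1.  ``noise_frac = 0`` returns the exact profile with
    a tiny floor σ so χ² remains defined.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be ≥ 0")
    rng = np.random.default_rng(seed)
    clean = ensemble_profile(e, q, model, granularity)
    if noise_frac == 0.0:
        sigma = np.maximum(1e-12 * np.abs(clean.intensity), 1e-30)
        return SAXSProfile(q=clean.q, intensity=clean.intensity.copy(), sigma=sigma)
    noisy = clean.intensity * (1.0 + rng.normal(0.0, noise_frac, clean.intensity.shape))
    sigma = noise_frac * np.abs(clean.intensity)
    return SAXSProfile(q=clean.q, intensity=noisy, sigma=sigma)
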