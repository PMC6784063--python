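# Methods

This note records the models, conventions and numerical choices behind
each analysis, what the synthetic data emulate, and what the tests do and
do not demonstrate about real data.

## Coordinate handling

Structures are flat lists of typed atom records parsed from fixed-column
PDB (gemmi does the reading; writing is done directly so the round trip
is exact at format precision, coordinates to 3 decimals).  Author residue
numbering is preserved — EU-style numbers such as Tyr296 or Met428 are
whatever the file says; nothing is renumbered.  Alternative locations are
resolved at read time to a single record per atom: highest occupancy
wins, ties go to the lexicographically smallest altloc character.  Only
the first MODEL is read for single-structure work; the multi-model reader
returns an ensemble and refuses files whose models disagree on the atom
set, naming the first offending atom.  Carbohydrate residues are
identified by name (NAG, FUC, BMA, MAN, GAL, NDG, FUL, GLA; the set is a
module constant callers may replace).  Hydrogens are kept on read; each
analysis decides its own exclusion rule.

## Superposition, average structure, RMSF

Kabsch superposition is the standard SVD solution with the determinant
correction that forbids reflections; inputs of fewer than 3 points or
rank < 2 raise rather than returning an arbitrary rotation.  The
ensemble-average structure is computed iteratively: fit every conformer
to the current mean on the fit selection (all Cα by default), recompute
the coordinate-wise arithmetic mean (no mass weighting), and stop when
the mean moves by less than 1e-6 Å RMSD (max 100 iterations; conformer 1
seeds the loop).  The iterated mean is order-independent, which a single
pass over conformers is not; whether to fit to the first conformer, to a
pairwise scheme, or to a converged mean was genuinely open, and the
converged mean was chosen as the only order-free option.  RMSF is then
the per-atom RMS deviation from the converged average after fitting each
conformer to it; reported per Cα by default but any reporting selection
works.  Because the fitted atoms participate in the rigid fit, a pure
noise ensemble yields an RMSF about 1−2/N_fit of σ√3 (≈ 2% low at the
toy's 46 Cα); the tests budget for this.

## Domain-orientation angle

The C_H2–C_H3 angle of one chain is the planar angle at a vertex atom
between two arm atoms, all three given as (residue, atom-name) keys —
default Tyr300 Cα / Met428 Cα (vertex) / Gln362 Cα.  The vertex is taken
as the middle-listed atom; no formula fixes this choice, so the triple
and vertex are plain arguments, making any alternative auditable.  The
angle is rigid-motion invariant and lives in [0, 180].

## Dihedrals and rotamers

Torsions follow the IUPAC convention: cis = 0, sign by the right-hand
rule about the central bond, range (−180, 180].  χ1 is N–CA–CB–γ with the
γ atom found per residue type (OG for Ser, SG for Cys, CG1 for Ile/Val,
CG otherwise).  Values printed on a [0, 360) axis (e.g. a flipped-out
tyrosine at 189°) correspond to the internal value minus 360; the
conversion is exposed and the CLI offers the unsigned display mode.
Circular histograms bin lower-inclusively on either axis convention with
a bin width that must divide 360, so re-mapping bin centers mod 360
converts one convention's counts into the other's exactly.

## SAXS

The theoretical profile is the orientationally averaged Debye double sum
with vacuum atomic form factors in the four-Gaussian Cromer–Mann
parameterization (H, C, N, O, P, S; f(0) matches the element's electron
count to ~0.01 e).  No excluded-volume or hydration-layer term is
applied: those corrections depend on fitted parameters that vary between
programs, while the vacuum Debye sum is a fixed, reproducible core.  A
consequence worth stating: absolute χ² values against real, buffer-
subtracted data will differ from hydration-aware programs, and profiles
here are meaningful mainly through the fitted scale c.  Hydrogens are
excluded from the sum and their electrons are not folded into the heavy
atoms in this version.  Two granularities exist: per heavy atom, and one
bead per residue at the heavy-atom centroid carrying the residue's
electron count — the bead mode agrees with the atomic mode at low q
(within 5% for q·R_g ≲ 1 on the toy template) and is intended for
ensemble-scale runs where the O(n²) atomic sum is too slow.  The default
grid is 200 log-spaced points on 0.015–0.5 Å⁻¹, the wide measured range
of a two-detector-distance experiment.  Experimental profiles are
three-column text (q, I, σ; '#' comments; whitespace or commas); the
experimental grid is authoritative and calculated profiles are linearly
regridded onto it (no extrapolation).  The scale c minimizing χ² has the
closed form [Σ I_exp I_calc/σ²]/[Σ I_calc²/σ²]; χ² uses the 1/(N−1)
prefactor.

## Contact networks

A residue pair is in contact when any heavy-atom pair across the two
groups is strictly within the cutoff (default 4.0 Å).  Heavy atoms only:
crystal structures mostly lack hydrogens, and a single rule must serve
crystal structures and ensembles alike.  "Within" is read as strict <;
incidence bands are upper-inclusive/lower-exclusive, so "24,000 to
16,000" means (16,000, 24,000].  The bands are stored as fractions of the
ensemble size (> 0.9375 thick; (0.625, 0.9375] thin; (0.3125, 0.625]
dashed; the absolute 24,000/16,000/8,000 thresholds are the
25,600-conformer special case).  Protein–protein pairs are out of scope
and raise.  The exported edge list is sorted by class then pair keys, so
repeated runs are byte-identical.

## Synthetic ensembles

The generator emulates the *statistical* structure of an Fc MD ensemble,
not its physics: there are no sterics, no force field, and no glycan
torsion sampling.  The template is a miniature two-chain system (68
atoms): per chain a 3-residue hinge, a rigid C_H2 cluster holding the
marker residue (Tyr-like N/CA/CB/CG at a settable χ1) and the moving
angle-triple atom, a rigid C_H3 cluster holding the vertex and second arm
atoms, and a NAG-NAG-BMA-MAN branch whose innermost atom sits at an exact
requested distance from the protein.  Chain B is chain A rotated 180°
about z — a proper rotation, so chirality and χ1 are preserved — and the
angle-triple plane of both chains is z = 0.

Per conformer the generator: (1) draws per-chain domain angles from a
Normal truncated to (0, 180) — independent by default, with optional
correlation ρ, since two-dimensional angle distributions of the two
chains look roughly isotropic and correlation should be an explicit
assumption; (2) realizes each drawn angle *exactly* by rotating the C_H2
cluster about an axis through the hinge pivot (the C_H2-proximal hinge
residue's Cα) perpendicular to the triple plane — the rotation magnitude
is solved by bracketing plus Brent's method (xtol 1e-14), and the layout
places the vertex inside the circle swept by the moving atom so every
angle in (0, 180) is reachable; (3) draws a χ1 rotamer state per chain
from the categorical distribution, adds von Mises noise (concentration
κ), and sets the marker χ1 exactly by rotating Cγ about the CA→CB axis;
(4) adds i.i.d. Gaussian jitter (sd `jitter_sd_A`) to every coordinate.
A fixed seed gives bit-identical ensembles.

Defaults are the study conditions the analyses target: angle mean 90°
and sd 10° per chain (the solution-state cluster), rotamer states
{80°: 0.7, 180°: 0.3} (a flipped-in-dominant fucosylated form), κ = 50
(≈ 8° angular noise), jitter 0.25 Å.  Note that coordinate jitter feeds
through the finite lever arms into the measured angles and torsions, so
measured spreads sit slightly above the drawn ones (≈ 0.5–0.7° on the
angle sd at defaults); recovery tests that target a specific noise
channel switch the others off.

The mock experiment is the ensemble profile with multiplicative Gaussian
noise of relative sd `noise_frac` and σ set to `noise_frac`·I of the
noiseless curve, so the generating ensemble's self-fit χ² follows
χ²(N−1)/(N−1).

What passing tests show: the estimators (angles, χ1 fractions, RMSF, χ²)
are unbiased and correctly calibrated on data whose generating process is
known.  What they do not show: behavior on real MD output with
anisotropic, correlated fluctuations, real glycan flexibility, or real
scattering contrast — the generator has none of these.

## Problem sizes and tolerances

Validation studies run at sizes where their statistical bounds are sharp
on one CPU: n = 1000 for angle-distribution recovery (mean within 1°, sd
within the χ² band [8.5, 11.5]), n = 2000 for rotamer fractions (3σ
binomial bound) and for RMSF (σ√3 within 5%), ~4000 beads for the sphere
oracle (2% for qR ≤ 4), 5 seeds for the χ² self-fit band [0.7, 1.4] at
N = 200 grid points, and a 6° Euler grid for the superposition oracle.

## Known limitations

No mmCIF input; no mass-weighted fitting or PCA of fluctuations; vacuum
scattering only (no hydration shell, no Guinier/P(r) tooling); contact
analysis is residue-level, not atom-level; χ2/χ3 rotamers and full
rotamer-library classification are out of scope.  The toy template's
geometry is schematic — distances and cluster shapes are chosen for
testability, not to mimic immunoglobulin-fold dimensions.
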