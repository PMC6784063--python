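# fcensemble

Conformer-ensemble analyses for the Fc region of IgG1-like glycoproteins.

The Fc stem of immunoglobulin G is a horseshoe-shaped homodimer whose two
C_H2 domains do not touch each other but bracket a pair of N-glycans
attached at Asn297.  Solution ensembles of Fc (typically sampled by
molecular dynamics) are characterized by a handful of scalar observables,
and this package implements that analysis stack for anyone working with
multi-model coordinate ensembles of such systems:

- **Domain orientation** — the intra-chain C_H2–C_H3 angle defined by the
  Cα atoms of Tyr300, Met428 and Gln362 (vertex at Met428), measured per
  chain and per conformer.
- **Flexibility** — root mean square fluctuation (RMSF) per Cα about an
  ensemble-average structure obtained by iterated least-squares (Kabsch)
  superposition, plus minimum-RMSD search of an ensemble against a
  reference structure.
- **Scattering** — theoretical small-angle X-ray scattering by the Debye
  equation, I(q) = Σᵢⱼ fᵢ(q) fⱼ(q) sin(q rᵢⱼ)/(q rᵢⱼ), with vacuum atomic
  form factors; ensemble averaging; and the reduced goodness-of-fit
  χ² = 1/(N−1) Σⱼ [(I_exp(qⱼ) − c·I_calc(qⱼ))/σ(qⱼ)]² with the scale c
  minimized analytically.
- **Glycan contacts** — residue pairs within 4 Å (heavy atoms), their
  incidence across the ensemble, and the thick/thin/dashed classification
  of interaction-network figures (bands at 24,000/16,000/8,000 of 25,600
  conformers, stored as fractions so any ensemble size works).
- **Side-chain rotamers** — χ1 (N–CA–CB–Cγ) series and circular
  histograms, e.g. the flipped-in (≈ 80°) vs flipped-out (≈ 180°) states
  of Tyr296 that track core fucosylation.

Because MD trajectories are rarely redistributable, the package ships a
**synthetic-ensemble generator**: a miniature two-chain Fc template with
known domain angles, a marker residue with settable χ1, and a glycan-like
branch, sampled with truncated-Normal angles, categorical rotamer states
with von Mises noise, and Gaussian jitter.  Every analysis is validated
closed-loop against the generator's known parameters and against analytic
oracles.

## Worked example

```python
import numpy as np
from fcensemble import (SyntheticEnsembleConfig, build_template, chi_square,
                        default_q_grid, domain_angle_pairs, ensemble_profile,
                        generate_ensemble)
from fcensemble.synthetic import make_mock_experiment

template = build_template()                       # toy Fc at 90°/90°, chi1 80°
ensemble = generate_ensemble(template, SyntheticEnsembleConfig(
    n_conformers=500, seed=1))                    # mean 90°, sd 10° per chain

pairs = domain_angle_pairs(ensemble, "A", "B")
a = np.array([p.chain_a_deg for p in pairs])
print(f"chain A angle: mean {a.mean():.1f}, sd {a.std(ddof=1):.1f} deg")

q = default_q_grid(0.015, 0.5, 200)
experiment = make_mock_experiment(ensemble, q, noise_frac=0.02, seed=99)
fit = chi_square(experiment, ensemble_profile(ensemble, q))
print(f"chi2 = {fit.chi2:.2f}, c = {fit.c:.3f}, N = {fit.n_points}")
```

prints

```
chain A angle: mean 89.2, sd 10.0 deg
chi2 = 0.95, c = 1.000, N = 200
```

The measured angle statistics recover the generating distribution, and
refitting the generating ensemble to its own 2%-noise mock data gives a
reduced χ² near 1, i.e. the model explains the data to within its errors.
The scripts in `examples/` walk through each capability the same way
(simulation, angles, RMSF, SAXS fitting, contact networks, rotamers), and
`fcensemble` is also available as a command-line tool with subcommands
`simulate`, `angles`, `rmsf`, `saxs-fit`, `contacts` and `dihedrals`.

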