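"""Measure the C_H2–C_H3 domain-orientation angle distribution.

The angle is defined per chain by three Cα atoms (Tyr300, Met428,
Gln362; vertex at Met428) and summarizes how the mobile C_H2 domain sits
relative to C_H3.  Solution ensembles cluster near 90°; crystal
structures tend to be more open.
"""

import numpy as np

from fcensemble import (SyntheticEnsembleConfig, angle_histogram, build_template,
                        domain_angle_pairs, generate_ensemble)

ensemble = generate_ensemble(build_template(),
                             SyntheticEnsembleConfig(n_conformers=500, seed=1))
pairs = domain_angle_pairs(ensemble, "A", "B")
a = np.array([p.chain_a_deg for p in pairs])
b = np.array([p.chain_b_deg for p in pairs])
print(f"chain A: mean {a.mean():.1f} deg, sd {a.std(ddof=1):.1f} deg")
print(f"chain B: mean {b.mean():.1f} deg, sd {b.std(ddof=1):.1f} deg")
print("(generated at mean 90, sd 10: the analysis recovers the inputs)")

centers, counts = angle_histogram(a, bin_width=5.0, range_convention="unsigned")
top = np.argsort(counts)[-3:][::-1]
print("most populated 5-degree bins (chain A):",
      ", ".join(f"{centers[i]:.0f} deg x{counts[i]}" for i in top))
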