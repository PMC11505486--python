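"""Amino-acid occurrence vs lifespan: planted preference and avoidance.

Occurrence profiles for 49 species are generated with leucine planted at a
population correlation of +0.62 with lifespan (preference) and proline at
-0.7 (avoidance); the per-amino-acid Pearson correlations recover the plant
while unplanted amino acids stay near zero.
"""

import numpy as np

from evorate import SpeciesTraits, TraitTable, correlate_composition
from evorate.synth import generate_composition_profiles

rng = np.random.default_rng(7)
mrls = {f"sp{i:02d}": float(v) for i, v in enumerate(rng.uniform(3, 60, 49))}
profiles = generate_composition_profiles(mrls, {"L": 0.62, "P": -0.7}, seed=8)
traits = TraitTable([SpeciesTraits(sp, mrls=v) for sp, v in mrls.items()])

corr = correlate_composition(profiles, traits, "mrls")
print("aa  mean%   r       p")
for aa in ("L", "P", "A", "E", "V"):
    c = corr[aa]
    r = "  const" if c.r is None else f"{c.r:+.2f}"
    p = "" if c.p is None else f"  {c.p:.2g}"
    print(f"{aa}   {c.mean_occurrence:5.2f}  {r}{p}")
print("\nPositive r = preference (occurrence rises with lifespan), "
      "negative = avoidance; A/E/V were not planted.")
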