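"""Simulate a twin cohort and describe it.

Generates a cohort with the walkability variance split A/C/E = 22/22/56
at the study scale (477 MZ + 734 DZ complete pairs, index mean 43.4,
SD 12.0) and prints the structural counts and twin correlations by
zygosity.  ``cohort.write_csv(path)`` would persist it.
"""

import numpy as np

from twingem import UnivariateSimSpec, simulate_univariate

cohort = simulate_univariate(UnivariateSimSpec(seed=1))

print("cohort counts:", cohort.meta)
walk = cohort.df["walkability"]
print(f"walkability mean {walk.mean():.1f}, SD {walk.std():.1f}")
for z in ("MZ", "DZ"):
    pairs = cohort.paired_values("walkability", z)
    r = np.corrcoef(pairs.T)[0, 1]
    print(f"sample twin correlation {z}: {r:.3f}")
print(
    "The MZ correlation exceeding the DZ correlation signals genetic"
    " influence on the phenotype; under the generative truth they are"
    " 0.44 and 0.33."
)
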