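"""Score a simulated GFP-RBP binding assay.

Simulates a plate for two RBPs against three strains with known affinities,
normalises fluorescence to FU ((raw - control)/OD600, clamped at 0),
computes relative binding-affinity scores, and compares strains with
Welch's t-test.
"""

import pandas as pd

import rbprofiler as rp

affinity = pd.DataFrame(
    {"3107": [1.0, 0.0], "MG1363": [0.37, 0.2], "IL1403": [0.0, 1.0]},
    index=["rbp_groupI", "rbp_groupII"],
)
wells, truth = rp.simulate_plate(rp.PlateSpec(true_affinity=affinity, seed=3))
fus = rp.normalize_plate(wells)
result = rp.binding_matrix(fus, alpha=0.01)

print("relative binding scores (%):")
print(result.score_matrix().round(1).to_string())
print()
print("truth:")
print(truth.round(1).to_string())
print()
print(result.p_values.round(6).to_string(index=False))
print()
print(
    "The optimal host of each RBP scores 100; other strains score their"
    " mean FU as a percentage of the optimal host's. Estimated scores land"
    " within a few points of the generating affinities; p-values below 0.01"
    " mark strain pairs with significantly different binding."
)
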