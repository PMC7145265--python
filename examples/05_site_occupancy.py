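"""Ion binding-site occupancy frequencies per conformational state.

Samples per-state conformation ensembles in which each chloride site
(S_ext, S_cen, S_int) is occupied with a prescribed probability, then
recomputes the empirical occupancy table: fraction of conformations
with at least one ion inside each 2.5 A site sphere.
"""

import numpy as np

import clcgating as cg

sites = {"S_ext": np.array([0.0, 0.0, 10.0]),
         "S_cen": np.array([0.0, 0.0, 0.0]),
         "S_int": np.array([0.0, 0.0, -10.0])}
# site-occupancy probabilities per macrostate: the open-like state binds
# chloride at the extracellular site almost always, the closed states
# almost never
probs = {"C_oi": {"S_ext": 0.01, "S_cen": 0.00, "S_int": 0.02},
         "C_o": {"S_ext": 0.07, "S_cen": 0.01, "S_int": 0.02},
         "O": {"S_ext": 0.93, "S_cen": 0.04, "S_int": 0.04},
         "U": {"S_ext": 0.11, "S_cen": 0.04, "S_int": 0.04}}

ensembles = cg.make_ion_fixture(sites, probs, n_samples=1000, seed=0)
table = cg.occupancy_table(
    ensembles, [cg.SiteDefinition(n, tuple(c)) for n, c in sites.items()])
print(table.round(2))
# Rows are macrostates, columns binding sites; entries are empirical
# frequencies over 1000 conformations, matching the generating
# probabilities to binomial accuracy (~+-0.03 at n=1000).
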