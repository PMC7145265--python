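"""Build the calibrated gating kinetics and inspect its equilibrium.

The reference model encodes the four selectivity-filter macrostates of
CLC-2 (C_oi, C_o, O, U) as a continuous-time jump process: Boltzmann
basin free energies plus Arrhenius barrier rates, with the occluded U
state present only when the external-gate glutamate is protonated.
"""

import numpy as np

import clcgating as cg

for protonated in (True, False):
    model = cg.build_reference_model(protonated=protonated)
    pi = model.stationary_distribution()
    print(f"\nprotonated={protonated}: states {model.state_labels}")
    print("  free energies (kcal/mol):", model.free_energies)
    print("  stationary populations:  ", np.round(pi, 4))
    print("  exit rates (1/frame):    ", np.round(-np.diag(model.rate_matrix), 5))

# The populations are Boltzmann weights of the basin free energies at
# 300 K: the two closed states hold ~98% of the equilibrium, while the
# open-like O state (and U, when protonated) sits near 1% -- the low
# open probability of the channel at 0 mV.
paths = cg.sample_ctmc(cg.build_reference_model(True), n_traj=3,
                       n_steps=2000, seed=0)
occ = np.bincount(np.concatenate(paths), minlength=4) / (3 * 2000)
print("\nempirical state frequencies of 3 sampled trajectories:",
      np.round(occ, 4))
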