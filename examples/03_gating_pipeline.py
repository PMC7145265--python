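"""Run the full gating analysis on a scaled-down synthetic dataset.

Generates jump-process trajectories under both protonation conditions,
emits von Mises dihedral features for the 17 selectivity-filter
residues, fits one shared tICA model and microstate decomposition, then
estimates per-condition MSMs, PCCA+ macrostates and rate matrices.
(The study-scale run uses 200 trajectories x 2e4 frames and 324
microstates; this example is ~30x smaller and runs in ~15 s.)
"""

import numpy as np

import clcgating as cg

cfg = cg.PipelineConfig(n_traj=30, n_steps=4000, k=80, n_boot=20,
                        kmeans_iter=150, seed=3)
study = cg.run_pipeline(cfg)

for cond, r in study.conditions.items():
    print(f"\n{cond}: {r.macromodel.n_macrostates} macrostates")
    for label in r.populations:
        print(f"  {label:5s} population {r.populations[label]:.4f}"
              f" +- {r.population_sd.get(label, float('nan')):.4f}"
              f"   dG {r.delta_g[label]:+.2f} kcal/mol")
    print("  rate matrix (1/ns):")
    print(np.array2string(r.rate_matrix_per_ns, precision=5,
                          suppress_small=True))

# Under protonation four macrostates appear (the occluded U state joins
# C_oi, C_o, O); without it only three.  Populations recover the
# generator's Boltzmann weights: ~71% / ~27% closed states and ~1% for
# each rare state, i.e. dG(C_o) < 1 kcal/mol and dG(O), dG(U) in the
# 2-3 kcal/mol band.
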