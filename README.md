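# clcgating

Markov state model analysis of CLC-2 selectivity-filter ("fast") gating,
built as a reusable Python library: from signed-dihedral feature time
series to slow reaction coordinates (tICA with kinetic mapping),
microstate Markov state models, metastable macrostates (PCCA+),
free-energy landscapes, continuous-time macrostate rate matrices,
pore-radius profiles and chloride binding-site occupancies.

The CLC-2 chloride channel opens through two gates inside its
selectivity filter: rotation of the S168–G169–I170 backbone opens the
inner gate, and a rotameric flip of the external-gate glutamate (E211,
"GLU_ex") clears the extracellular site. The library models this cycle
with four macrostates — **C_oi** (both gates closed), **C_o** (inner
gate open), **O** (putative open, ~1% equilibrium population at 0 mV)
and **U** (a pore-occluding rotamer accessible only when GLU_ex is
protonated) — and recovers their thermodynamics and kinetics from
trajectory data.

Because no public trajectory archive accompanies this system, the
package ships first-class synthetic generators with known ground truth,
calibrated to the published landscape:

* a continuous-time jump process over the macrostates with Boltzmann
  populations `π_i ∝ exp(−G_i/kT)` (G = 0, 0.59, 2.55, 2.55 kcal/mol at
  300 K) and Arrhenius rates `k = ν·exp(−ΔG‡/kT)` obeying detailed
  balance, sampled exactly by the Gillespie algorithm;
* von Mises dihedral emissions over the 17-residue selectivity-filter
  feature set (φ, ψ, χ1, χ2), in which ψ(I170,G169)/ψ(G169,S168)
  separate C_oi from the rest and χ1(E211) takes three rotameric modes;
* overdamped Langevin dynamics on piecewise-analytic double wells with
  closed-form barriers;
* analytic pore geometries (cylinder/hourglass/blocked) and Bernoulli
  ion-site ensembles.

## The core estimators

* **tICA** — solves `C_τ v = λ (C_0 + εI) v` with the symmetrized
  lagged covariance; projections optionally scaled by λ (kinetic map).
* **Mini-batch k-means** — greedy k-means++ seeding, per-center 1/count
  learning rates, full-pass final assignment (default k = 324).
* **Reversible MSM** — sliding-window counts at a 28.8 ns lag
  (9.6 ns/frame), ergodic trimming, and the detailed-balance
  maximum-likelihood fixed point
  `x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j)`; stationary populations
  from the converged edge weights; uncertainties from 100
  trajectory-level bootstrap MSMs.
* **PCCA+** — inner-simplex vertex search plus constrained crispness
  optimization on the dominant eigenvectors; macrostate count chosen at
  the largest implied-timescale gap.
* **Rate-matrix MSM** — maximum-likelihood generator `K` (off-diagonals
  ≥ 0, zero row sums, detailed balance) fit through `expm(Kτ)`,
  initialized from the projected matrix logarithm.
* **Pore profiler** — maximal-inscribed-sphere radius
  `r(s) = max_p min_i (‖p − x_i‖ − R_i)` along a conduction pathway,
  with sub-threshold (1.8 Å chloride radius) extent measurement.

## Worked example

`examples/03_gating_pipeline.py` runs the full chain on a scaled-down
synthetic dataset (30 trajectories × 4000 frames per condition):

```
protonated: 4 macrostates
  C_oi  population 0.7208 +- 0.0040   dG -0.00 kcal/mol
  C_o   population 0.2627 +- 0.0041   dG +0.60 kcal/mol
  O     population 0.0084 +- 0.0027   dG +2.65 kcal/mol
  U     population 0.0081 +- 0.0023   dG +2.68 kcal/mol

deprotonated: 3 macrostates
  C_oi  population 0.7249 +- 0.0035   dG -0.00 kcal/mol
  C_o   population 0.2662 +- 0.0035   dG +0.60 kcal/mol
  O     population 0.0089 +- 0.0026   dG +2.62 kcal/mol
```

Four macrostates appear only under protonation; the recovered
populations track the generator's Boltzmann weights (the rare-state
estimates tighten to ~1% at the full study scale of 200 × 2·10⁴
frames). Other examples cover the reference kinetics, Langevin barrier
recovery, PDB featurization, pore profiling and site occupancy; each
prints the numbers it computes and what they mean.

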