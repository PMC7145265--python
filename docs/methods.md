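# Methods

This note documents the models implemented in `clcgating`, the
parameters that matter, the synthetic-data generators used as ground
truth, and the numerical choices made where the design was open.

## The gating model

The CLC-2 selectivity filter is described by four metastable
conformations: `C_oi` (inner and outer gates closed), `C_o` (inner-gate
backbone S168–G169–I170 rotated open), `O` (external-gate glutamate
E211 flipped clear of the pathway; putative open state) and `U` (a
second, pore-occluding E211 rotamer that exists only when the glutamate
is protonated). The reference kinetic model
(`kinetics.build_reference_model`) encodes this cycle as a
continuous-time Markov jump process.

**Free energies.** Basin free energies are fixed at
G = {C_oi: 0, C_o: 0.59, O: 2.55, U: 2.55} kcal/mol. The values sit
inside the published qualitative bounds (C_o less than 1 kcal/mol above
C_oi; O and U between 2 and 3 kcal/mol) and were chosen so the
Boltzmann populations at 300 K are (0.715, 0.266, 0.0099, 0.0099) —
i.e. ~1% for each rare state, matching the reported low open
probability at 0 mV. kT uses k_B = 1.9872×10⁻³ kcal/mol/K, so
kT(300 K) = 0.59616 kcal/mol (printed as 0.5962).

**Rates.** Forward rates are Arrhenius, k = ν·exp(−ΔG‡/kT) with unit
prefactor (ν = 1 per frame); barriers are measured from the minimum of
the edge's origin basin: C_oi→C_o: 2.0, C_o→O: 4.5, C_o→U: 5.0
kcal/mol. Every reverse rate follows from detailed balance
π_i k_ij = π_j k_ji, so the generator's stationary law equals the
Boltzmann weights by construction (verified to 10⁻¹² in tests). Under
protonation two small direct escape channels from U are added, with
barriers 4.0 (U→O) and 5.0 (U→C_oi) kcal/mol from the U basin; their
detailed-balance reverses are small enough that the C_oi→U edge falls
below the network-summary resolution at the study's sampling depth —
the network table reports such edges as "not observed at this sampling
depth", never as rate 0.

A consequence of the unit prefactor worth stating: with these barriers
the C_oi↔C_o exchange (~8 frames) is *faster* than the O and U flips
(~65–135 frames), so the ordering of tICA components by eigenvalue is
not fixed a priori. In practice the backbone process still dominates
tIC 0 because its between-state feature variance is ~20× larger than
that of the ~1%-populated rotamer processes; the ψ(I170,G169) /
ψ(G169,S168) pair tops the tIC 0 loadings and χ1(E211) dominates the
next components, reproducing the published loading pattern. Tests
assert the feature↔process association, which is the substantive claim.

**Sampling.** `sample_ctmc` uses exact Gillespie simulation with
discretization onto the frame grid (frames strictly before a jump keep
the pre-jump state). Because jump times are exact, there is no
time-step bias in rare-transition statistics; the grid bound
max|K_ii|·dt ≤ 0.1 is enforced only so that the discrete chain resolves
individual jumps. Paths start from the stationary law.

## Dihedral emissions

`emissions.default_emission_model` emits, independently per frame, one
von Mises angle per feature over the 17 selectivity-filter residues
(φ, ψ for all; χ1/χ2 where the residue type has them; 57 features
total). Concentration κ = 14.6 gives a circular SD of ~15°, small
enough for separable macrostates with realistic overlap. The
discriminative structure is:

| feature | C_oi | C_o | O | U |
|---|---|---|---|---|
| ψ(I170,G169) | −45° | 140° | 140° | 140° |
| ψ(G169,S168) | −30° | 120° | 120° | 120° |
| χ1(E211) | −65° | −65° | 65° | −160° |
| φ(S168,G167) | −60° | −60° | −60° | −150° |
| φ(G169,S168) | 70° | 70° | 150° | 70° |

All other features share one mean across states (drawn once from
typical backbone/rotamer regions). The U rotamer of χ1(E211) is placed
at −160° rather than 180°: a mode exactly on the ±180° wrap boundary
splits into two antipodal clumps that no linear signed-angle coordinate
can represent, an artifact of the signed-scalar convention rather than
of the science; at −160° only ~9% of the mass wraps. Angles are wrapped
to [−180°, 180°).

What the generator deliberately does not emulate: intra-basin
autocorrelation (emissions are i.i.d. given the state, so within-state
mixing is instantaneous), anharmonic basin shapes, correlated
side-chain/backbone motion, and solvent/ion coupling. Passing tests
therefore demonstrate correct recovery of the *kinetic model
underneath the emissions*, not robustness to every feature of real MD
data.

## Featurization

Dihedrals are signed, in degrees, in the half-open interval
[−180°, 180°), right-hand rule about the central bond; φ(i) =
C(i−1)–N(i)–CA(i)–C(i), ψ(i) = N(i)–CA(i)–C(i)–N(i+1), χ per the
standard side-chain quadruples. Backbone feature names span the two
residues involved ("psi:I170-G169" is ψ of G169). Angles are kept as
signed scalars to mirror the published featurization; near-boundary
features are the known cost of that convention. Multi-model PDB I/O
goes through biotite. Residues lacking a requested side-chain angle are
dropped from that angle kind with a logged notice; missing backbone
atoms are an error naming residue, atom and frame.

## tICA

Means and covariances are estimated over all lagged pairs; C_τ is
symmetrized as (C+Cᵀ)/2, which guarantees a real spectrum at the cost
of a small bias for finite samples. The generalized problem is solved
against C₀ + εI with ridge ε = 10⁻⁶·tr(C₀)/F by default (collinear
dihedral columns otherwise make C₀ singular). Kinetic mapping scales
component i by λ_i (the alternative λ/√(1−λ²) commute scaling is not
used). All components are retained for clustering. Signs are fixed by
making each eigenvector's largest-magnitude coefficient positive;
near-degenerate slow eigenvalues trigger a warning since only their
span is well defined. "Top loadings" of a component are coefficients
exceeding mean(|v|) + 2·SD(|v|).

## Microstates

Mini-batch k-means with greedy k-means++ seeding (2 + ln k candidates
per step, best-potential choice — the standard quality refinement),
batch size 1000, 300 batch updates, per-center learning rate 1/count,
and a final full-pass assignment. Ties break to the lowest center
index; empty clusters are reseeded to the farthest point. Seeding uses
a bounded 10⁵-point subsample at large n. Default k = 324. Everything
is driven by one explicit seed and reproduces bit-for-bit.

## Markov state models

Sliding-window counts at the lag; ergodic trimming to the strongly
connected component carrying the most counts; reversible MLE via the
edge-weight fixed point iterated until the relative log-likelihood
change falls below 10⁻¹⁰ (the stationary vector is cross-checked
against the leading left eigenvector). The physical frame time is a
declared constant, 9.6 ns/frame by default, so the production lag of
28.8 ns is exactly 3 frames. Implied timescales use the π-symmetrized
spectrum; non-positive eigenvalues are reported as gaps (NaN), not
dropped. Bootstrap uncertainty resamples whole trajectories (the unit
that preserves autocorrelation), 100 replicas by default, all sharing
the full-data active set; replicas that lose connectivity are dropped
and counted.

Free energies are ΔG_i = −kT·ln(π_i/max π), minimum exactly 0, with
zero-population states flagged +∞. 1-D landscapes are stationary-
weighted histograms (per-frame weight π(state)/count(state)) over 72
bins by default; barriers are read from bin maxima between basin
minima, a deliberately simple rule whose bias is of order the bin
width; bins under a count floor are flagged unsampled, never
interpolated. Barrier values are always quoted from the origin basin's
minimum.

## Macrostates and rates

PCCA+ maps the top-n right eigenvectors to the membership simplex:
deterministic greedy vertex search, then Nelder-Mead refinement of the
crispness objective trace(diag(1/A[0,:]) AᵀA) under the feasibility
projection (positivity + partition of unity). The macrostate count
defaults to the largest ratio of successive implied timescales below
`max_n` = 6, with the full gap table logged and a user override
honored. Macrostates are named by matching circular-mean
discriminative-feature signatures to the emission archetypes via
optimal one-to-one assignment (cost 1 − cos Δ); in a real-data setting
the same hook labels by tIC-basin position.

The continuous-time generator is the maximum-likelihood K under
off-diagonal ≥ 0, zero row sums and detailed balance with respect to
the coarse MLE's stationary law, parameterized by log symmetric fluxes
and fit by L-BFGS-B through expm(Kτ); the initializer is the matrix
logarithm of the macrostate transition matrix projected onto the
feasible cone (projection is flagged when logm is not a generator).
Rates are reported per nanosecond via the declared frame time.

## Pore profiles and occupancies

The pore radius at arc position s is the maximal probe clearance
max_p min_i (‖p − x_i‖ − R_i) over the slice plane, searched inside an
explicit disk (default 8 Å; a fixture-appropriate radius must be chosen
narrower than the surrounding wall): coarse 1 Å grid, fine 0.25 Å grid
around the coarse optimum, then a disk-constrained simplex refinement
to 0.01 Å. Slices whose optimum reaches the disk boundary are flagged
"open funnel"; r ≤ 0 is flagged impassable. Sub-threshold extents
(default threshold 1.8 Å, the chloride radius) interpolate crossings
linearly on the s-grid. Van der Waals radii come from the bundled
Bondi table. Curved pathways are supported as polylines; the
two-half-profile convention (extracellular and intracellular from the
gate glutamate) is realized as two polylines sharing the origin.

For the hourglass fixture the analytic ground truth accounts for wall
tangency: the inscribed sphere at height z may touch the sloping wall
above or below the slice, so the exact radius is
min_z' √(r(z')² + (z'−z)²) − R_atom over the generating curve r(z');
at the waist this reduces exactly to the waist radius.

Binding-site occupancy is the fraction of conformations with ≥ 1 ion
center inside a site sphere (default radius 2.5 Å — the occupancy
geometry is a documented choice, since no exact definition is
published). Macrostate ensembles draw microstates ∝ π within the
macrostate and frames uniformly within microstates (default 1000
conformations per state). Ramachandran densities are wrap-aware 2-D
histograms normalized to unit mass with superlevel contour thresholds
at stated mass fractions.

## Langevin surrogates

The double-well potential is piecewise C¹: cubic smoothsteps between
the minima at x = ±1 and the barrier top at x = 0, harmonic walls
outside. Barrier heights are exact by construction: H from the left
basin, H − ΔG from the right. Overdamped Euler-Maruyama integration
x' = x + (D/kT)F(x)dt + √(2Ddt)ξ is refused when
D·U''_max/kT·dt > 0.2 (the deterministic relaxation per step must stay
well below the well width). The long-time law is Boltzmann, so
−kT·ln(histogram) recovers the potential; with dt = 10⁻³, D = 1 and
kT = 0.59616, a 10⁶-step run crosses a 2 kcal/mol barrier ~100 times
and a 10⁷-step run crosses a 5 kcal/mol barrier ~20 times, which sets
the quoted recovery tolerances (±0.3 and ±0.5 kcal/mol). The tight
integration loop uses numba.

## Study-scale choices

The packaged study conditions are 200 trajectories × 2·10⁴ frames per
protonation condition (4·10⁶ frames each, ~one tenth of the published
600 µs at 9.6 ns/frame), k = 324 microstates, tICA and MSM lag
28.8 ns, 100 bootstrap MSMs. At this depth the rare-state populations
carry bootstrap SDs of ~0.07 percentage points and every pairwise rate
among {C_o, O, U} is observed hundreds of times; the C_oi→U edge is
deliberately below resolution, mirroring the published network. The
full pipeline runs in ~4 minutes within ~4.5 GB on one CPU (covariance
and distance computations stream over trajectories/chunks so the peak
footprint stays near two float32 copies of the dataset); example
scripts use a ~30× smaller configuration.

## Known limitations

* Emissions are conditionally i.i.d.; within-macrostate implied
  timescales are sub-frame, which makes state decomposition easier than
  in real MD data.
* The reversible MLE's bootstrap bands capture sampling noise, not
  discretization bias; on this generator the bias is within the bands.
* Barrier read-off from histogram bin maxima carries O(bin width) bias
  and no spline smoothing by design.
* The pore search disk must be chosen inside the channel wall;
  geometries whose exterior is closer than the wall to the pathway
  will report the exterior (flagged "open funnel" when the boundary is
  hit).
* PCCA+ crispness optimization uses a local simplex method from a
  deterministic vertex start; for strongly non-metastable spectra only
  the vertex-search solution is meaningful.
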