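# Methods

`gelscape` models the gelation of short-range-attractive colloids at
intermediate volume fraction as a nonequilibrium percolation
transition.  It has three computational layers: a Brownian-dynamics
simulator that produces gelation trajectories, an analysis layer that
reduces trajectories (or experimental point clouds) to cluster-level
order parameters and kinetic rate constants, and an analytically
solvable coagulation–fragmentation model whose predictions the
measurements are compared against.  A synthetic-data layer generates
configurations and trajectories with known ground truth so that every
analysis stage is testable without running the simulator.

## Pair potentials and the sticky-sphere mapping

The working potential is a Mie (generalized Lennard-Jones) form
U(r) = C ε [(σ/r)^n − (σ/r)^m] with C = n/(n−m)·(n/m)^(m/(n−m)), so the
well depth is exactly −ε at r_min = (n/m)^(1/(n−m)) σ.  The exponents
default to (n, m) = (30, 20).  This pair is a reconstruction, not an
a-priori constant: the bond criterion used throughout is the inflection
point of the well, r_infl = (n(n+1)/(m(m+1)))^(1/(n−m)) σ, and
(30, 20) is the pair for which this equals (31/14)^0.1 σ ≈ 1.0827 σ
while the well width comes out ≈ 0.08 σ, the short attractive range the
system is designed to have.  Both exponents are exposed in the
configuration.  The potential is truncated at r_c = 1.5 σ_aa and
energy-shifted to zero there (no force shift), which preserves the well
depth to within the ~0.002 ε shift.

The binary mixture uses σ_aa = 1, σ_bb = 1.1 (size ratio 1:1.1),
additive mixing σ_ab = (σ_aa+σ_bb)/2, one ε for all pairs, and
equal-material-density masses m_b = 1.1³ m_a.  These mixing choices are
the simplest consistent with an equal binary mixture; none of them is
constrained further by the problem.

A "continuous square well" (CSW) is provided as the generality check:
U(r) = (ε/2)[(1/r)^n + tanh(m(r−1)(r−r_sw)/2) − 1] with steepnesses
m = 7000, n = 700.  The tanh form is the overflow-safe rewriting of the
sigmoid; the steep core power is evaluated in log space and saturated
at e^700.  `calibrate_csw` root-finds the CSW depth so its second
virial coefficient matches the Mie one at ε/k_BT = 3 (the width r_sw
defaults to the Mie bond distance and scales with the pair contact
distance).  Because Eq.-form couples the core and well through the
single prefactor ε, a zero-attraction target does not calibrate to a
zero-depth CSW; the calibration is meaningful for targets with
ε/k_BT ≳ 1.

Second virial coefficients are computed by adaptive quadrature of
B2 = 2π ∫ (1 − e^{−U/kT}) r² dr, split at the potential's
characteristic radii, with the hard-core region (U > 50 kT) integrated
exactly as r².  An ideal square-well type with a closed-form B2 serves
as the quadrature's analytic validation.  The reduced virial
B2* = B2/(2π d³/3) uses a Barker–Henderson effective diameter
d = ∫ (1 − e^{−U/kT}) dr over the repulsive branch (a plain σ
reference is available as a config alternative; the two differ by < 1%
for these steep cores).  The Baxter adhesive-hard-sphere stickiness
with matched B2 is τ_B = 1/(4(1 − B2*)).  At the critical attraction
ε/k_BT = 2.5 this gives τ_B ≈ 0.08–0.10, the known adhesive-sphere
gelation onset region; τ_B decreases monotonically with attraction.

## Brownian dynamics

Particles follow the inertial Langevin equation m dv/dt = F_pair −
(m/ζ) v + f_B with ⟨f_B(t)f_B(t')⟩ = 2 m k_BT δ(t−t')/ζ, integrated
with the BAOAB splitting at dt = 0.0025 t_s and damping ζ = t_s, where
t_s = (m r_a²/ε)^{1/2}.  With noise and friction disabled BAOAB
reduces to velocity Verlet (energy-conserving); with them enabled the
O-step is the exact Ornstein–Uhlenbeck update, so free particles
reproduce equipartition ⟨v²⟩ = 3 k_BT/m and the Einstein diffusivity
D = k_BT ζ/m exactly up to sampling error.  The friction coefficient
is m/ζ (velocity decays as e^{−t/ζ}), matching the quoted noise
covariance.

Forces are evaluated per pair from a periodic k-d tree
(`scipy.spatial.cKDTree` with `boxsize`) at the largest pair cutoff;
this is exact (validated against an all-pairs double loop) and fast
enough for the desk-scale systems used here (N ≲ 2×10³).  Initial
states are jittered dilute-lattice placements (no core overlaps by
construction at φ < 0.64) with Maxwell–Boltzmann velocities, melted at
the equilibration attraction ε/k_BT = 1 for 100 t_s by default; the
quench switches ε/k_BT to its target and emits frames every 1 t_s
(0.05 t_s in the fine mode used for kinetics).  Equilibration length
and sampling cadence are package choices, exposed in the config.
Volume fraction accounting uses nominal radii r_i = σ_ii/2:
φ = (4π/3)(n_a r_a³ + n_b r_b³)/L³.

## Cluster analysis

Bonds are pairs within the inflection radius of their pair potential
(simulation criterion, minimum-image distances) or within d₀ = 2.6 r
(experiment criterion, open boundaries; cluster grouping may use the
looser d_c = 3.5 r, both thresholds configurable).  Clusters are
connected components (scipy sparse graph machinery), labelled
deterministically by smallest member index.  Per-cluster geometry is
computed after unwrapping member coordinates by walking the bond graph
with minimum-image displacements; a bond whose unwrapped endpoints
disagree closes a loop around the box and flags the cluster as
percolating (self-image connectivity).  R_g of a spanning cluster is
reported on the unwrapped tree but is not unique.

Frame-level observables: mean coordination z = 2·bonds/N; largest and
second-largest cluster fractions; correlation length
ξ² = 2 ∑ R_gi² N_i²/∑ N_i², with the spanning cluster included before
percolation and excluded after (both exposed as flags); linear or
log-binned cluster-mass histograms with an option to drop the largest
cluster (the post-gel convention).

The fractal dimension is estimated from the mass–size relation
N ∝ R_g^{d_f}.  The regression is log R_g on log N with d_f the
inverted slope: sizes are exact counts while R_g carries shape noise,
and regressing the noisy variable on the exact one avoids the ~5–10%
attenuation bias that the opposite orientation shows on synthetic
clusters at d_f = 3.  Window defaults to 3 ≤ N ≤ 0.1 N_total,
excluding the spanning cluster; errors are bootstrap over clusters.

## Kinetics: association and dissociation rates

Clusters are matched across consecutive finely-spaced frames by
particle identity.  A new cluster with two parents logs a merge
(i, j) → i+j; an old cluster with two children logs a split.
Compound transitions (≥ 3 parents or children) are decomposed greedily
by largest shared membership, counted once each, and the compound
fraction is reported (a warning fires above 1%).  An optional debounce
counts an event only if it persists into the following frame; without
it, pairs vibrating across the distance cutoff inside the attractive
well register a split+merge pair almost every frame and saturate the
apparent rates at the frame rate.  Rate constants
follow the master-equation definitions: K⁻_ij = splits/(∫ n_{i+j} dt)
(per-cluster, 1/t_s) and K⁺_ij = merges/(V ∫ c_i c_j dt) (second
order, r_a³/t_s); the per-volume event rate merges/(V T) is emitted
alongside since the two normalizations differ only by known factors.
Size-class aggregation (e.g. the j-average of K⁻_4j) and the
forward/reverse flux ratio K⁺c_ic_j/(K⁻c_{i+j}) — unity iff detailed
balance holds — are provided.  Exposure integrals are trapezoids over
the per-frame size census; classes with zero exposure are omitted, not
reported as zero.

## The chipping master equation

The analytic model evolves cluster concentrations c_k under
size-independent aggregation K⁺ = 2 and single-particle breakup: every
cluster of size k ≥ 2 sheds one monomer at rate 2λ.  The fragmentation
is implemented event-based because the printed general fragmentation
terms, specialized literally to single-particle splits with a
symmetric kernel, double-count the monomer channel and do not conserve
mass; the event form k → (k−1) + 1 at per-cluster rate 2λ is the
unique bookkeeping that reproduces the generating-function equation

    dC/dt = C² + 2λ(1−z)/z·C + 2λ(1−z)²/z·N(t),

which a property test verifies numerically against the right-hand side
on random states (this also pins the constant 2λ).  The stationary
solution of the quadratic on the branch with C(1) = 0 and c_k ≥ 0 is
C(z) = (1−z)/z·[−λ + √(λ² − 2λNz)], giving a continuous transition at
λ_c = 1 between a sol (λ > 1, N = 1 − 1/(2λ), all mass in finite
clusters) and a gel (λ < 1, N = λ/2, a giant cluster holds mass 1−λ).

Series coefficients come from the binomial recursion of √(1 − az),
a = 2N/λ — c_j = λ(s_{j+1} − s_j) — with no numerical
differentiation.  The exact structure is
c_k = λ C_k a^k [(1−a) + 3/(2k) + O(k⁻²)] with C_k ~ k^{−3/2}/(2√π):

* gel phase: a = 1, so c_k ~ k^{−5/2} with no cutoff;
* sol phase: the tail is k^{−3/2} e^{−k/k_c} with
  k_c = 1/ln(1/a) = {2 ln λ − ln(2λ−1)}⁻¹, diverging as (λ−1)^{−2};
* near the critical point a window 1 ≪ k ≲ k_c opens in which the
  3/(2k) term dominates and the distribution shows the critical
  k^{−5/2} form; the −3/2 prefactor becomes visible only beyond
  k* ≈ (3/2)k_c.  Fits of the sol-phase exponent therefore use the
  compensated form A k^{−τ} e^{−k/k_c} on the far tail (or moderate λ,
  where k* is a few particles and the −3/2 regime starts immediately).

Numerics: the size axis is truncated at k_max (default 10⁴, with the
requirement k_max ≫ k_c checked in sol-phase use); mass aggregating
past k_max enters a non-interacting gel compartment (it neither
aggregates nor chips), which conserves total mass exactly and doubles
as the gel-phase detector.  The aggregation convolution is evaluated
by FFT; time integration uses DOP853 with rtol 10⁻⁸ (10⁻⁵ for phase
scans, where only the coarse mass budget matters) and non-negative
clipping of trial states.

Phase classification at a given λ evolves monomers in doubling time
chunks and decides "gel" as soon as the finite-cluster mass M₁ drops
below 0.99, or "sol" when the distribution is stationary with full
mass (|dN/dt| < 10⁻⁷, no gel influx, 99.9%-mass front advanced < 2%
over the last chunk).  Near λ_c both signals need times of order the
critical-slowing scale (λ−1)^{−2}; the budget is capped at t ≈ 6×10³
(the doubling chunk schedule overshoots it to ≈ 7.7×10³ so the
checkpoint times stay geometric), after which the tie-break compares
the cluster density — Aitken-Δ²-extrapolated over the last three
checkpoints, which cancels power-law transients exactly on geometric
checkpoints — with the two analytic branch values and picks the
nearer.  On a λ grid of step 0.02 this locates λ_c to one grid step.
Gel-side stationary densities converge as a slow power law (the
draining coarsening front); `stationary_density` therefore
Aitken-extrapolates checkpoint densities, which reaches the λ/2 branch
to ~10⁻³ in ~2×10⁴ time units.

## Critical-scaling fits

f_z ~ (z_c − z)^{−σ} and ξ ~ (z_c − z)^{−ν} are fitted by grid search
over the unknown critical value with OLS in log–log space at each
candidate, selecting the candidate maximizing R²; errors are block
bootstraps (block = 10 frames) to respect temporal correlation.  f_z
is a bounded fraction, so the divergence can hold only in a window
below z_c; the default window keeps pre-percolation frames with
0.02 ≤ f_z ≤ 0.5.  z and f_z (or ξ) are paired per frame, making the
curve time-parametric as in the underlying experiments.  The
z_max(ε) fit works the same way jointly over (ε_c, z_c) with exponent
θ free (no reference value exists for θ).  The hyperscaling relation
τ = d/d_f + 1 is provided as the cross-check linking the cluster-mass
exponent to the fractal dimension (τ = 5/2, d = 3 → d_f = 2).

## Synthetic data

`sample_sizes` draws cluster sizes from k^{−τ} e^{−k/k_c} by
inverse-CDF on a table truncated where the tail weight is < 10⁻¹².
`build_cluster` grows a bonded chain whose i-th particle is placed at
bond length b from its predecessor, as close as possible to a radial
envelope ρ_i = 0.7·b·(i+i₀)^{1/d_f}; winding at constant local density
inside a growing ball makes R_g(N) ∝ N^{1/d_f} with all consecutive
bond lengths exactly b.  The offset i₀ = max(0, 12(d_f−2)) compensates
the small-N discreteness of the envelope and was calibrated once
against the measured R_g(N) exponent of large generated clusters
(d_f ∈ {1, 2, 3} recover to ≈ ±0.03).  `assemble_frame` places
clusters with bounding-sphere rejection so inter-cluster gaps exceed
twice the bond length: the bond criterion then reproduces the
generator's partition exactly, which is the ground truth for the
cluster stage.  `scripted_trajectory` renders an explicit merge/split
schedule into frames (clusters as compact blocks on a spaced grid), the
ground truth for event tracking and rate estimation.  Fixtures carry
the target statistics but no dynamics, excluded volume, or spatial
correlations between clusters — tests on them validate the analysis
stages, not the physics of the simulator.

## Problem sizes and limitations

The bundled tests and the reproduction script run at desk scale:
master-equation scans at k_max = 10⁴, simulations at N ≈ 200–2000 for
tens of t_s.  At these sizes the simulation layer demonstrates the
qualitative gelation phenomenology (strong-attraction quenches grow a
dominant cluster, weak ones do not; association outruns dissociation;
single-particle detachment dominates splits).  Quantitative exponent
reproduction (σ ≈ 1.6, ν ≈ 0.8, z_c ≈ 5.5, ε_c/k_BT ≈ 2.5) requires
N ≳ 10⁴ and hours of integration; the pipeline supports it unchanged
through the same configs.  Other known limitations: no hydrodynamic
interactions, shear, or gravity; binary dilutions only; the
master-equation gel compartment is non-interacting (no sol–gel
kernel); and the near-critical phase classifier depends on analytic
branch values for its final tie-break, so it is a locator of the known
transition rather than a blind detector to better than one grid step.
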