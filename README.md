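# gelscape

Colloidal gelation as a nonequilibrium percolation transition: Brownian
dynamics of short-range-attractive particles, cluster and percolation
statistics, association/dissociation kinetics, and an analytically
solvable aggregation–fragmentation model — in one tested pipeline.

## The problem

Short-range-attractive colloids at moderate volume fraction
(φ ≈ 0.12) gel: growing clusters suddenly connect into a
system-spanning network.  This package treats that event as a
continuous nonequilibrium phase transition and provides the tools to
measure its signatures:

* the mean coordination number z (bonded neighbors per particle) as
  the order parameter, with the largest-cluster fraction f_z and the
  cluster correlation length ξ² = 2∑R_gi²N_i²/∑N_i² diverging as
  f_z ~ (z_c − z)^(−σ) and ξ ~ (z_c − z)^(−ν);
* cluster-mass distributions c_k ~ k^(−3/2)e^(−k/k_c) before and
  ~ k^(−5/2) after gelation, and the fractal dimension d_f from
  N ∝ R_g^{d_f}, linked by the percolation hyperscaling relation
  τ = d/d_f + 1;
* directly measured association/dissociation rate constants K±_ij,
  whose imbalance (association ≫ dissociation) shows the transition
  violates detailed balance.

The analytic backbone is the coagulation–fragmentation master equation
with constant aggregation kernel (K⁺ = 2) and single-particle breakup
at per-cluster rate 2λ ("monomer chipping").  Its generating function
obeys a Riccati equation whose stationary solution gives a continuous
sol–gel transition at λ_c = 1, cluster density N = 1 − (2λ)⁻¹ (sol)
vs N = λ/2 (gel), and a cutoff size k_c = {2lnλ − ln(2λ−1)}⁻¹ that
diverges as (λ−1)^(−2).

Simulations integrate the inertial Langevin equation for an equal
binary mixture (size ratio 1:1.1) with a steep Mie (30, 20) potential
(well depth ε, width ≈ 0.08 r_a, cutoff 1.5 r_a), quenched from a
liquid at ε/k_BT = 1 to the target attraction.  A continuous
square-well potential and the Baxter sticky-sphere mapping via second
virial coefficients connect the results to adhesive-hard-sphere phase
behavior.  See `docs/methods.md` for model details and numerical
choices.

## Worked example

```python
import numpy as np
from gelscape.master_equation import (KineticParams, series_coefficients,
                                      steady_state_density, cutoff_size, tail_fit)
from gelscape.potentials import MiePotential, second_virial

# stationary cluster-mass distribution of the chipping model, sol side
lam = 2.0
ck = series_coefficients(KineticParams(lam=lam), 400)
fit = tail_fit(ck, window=(60, 250))
print(f"N_inf = {steady_state_density(lam):.4f}")
print(f"tail exponent = {fit.exponent:.3f}, cutoff = {fit.cutoff:.2f} "
      f"(closed form {cutoff_size(lam):.2f})")

# Baxter stickiness at the critical attraction
v = second_virial(MiePotential(), kT=1.0 / 2.5)
print(f"B2* = {v.B2_reduced:.3f}, tau_B = {v.baxter_tau:.3f}")
```

prints

```
N_inf = 0.7500
tail exponent = 1.573, cutoff = 3.48 (closed form 3.48)
B2* = -2.045, tau_B = 0.082
```

i.e. three-quarters of the initial monomers survive as free clusters at
λ = 2, the mass distribution decays as ≈ k^(−3/2) (the fitted exponent
carries a small positive finite-size correction, 3/(2k(1−a)), that
vanishes deeper in the tail) under an exponential cutoff of ≈ 3.5
particles matching the closed form, and the potential at ε/k_BT = 2.5
maps to an adhesive hard sphere with stickiness τ_B ≈ 0.08–0.1 — the
known gelation-onset region.

A small end-to-end simulation (equilibrate → quench → cluster
analysis → scaling fit) runs through the CLI:

```bash
gelscape reproduce --seed 0 --out report.json
gelscape kinetics --lam 0.5 --kmax 4000 --out ck.csv
```

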