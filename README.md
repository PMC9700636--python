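# dpgeom

Large-deviation and information geometry of Markov jump processes on integer
lattices: tilted generating functions, variance-optimal importance sampling,
and the Hamiltonian (Doi–Peliti / WKB) stationary-path dynamics with its
conservation laws.

## Who this is for

Researchers working with stochastic population models — chemical reaction
networks, birth–death systems, evolutionary or epidemiological population
processes — who need rare-event (tail) probabilities, large-deviation rate
functions, or the phase-space (eikonal) picture of how distributions and
sampling biases propagate in time.

## The machinery

For a distribution ρ on the non-negative integer lattice, the cumulant
generating function (CGF) is

    ψ(θ) = log Σ_n ρ_n e^{θ·n},        z_i = e^{θ_i},

and each tilt θ indexes a member ρ̃_n = ρ_n e^{θ·n − ψ} of the exponential
family over ρ — an importance distribution with likelihood ratio
e^{θ·n − ψ}. The package computes, by exact summation on a truncated lattice:

* the mean n(θ) = ∂ψ/∂θ, the Fisher metric g = ∂²ψ/∂θ² (tilted covariance),
  and the cubic (Amari–Chentsov) tensor T = ∂³ψ/∂θ³;
* the Legendre transform ψ*(n) = sup_θ [θ·n − ψ(θ)] — the large-deviation
  function — with its dual tilt θ(n) and inverse metric;
* tail probabilities P(n > n̄) with the unbiased tilted estimator
  h̃ = e^{ψ − θn} 1{n > n̄}, the Chernoff bound e^{ψ − θn̄}, the matching
  variance bound, and the variance-optimal tilt whose bound is e^{−ψ*(n̄)};
* the master-equation generator T of a mass-action model (dρ/dt = Tρ), its
  matrix-exponential evolution and steady states.

At large scale the generator acts on generating functions through a
phase-space Hamiltonian, the Liouville function

    ℒ(θ, n) = Σ_r k_r (1 − e^{θ·(ȳ_r − y_r)}) Π_i n_i^{y_ri},

whose characteristics θ̇ = ∂ℒ/∂n, ṅ = −∂ℒ/∂θ carry the final-time tilt
z = e^{θ_T} and the initial CGF ψ₀ into a two-point boundary problem solved
here by shooting. Along solutions the package verifies the conservation laws
that make this dynamics an *information transport*: ℒ constant, Liouville
phase-volume conservation (unit monodromy determinant), the Hamilton–Jacobi
equation ∂ψ*/∂t = ℒ(∂ψ*/∂n, n) for the evolved rate function, and the
invariance of the pairing δθ·δn between final-tilt variations (transported
backward) and base-distribution variations (transported forward).

The two-state hopping system a ⇌ b with N independent walkers is included in
closed form (module `dpgeom.two_state`): overlap parameter Λ, conserved
density Φ̂₀ = (1 + Λe^{−T})⁻¹, invariant CGF ψ/N = −log Φ̂₀, exponential
stationary-path laws, the Fisher eigenvalue in both its coherent-data and
exponential-coordinate forms, the conserved volume integral ∫ dv du Φ̂₀²,
and the dual covariant-transport brackets (±1 plus Le Chatelier-like
susceptibilities) that sum to zero.

## Worked example

```python
import numpy as np
from dpgeom import (poisson_distribution, TailQuery, exact_tail,
                    optimal_tilt, tilted_estimate)
from dpgeom import two_state as ts

# --- rare-event estimation for a Poisson(2) count ---
rho = poisson_distribution([2.0], [40])
q = TailQuery(nbar=5.0)                      # P(n > 5), strict convention
theta = optimal_tilt(rho, q)                 # log(5/2): mean-matching tilt
est = tilted_estimate(rho, q, theta, n_samples=100_000, seed=7)
print(f"exact tail         P(n > 5) = {exact_tail(rho, q):.7f}")
print(f"optimal tilt       theta    = {theta[0]:.6f}")
print(f"tilted estimate             = {est.estimate:.7f} +/- {est.stderr:.7f}")
print(f"Chernoff bound e^(-psi*(5)) = {est.chernoff_bound:.6f}")

# --- conserved information density of the two-state system ---
params = ts.TwoStateParams(k_plus=2.0, k_minus=1.0)   # steady state 2/3 : 1/3
bnd = ts.TwoStateBoundary(nu_bar_0=-0.25, nu_under_T=-1/6, T=3.0)
phi0, psiN = ts.phi0_and_invariant_cgf(params, bnd)
rect = ((-1/6 - 0.075, -1/6 + 0.075), (-0.25 - 0.05, -0.25 + 0.05))
vol = ts.descaled_uv_and_volume(params, rect, 3.0, np.linspace(0, 3, 5))
print(f"Lambda   = {ts.overlap_lambda(params, bnd):.6f}")
print(f"PhiHat0  = {phi0:.6f},  psi/N = {psiN:.6f}")
print(f"conserved volume integral = {vol['integral'][0]:.9f}, "
      f"max drift {vol['max_deviation']:.2e}")
```

This prints (exact values, seeded sampling):

```
exact tail         P(n > 5) = 0.0165636
optimal tilt       theta    = 0.916291
tilted estimate             = 0.0166210 +/- 0.0000918
Chernoff bound e^(-psi*(5)) = 0.205676
Lambda   = 0.625000
PhiHat0  = 0.969822,  psi/N = 0.030643
conserved volume integral = 0.003161042, max drift 1.39e-17
```

The tilted estimate agrees with the exact tail within one standard error
while using two orders of magnitude fewer effective samples than naive Monte
Carlo would need; the Chernoff bound is the tightest exponential bound,
attained at the Legendre tilt. For the two-state system, Φ̂₀ is the
phase-space density conserved along stationary paths, ψ/N = −log Φ̂₀ is the
time-invariant scaled CGF, and the volume integral of Φ̂₀² over the
transported boundary rectangle is constant to machine precision — Liouville's
theorem for the information carried between initial distributions and
final-time sampling biases.

A command-line interface mirrors the library:

```
dpgeom two-state --k-plus 2 --k-minus 1 --nu-bar0 -0.25 \
       --nu-under-t -0.1667 -T 3 --out report/
dpgeom tilt-estimate --rho dist.csv --threshold 5 --theta auto \
       --samples 100000 --seed 7 --out report/
```

## Documentation

`docs/methods.md` describes the model assumptions, numerical choices
(truncation, Legendre solver, shooting tolerances), what the synthetic study
conditions do and do not probe, and known limitations.
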