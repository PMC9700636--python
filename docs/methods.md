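# Methods

## Scope and model class

The package treats continuous-time Markov jump processes on the
non-negative integer lattice in D species, with transitions given by
integer stoichiometries (y_r, ȳ_r) and mass-action propensities
k_r Π_i n_i!/(n_i − y_ri)! (proportional sampling). Three layers are
implemented on top of this model class:

1. **Exact lattice layer** — the master-equation generator on a truncated
   lattice, its evolution and steady states, and the exponential-family
   geometry (CGF, tilts, Fisher metric, cubic tensor, Legendre/rate
   function, Bregman divergence) by exact summation.
2. **Stationary-path layer** — the large-deviation (eikonal) Hamiltonian
   dynamics of the generating function, as a two-point boundary-value
   problem in phase space, with its conservation diagnostics.
3. **Closed-form layer** — the two-state hopping system, where every object
   of the first two layers has an explicit formula and serves as the
   verification surface.

Time-dependent rate constants are not supported: the API accepts constants
only, and the adjoint (descaled) coordinate transform explicitly rejects
time-dependent generators, whose extra d/dt log n̂ term is out of scope.

## Truncation and the generator

The lattice is truncated to a user-chosen box 0 ≤ n_i ≤ max_counts_i,
enumerated row-major over species (last index fastest), optionally cut to a
conserved shell w·n = const; flat indices are fixed by this convention and
reproducible. The generator has column sums exactly zero: a jump whose
target leaves the box is *dropped*, and its propensity is recorded in a
separate `boundary_outflow` vector. This keeps probability exactly
conserved (the dynamics reflect at the wall) while making truncation error
visible as a diagnostic rather than a silent mass leak; users should grow
the box until `boundary_outflow` is negligible where the distribution has
support. Evolution uses the dense matrix exponential below 2,000 states and
Krylov `expm_multiply` above; steady states come from the dense null space
and require a one-dimensional kernel, so models with conserved quantities
must be restricted to a sector first (the error message says so).

## Exponential-family geometry

All moments are exact weighted sums over the truncated lattice, computed
from log-weights with `logsumexp` for stability; finite differences appear
only as cross-checks in the test-suite (central, step 1e-4). The Legendre
transform maximises the concave dual θ·n − ψ(θ) by damped Newton iteration
(gradient tolerance 1e-9, step halving on non-improvement, bracketed
coordinatewise fallback). Conserved quantities give exactly flat directions
of ψ: the Fisher metric is inverted by eigendecomposition with eigenvalues
below 1e-10 (relative) treated as degenerate, the degenerate subspace is
returned explicitly, and a requested mean off the conserved shell raises an
"unreachable mean" error instead of a silent projection.

## Importance sampling

Tail queries are one-dimensional (a declared species or integer linear
combination); the strict convention n > n̄ is the default and every report
names the convention used, since the ratio estimator below uses n ≥ n̄.
Sampling is inverse-CDF on the truncated lattice from a seeded
`numpy.random.default_rng`; seeds are mandatory arguments. The
variance-optimal tilt is the Legendre tilt θ(n̄) of the (marginal)
distribution, no adaptive refinement is attempted.

The parameter-difference estimator compares conditional exceedance ratios
P(n ≥ n_B)/P(n ≥ n_A) between two sample sets and divides the log-ratio by
n_B − n_A, estimating the difference of exponential-family parameters to
leading exponential order. Its accuracy depends on the thresholds being
genuine tail thresholds *for both arms*: in the reference study (binomial
N = 200 per count, planted log-odds difference 0.2, 10^6 samples per arm)
the thresholds are placed at the larger arm's mean +0.5σ and +1.5σ. Placing
them relative to the smaller arm's mean puts n_A below the other arm's
mean, where P(n ≥ n_A) ≈ 1/2 is not a large-deviation probability and the
estimator's deterministic (infinite-sample) bias alone is ~33%; with the
adopted placement the deterministic value is 0.170 (15% bias, shrinking
with system size) and sampling noise at 10^6 draws is ~2%.

## Stationary-path dynamics

The Liouville function is built symbolically (sympy) from the model
stoichiometry, in coherent-state fields (φ⁺, φ) and in number-potential
coordinates (θ, n) with φ⁺ = e^θ, φ = e^{−θ}n; all first and second
derivatives are exact compiled expressions, never finite differences. The
Hamiltonian sign convention is θ̇ = +∂ℒ/∂n, ṅ = −∂ℒ/∂θ, under which the
θ = 0 section reproduces the deterministic mass-action rate equation and
the two-state closed forms are recovered with their printed signs.

The boundary problem (final tilt φ⁺_T = z, initial mean n₀ = ∇ψ₀(θ₀)) is
solved by single shooting with Newton iteration on θ₀: residual tolerance
1e-10 on θ_T − log z, finite-difference shooting Jacobian, damped steps,
and bounded restarts from a ladder of initial guesses (log z · e^{−T},
log z, 0, log z/2 — the first is the slow-relaxation heuristic). Time
integration is adaptive eighth-order Runge–Kutta (DOP853) at rtol 1e-10 /
atol 1e-12 with a dense output used by all transport diagnostics; the
action and the running CGF ψ_t(θ_t) = ψ₀ + ∫(θ̇·n − ℒ) are accumulated as
extra quadrature states. Collocation was not needed for the models
exercised here; shooting failure raises with the residual rather than
falling back silently.

Conservation diagnostics, all computed rather than assumed:

* drift of ℒ along the path (autonomous Hamiltonian);
* phase-space divergence of the coherent-state field (identically zero by
  pairwise cancellation; evaluated from exact second derivatives);
* the monodromy matrix from the variational equations; its determinant on
  the dynamical (nonzero-Fisher-eigenvalue) subspace is 1. Eigenvalues of
  the dynamical block are chart-dependent along a trajectory; the e^{±T}
  pair of the two-state system is exhibited in the descaled (v, u) chart,
  where the flow is a constant-coefficient dilation;
* the split-CGF invariance: recombining the running CGF at any interior
  time with the remaining action integral (independent Simpson quadrature)
  reproduces ψ_T — the implementable stationary-point form of conservation
  of the phase-space density; the functional-integral density itself is
  never materialised;
* the Hamilton–Jacobi residual ∂ψ*/∂t − ℒ(∂ψ*/∂n, n) against an
  independently evolved distribution, with a central time difference
  (second-order in the step); the tilt comparison ∂ψ*/∂n = θ projects out
  conserved flat directions, along which θ is a gauge;
* dual tangent transport: δθ integrated backward from its final value and
  δn forward from its initial value through the exact mixed Hessian of ℒ,
  with the pairing δθ·δn conserved; δη optionally transported in the
  adjoint chart built from a supplied steady state. The initial base
  variation can be given directly as δn₀ or as δη₀ through the initial
  family's metric (Hessian of ψ₀).

## Two-state closed forms

All closed forms are implemented in descaled time τ (dτ/dt = k₊ + k₋)
with the steady-state offset ν̂ = (k₊ − k₋)/(2(k₊ + k₋)); conversion to
physical time happens only at the I/O boundary. The additive
exponential-family forms use tanh/cosh throughout (θ = 2 artanh 2ν̲ − θ̂
and cyclic relatives). Identity checks that the module enforces at
tolerance 1e-10 or better on every call: the two forms of the Fisher
eigenvalue, the bracket form of the invariant CGF against −log Φ̂₀, the
three-term decomposition of the coherent-state Hessian defect against
−(ν − ν̲)², and the equality of the connection-coefficient and
density-susceptibility routes to the covariant metric change. These
identities were additionally verified symbolically during development.

The conserved volume integral maps a boundary rectangle (in ν̲_T, ν̄₀)
through the affine flow laws and integrates Φ̂₀² = (1 + uv)^{−2} over the
image with 80-point Gauss–Legendre quadrature per axis. Because the flow
dilates u and v reciprocally and uv is pointwise invariant, the integral is
conserved to machine precision; the per-τ values are reported so that the
conservation is measured, not asserted.

For this linear model the binomial family is *exactly* preserved under
evolution, so stationary-point quantities agree with exact lattice
quantities to numerical precision at every N, not merely to leading
exponential order; the N-ladder convergence checks therefore collapse to
exactness checks. This is a feature of the linear verification surface, and
nothing about nonlinear models should be inferred from it beyond the
correctness of the shared machinery.

## Synthetic study conditions

All inputs are synthetic: Poisson and binomial/multinomial base
distributions, the two-state model, and seeded ensemble draws. Default
study sizes — Poisson mean 2 truncated at 40, binomial ladders N = 20–160,
two-state N = 100 with boundary data (ν̄₀, ν̲_T, T) = (−1/4, −1/6, 3) at
steady-state offset 1/6, 10^6-sample arms for the ratio estimator — are
the reference conditions of the closed-form system and small enough that
every quantity has an exact oracle. What passing tests show: the machinery
reproduces exact lattice computations and closed forms, and the stochastic
estimators are unbiased with the stated bounds. What they do not show:
behaviour on stiff or multistable nonlinear networks (single-branch
shooting only; instanton multiplicity is out of scope), truncation
adequacy for heavy-tailed models, or estimator performance when tail
thresholds are misplaced relative to the arms' means (see above).

## Known limitations

* Multi-dimensional tail queries are reduced to declared 1-D marginals.
* The η-difference estimator requires user-supplied thresholds; no
  automatic placement rule is provided, only the guidance above.
* Shooting can fail for strongly nonlinear Liouville functions at long
  horizons; the failure is explicit, and no collocation fallback is
  currently wired in.
* Steady-state detection uses a dense eigendecomposition, practical only
  for a few thousand lattice states.
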