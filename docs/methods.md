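# Methods

## Model

A linear perceptron maps N presynaptic rate signals onto a scalar output
over P = αN patterns. Weights obey Dale's law (w_i ≥ 0 for the first
round(f_E·N) rows, ≤ 0 for the rest) and training minimizes

    E(w, b) = ½ Σ_μ (Σ_i w_i x_iμ + b − y_μ)² + (Nγ/2) Σ_i w_i² ,

with b either learned or clamped. Inputs are x_iμ = x̄_c + σ_c ξ_iμ with
per-population means and standard deviations; the fluctuations ξ have unit
variance and are independent across neurons. The Nγ scaling of the ridge
term and b = I√N reflect the O(1/√N) magnitude of individual weights at
the optimum, so that ε = E/N, v = Σw_i² and I are all O(1) observables.

Two statistical models of signal structure are treated:

- **Ensemble covariance (EC).** Each ξ row is a stationary Gaussian
  process with a unit-diagonal Toeplitz covariance C (exponential kernel
  e^{−|lag|/τ} or Gaussian/rbf kernel e^{−lag²/2τ²}); the output carries
  its own covariance C^y. The theory depends on C only through its
  eigenvalues, which converge to the power spectral density λ(φ):
  (1−x²)/(1−2x cos φ + x²) with x = e^{−1/τ} for the exponential kernel,
  and the Jacobi theta function ϑ₃(φ/2, q) with nome q = e^{−1/(2τ²)} for
  the rbf kernel.
- **Sample covariance (SC).** ξ = U S Vᵀ with Haar-distributed factors and
  a prescribed singular-value profile; the theory depends on the
  eigenvalues λ^x of ξξᵀ/N (the PCA variances) and on the output expansion
  coefficients c_μ on the right singular basis, through Stieltjes-type
  averages. I.i.d. inputs are the special case where λ^x follows the
  Marchenko–Pastur law with edges (1±√α)².

## Saddle-point theory

The zero-temperature replica-symmetric free energy yields a small closed
system in the scaled order parameters (Δq̃_w, A, B, C, q_w, I). Replica
symmetry is exact here: the training problem is a strictly convex QP for
γ > 0, so there is a unique minimum.

Per-population entropic terms carry the precision κ_c = A + γ/σ_c²: the
ridge penalizes w, not the rescaled variable J = σ√N·w, so populations
with larger input fluctuations feel relatively less regularization. With
the bias at its optimum the conjugate B vanishes identically, and:

- Δq̃_w solves the scalar fixed point
  Δq̃_w = Σ_c f_c /(2 κ_c) with A = α⟨λ^x/(1+Δq̃_w λ^x)⟩.
- ε = (σ_y²/2N) Σ_μ λ^y_μ/(1+Δq̃_w λ^x_μ), v = (C/2) Σ_c f_c/(σ_c² κ_c²),
  ε_err = ε − (γ/2)v, and b = I√N + ȳ.
- The rescaled-weight density is p0 δ(w) plus truncated Gaussians with
  std Σ_c = √C/(σ_c κ_c) per population; p0 = f_E H(−η_E B) + f_I H(η_I B)
  equals ½ exactly at B = 0.

With the bias clamped (B free), the full system is solved by damped
fixed-point iteration (damping 0.5) with B obtained from a bracketed root
solve of the monotone bias equation at each step; ε then carries explicit
B-dependent entropic terms that reduce to the spectral formula at B = 0.

Mixed input/output kernels (C^x ≠ C^y) use the circulant (ring-topology)
approximation: both spectra are evaluated on a common frequency ordering
and paired rank-by-rank. This is exact for circulant covariances and a
good approximation for Toeplitz ones at the sizes used here.

In the SC theory, the w-side spectral relation is the N-normalized
resolvent Δq̃_w = ⟨1/(λ^x + Λ̃_w)⟩ including the (1−α)₊ zero modes, with
the conjugate Λ̃_w = 1/Δq̃_w − A; energetic averages ⟨λ^y …⟩ are
(1/P)-normalized sums over output components paired by rank, with λ^x = 0
beyond min(N, P). These conventions are forced by two exact checks
implemented in the tests: the SC theory must coincide with the EC theory
for i.i.d. inputs (Marchenko–Pastur spectrum), and the unconstrained
formula (Λ̃_w = γ) must reproduce the pseudo-inverse Monte-Carlo averages.
The constrained weight norm uses the envelope identity v = 2 dε/dγ,
evaluated by a central finite difference along the solution path
(step 1e−6·max(1, γ)); in the unconstrained limit this reproduces the
closed form α σ_y²⟨λ^x λ^y/(λ^x+γ)²⟩ exactly.

## Solver

The constrained fit is solved exactly, not iteratively to tolerance: a
gauge transformation (flipping inhibitory input rows) turns the problem
into nonnegativity-constrained ridge regression, a learned bias is
eliminated by centering over patterns, and the resulting strictly convex
QP on the normal equations is solved by block principal pivoting with
Cholesky subproblem solves. Bound coordinates are exactly zero, which is
what makes the silent-synapse fraction p0 well defined; the KKT residual
(default tolerance 1e−10, relative to the largest gradient component) is
reported on every fit. If the number of infeasibilities stops decreasing,
the pivoting falls back to single-index (Murty) exchanges, which
guarantees finite termination for positive-definite systems. At γ = 0 the
normal matrix can be singular, so the solver switches to Lawson–Hanson
NNLS on the design matrix. Tiny closed-form instances, exhaustive
active-set enumeration, and an independent stacked-NNLS route serve as
oracles in the test suite.

## Numerical choices

- **Root finding.** The scalar overlap equation is bracketed on a
  log-spaced grid over [1e−12, 1e12] and polished by Brent's method to
  relative precision ~9e−16. Exact grid hits are accepted directly.
- **Capacity detection.** At γ = 0 the existence of a finite overlap
  solution is decided through the divergent-overlap limit: the load side
  saturates at α times the positive-eigenvalue mass of the spectrum while
  the entropic side equals ½. This analytic criterion is the only stable
  one for rapidly decaying spectra (e.g. rbf with τ = 10), whose
  eigenvalues fall below machine precision: just above capacity the
  overlap is finite mathematically but exceeds floating-point range, so a
  direct root search cannot represent it. Eigenvalues above −1e−10 count
  toward the positive mass (PSD round-off of strictly positive-definite
  kernels); spectra with genuine atoms at zero should pass their mass
  explicitly.
- **PSD factorization.** Covariance square roots come from an
  eigendecomposition with eigenvalues in [−1e−10, 0) clipped to zero
  (rbf Toeplitz matrices are numerically semidefinite); anything below
  −1e−10 raises.
- **Theta series.** ϑ₃ is truncated once a term falls below 1e−16; the
  O(1e−16) alternating-series noise where the true value underflows is
  clamped to zero.
- **Spectral averages.** Theory averages default to the eigenvalues of the
  finite P×P Toeplitz matrix (finite-size-matched, the right object to
  compare with N ≈ 1000 simulations); a thermodynamic mode evaluates the
  closed-form spectrum on a 4096-point grid instead.
- **Degenerate inputs.** f_E ∈ {0, 1} is a single orthant; a single
  pattern with a learned bias is absorbed exactly (w = 0, b = y); γ = 0
  with P > N is rejected for the unconstrained interpolating solver.

## Synthetic data and seeding

The generators produce exactly the ensembles the theory assumes: Gaussian
stationary processes (EC) and Haar-rotated fixed spectra (SC), with
defaults mirroring the standard study conditions — N = 1000, 50 samples
per point, unit population statistics, learned bias. One integer master
seed drives everything; per-component streams are derived via
`SeedSequence(seed, spawn_key)` and per-cell seeds in sweeps via hashed
cell coordinates, so any emitted number is regenerable from (manifest,
seed). What the generators deliberately do not emulate: non-Gaussian rate
statistics, correlations across neurons (EC assumes independent rows),
nonstationary kernels, and input/output correlations of teacher–student
type. Agreement of theory and simulation here therefore validates the
mathematics and the solver, not the biological realism of the signal
model.

Desk-scale problem sizes are used throughout the suite: training runs at
N = 1000 (N up to 4000 with 20 seeds for the balance-scaling experiment,
where the h̃ → ȳ limit needs the largest sizes), 25–50 realizations per
comparison point, and three-standard-error bands for stochastic checks.

## Open design choices

- **Index conventions in the SC profiles.** The singular-value profile
  uses the normalized rank index a_k = k/N and the output profile
  a_μ = μ/P, making both resolution-independent; output coefficients are
  passed through unnormalized. With these conventions, concentrating
  output power (at fixed total) on high-variance input components lowers
  the error, and on a flat (orthogonal-model) spectrum the error is
  exactly width-independent — both asserted in the tests.
- **Balance diagnostics.** h̃ = Σ_c N_c w̄_c x̄_c + b and
  c = (1/√N P) Σ_iμ δw_i x_iμ are computed with the nominal population
  means; only the learned-bias limits (h̃ → ȳ, c → 0) are asserted
  quantitatively, since the relative √N scaling of the two terms under a
  clamped bias depends on plotting conventions.
- **Zero counting.** A weight is silent iff the active-set solver leaves
  it at the bound (exact zero); for external solver routes a relative
  threshold of 1e−6 on √N·w (against the median active magnitude) guards
  the definition.

## Known limitations

- The fixed-bias saddle-point iteration requires γ > 0 and at least one
  population with nonzero mean-to-std ratio η_c.
- For γ = 0 loads just above ½ on super-exponentially decaying spectra the
  overlap is not representable in double precision; the solver raises
  rather than returning a truncated value (the phase classification
  remains correct).
- The SC theory assumes rotational invariance (Haar factors); empirical
  spectra from structured data violate this to an unquantified degree.
- Finite-size corrections at N = 1000 are visible (a few percent in v near
  small loads); the test suite absorbs them within Monte-Carlo error
  rather than modeling them.
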