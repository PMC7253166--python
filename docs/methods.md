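# Methods

## Channel model and assumptions

The package models communication through a network as a linear
Gaussian channel with memory. State dynamics are `dx/dt = Ax` with
`A ∈ ℝ^{n×n}` stable (all eigenvalue real parts negative); packets
`u_k ∈ ℝ^m` are zero-mean Gaussians with covariance `Σ` (unit trace),
delivered as impulses through `B ∈ ℝ^{n×m}` every `T` time units;
outputs `y = Cx` (`C ∈ ℝ^{p×n}`) are corrupted by i.i.d. Gaussian
readout noise of variance `σ²` per output. Assumptions worth keeping
in mind:

* **Linearity.** Node dynamics are first-order and linear — the
  standard linearization of rate or membrane-potential dynamics around
  a fixed point. Saturations, thresholds and adaptation are outside
  the model.
* **Stationarity.** Interference is evaluated at steady state: an
  infinite train of packets has already been transmitted.
* **Gaussian encodings.** The capacity is maximized over Gaussian
  input distributions only; `Σ` is the complete description of the
  encoder.
* The trace constraint is imposed as an equality `tr Σ = 1`: the
  objective is nondecreasing in input power, so the budget always
  binds at the optimum.

## Computation

**Gramians.** The finite-horizon observability Gramian
`O(T) = ∫₀ᵀ e^{Aᵀt}CᵀC e^{At} dt` has three interchangeable
implementations: (i) `doubling` (default) — a truncated Taylor
expansion of the integral on an initial interval `h` with
`‖A‖h ≤ ½`, then window doubling `O(2t) = O(t) + e^{Atᵀ}O(t)e^{At}`;
(ii) `lyapunov` — the stable-case closed form `Q∞ − e^{AᵀT}Q∞e^{AT}`
with `Q∞` from the continuous Lyapunov equation; (iii) `ode` —
adaptive integration of `X' = AᵀX + XA + CᵀC`. The three agree to
~1e−12 on well-conditioned inputs (tested); `doubling` is the default
because every accumulation is a PSD congruence, free of the
catastrophic cancellation that ruins the Lyapunov closed form under
strong transient amplification (for a directed chain with `α = 100`
the integrand's norm transiently spans ~17 orders of magnitude).

The discrete controllability Gramian solves the Stein equation
`W − e^{AT} W e^{AᵀT} = BΣBᵀ` by squared Smith iteration
(`X ← X + E X Eᵀ`, `E ← E²`), again PSD-accumulating and quadratically
convergent. Inside the capacity objective the iteration runs on a
*factor* (`W = FFᵀ`, `F ← [F, E^{2ʲ}F]` with LQ re-compression), so
small-but-amplified directions of `W` survive at factor precision
instead of being lost at `ε‖W‖`.

**Objective.** The two determinant arguments of the capacity differ by
the rank-m update `OhQOh` (`Oh = O^{1/2}`, from an eigendecomposition
with negative eigenvalues clipped at `−1e−10` relative), so the
objective is evaluated as the m×m determinant
`½ log₂ det(I_m + KᵀM₂⁻¹K)` with `K = Oh B Σ^{1/2}` and
`M₂ = σ²I + (Oh E F)(Oh E F)ᵀ`, applied through the SVD of its Gram
factor and assembled as `Σ log1p(sᵢ²)` over singular values of
`d⁻¹/²UᵀK`. No difference of large log-determinants is ever formed.
This keeps evaluations finite, nonnegative by construction, and below
the noiseless information bound even in regimes (α = 100 chains) where
both the naive `det(σ²I + OW)` route and a long-double reimplementation
of it break down. Remaining bias in extreme regimes is downward
(spurious singular-value floors only ever *inflate* the interference
denominator), i.e. conservative.

**Gradient.** `W` is affine in `Σ` through the Stein operator
`L(Q) = Σₖ EᵏQEᵀᵏ`, whose adjoint is the Stein solve with `Eᵀ`. The
exact gradient is
`∇_Σ = (1/2ln2)·Bᵀ[L*(G₁) − L*(EᵀG₂E)]B` with `Gᵢ = Oh Mᵢ⁻¹ Oh`,
`M₁⁻¹` obtained from `M₂⁻¹` by a spectrally applied Woodbury update.
It matches central finite differences to ~1e−10 (tested) and replaces
the automatic differentiation a black-box implementation would need.

**Optimization over Σ.** The trace-one PSD cone is parameterized as
`Σ = FFᵀ/tr(FFᵀ)` with an unconstrained factor `F ∈ ℝ^{m×m}` — every
iterate is exactly feasible, and rank-deficient optima (expected at
high noise) are reachable. Two backends: scipy L-BFGS-B on the factor
(default; the objective is rescaled by its value at the start so the
solver's relative tolerances remain meaningful when capacities are
~1e−6 bits), and a plain gradient ascent with Armijo backtracking
(`method="factor-gradient"`), kept as an independent reference.
Restarts: identity/m first, then caller-supplied starts — the capacity
engine always adds the rank-one covariance along the top eigenvector
of `BᵀOB`, which is the exact high-noise optimum — then seeded random
factors, up to `n_restarts` (default 20; published analyses of this
problem class used 10²–10³, which remains configurable). Ties resolve
to the earlier restart. When the concavity certificate
`CᵀC ⪰ e^{AᵀT}CᵀCe^{AT}` holds (the dimensionally consistent reading
of the condition; verified to imply 1-restart/20-restart agreement),
a single run from the identity is used.

**Structure short-circuits.** `m = 1` needs no search (`Σ = 1`). For
symmetric `A` with `B = C = I` the channel decomposes into independent
scalar channels along eigenmodes; the capacity reduces to a provably
concave power allocation over the probability simplex, solved by SLSQP
(objective normalized for the same small-value reason) and validated
against a brute-force simplex grid (step 0.01) and against the general
optimizer. General non-symmetric normal matrices take the generic
path; the decomposition shortcut is only claimed where
diagonalization is orthogonal.

**Windows.** `R_T` is evaluated only at `T ≥ 1e−3` (the objective is
ill-conditioned as `T → 0`); the single-node `T → 0` limit
`a/((1+2aσ²)ln2)` is available analytically and the window optimizer
reports a boundary flag when the best grid point is the smallest one.
`max_rate_over_T` refines interior maxima by golden-section search to
relative tolerance 1e−4.

## Network families

* **Chains** (`build_chain`): tridiagonal, `γ` on the diagonal
  (stability requires `γ < −2β`), forward `αβ`, backward `β/α`. The
  similarity `D A D⁻¹`, `D = diag(αᵏ)`, maps every `α` onto the
  symmetric chain, so the spectrum is `α`-independent (tested to
  1e−10) and `α` tunes non-normality alone. Sets of shorter chains are
  block-diagonal compositions (`chain_blocks`); how total size is
  split among blocks is the caller's choice.
* **Random stable ensembles** (`build_random_nonnormal`):
  `A = (−I + S)P`, `S` skew-symmetric with i.i.d. `N(0, σ_S²)` upper
  triangle, `P` inverse-Wishart with `ν = 24 + n` degrees of freedom
  and scale `ω⁻² = ν − n − 1` times the identity — so `E[P] = I`
  (verified by Monte Carlo) with heterogeneous eigenvalues. Stability
  holds for every draw (`xᵀ(−I+S)Px < 0` in the P-inner product).
  Sampling draws a Wishart (scipy) and inverts via Cholesky.

## Diagnostics

Effective dimensionality of a covariance is the participation ratio
`(Σλᵢ)²/Σλᵢ²` ∈ [1, n]. The non-normality scalar is Henrici's
departure from normality `sqrt(‖A‖_F² − Σ|λᵢ|²)` — the Frobenius mass
of the hidden feedforward (strictly triangular Schur) part — reported
normalized by `‖A‖_F` by default. There is no canonical scalar for
non-normality; Henrici's was chosen because it is standard, cheap and
exactly zero on normal matrices. The normalized variant saturates
quickly in disordered ensembles, so ensemble comparisons use the
unnormalized value (`normalized=False`).

## Connectome protocol

Inputs are a nonnegative weighted edge list (pre, post, weight) and a
class table (id, sensory/inter/motor, GABAergic flag). The adjacency
convention is `A[post, pre] = weight` (so `dx/dt = Ax` propagates
along edges); inhibition attaches to the *presynaptic* GABAergic
neuron — all its outgoing weights are negated after duplicate edges
are summed. Signs are applied before any manipulation, so
symmetrization and direction swaps act on the signed matrix (a
reversed inhibitory edge stays inhibitory). Dynamics are stabilized as
`(A − γI)/τ` with `τ = 0.5` and `γ` set so the largest eigenvalue
real part is −0.1; γ is recomputed for every manipulated realization,
since symmetrization and swaps move the spectrum. Readout noise
defaults to `σ² = 1`. Selectors are plain 0/1 indicator matrices.
Ensemble bands are normal-approximation 95% CIs (`mean ± 1.96 SE`;
percentile bootstrap behind `ci_method="bootstrap"`); per-realization
seeds derive from the base seed by unit increments. The default window
grid is 30 log-spaced points in [0.01, 10].

## The synthetic connectome generator

`synthetic_connectome_fixture` emulates the *schema and gross
statistics* of a chemical-synapse dataset: three classes in 88:82:107
proportions, an inhibitory fraction of 26/277, overall edge density
2194/(279·278), geometric integer weights, and a `directionality`
parameter that multiplies the probability of hierarchy-aligned edges
(sensory→inter→motor) by `1 + directionality` and divides
anti-aligned ones by the same factor (0 = no directed structure;
default 3). What it does **not** emulate: reciprocity statistics,
degree distributions, spatial organization, neuron identities, or the
actual magnitude of non-normality of any real connectome. Tests
passing on fixtures therefore certify the *pipeline* (stabilization,
selectors, nulls, bands) and the qualitative direction-of-effect on
graphs with known planted hierarchy — not quantitative claims about
real nervous systems, which require the real edge list in the same
file schema.

## Numerical choices and degenerate inputs

Stability threshold: spectral abscissa < −1e−12. PSD hygiene:
symmetrization plus clipping of eigenvalues above −1e−10 (relative);
anything lower raises. Stein iterations stop when the update falls
below 1e−15 of the accumulant and the squared propagator norm is
below the same tolerance; divergence (spectral radius ≥ 1) raises.
`σ² = 0` is rejected (the capacity may diverge; use `low_noise_rate`
for the noiseless rate). `Σ = 0` yields 0 bits. Zero factors in the
optimizer raise rather than silently renormalizing.

## Problem sizes

Default test and acceptance runs use desk-scale problems: chains of
length 8, ensembles of 10–20 matrices at n = 5–20 with 1–5 optimizer
restarts, connectome fixtures of 10–40 nodes, window grids of 5–10
points. All sizes are arguments; the paper-scale settings (n = 279,
100 realizations, 10²–10³ restarts, 30-point grids) run through the
same code paths.

## Known limitations

* Global optimality in the nonconvex regime is mitigated by restarts,
  not guaranteed; the certificate is sufficient, not necessary.
* Extreme transient amplification (e.g. chains at `α ≳ 100` with long
  windows) pushes past float64: values remain finite, monotone and
  bounded by the noiseless limit, but carry a conservative downward
  bias (cross-checked against an extended-precision reimplementation,
  which itself degrades first).
* Continuous-time controllability Gramians, time-varying or stochastic
  `A`, non-Gaussian encodings, and explicit decoders are out of scope.
* Gap-junction (undirected) connectome data cannot be analyzed — the
  protocol requires edge directionality.
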