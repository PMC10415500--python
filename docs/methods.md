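# Methods

This note documents the models, the numerics and the design choices behind
`turingfit`, in the order of the pipeline.

## Reaction–diffusion model and linear stability

The package ships the dimensionless two-species Gierer–Meinhardt kinetics

    f₁(u) = a − b·u₁ + u₁²/(u₂(1 + c·u₁²)),      f₂(u) = u₁² − u₂,

with diffusion matrix `D = s·diag(1, δ)`. Only the ratio δ of the two
diffusion constants affects stability; the overall scale *s* sets the
pattern wavelength. All parameters are positive (c = 0 is admitted as the
unsaturated limit). The solver and feature code are written for general
N-species kinetics with diagonal diffusion; the kinetics library contains
the Gierer–Meinhardt model only.

The homogeneous equilibrium solves `f(u*) = 0`; eliminating `u₂* = (u₁*)²`
leaves the scalar equation `a − b·u₁ + 1/(1 + c·u₁²) = 0`, which has a
unique positive root because the nonlinear term is bounded by 1 and the
function is strictly decreasing where it crosses zero. The root is found by
Brent's method on the bracket `(0, (1+a)/b + 10]` — derivative-free and
guaranteed; the c = 0 root upper-bounds the general root.

A Turing instability is declared when (a) all eigenvalues of `J(u*)` have
negative real part, (b) some finite `q² > 0` gives `J(u*) − q² D` an
eigenvalue with positive real part, and (c) the real parts are negative
again at the upper end of the q² grid. The test evaluates a geometric grid
of 400 points on `[1e−4, 50]` plus q² = 0; the cutoff 50 stands in for
`q² → ∞` and covers every wavelength resolvable on grids up to 128×128 at
the diffusion scales used here. For diagonal positive D the decay at large
q² is automatic, so the cutoff choice is uncritical. Eigenvalues come from
the general dense solver even though N = 2 admits a closed form; the
trace/determinant closed form is kept as a cross-check in the tests.

## Integrator

The PDE is discretized on an n×n torus (unit spacing, 5-point Laplacian
stencil) and integrated by implicit Euler with step h. Each step solves

    v ← (I − h dᵢ L)⁻¹ (v_k + h f(v))    per species i,  dᵢ = s δᵢ,

by fixed-point iteration. The torus makes `I − h d L` block-circulant, so
the inverse is applied per step as FFT → elementwise division by the
stencil symbol `1 + h d (4 − 2cos(2πk/n) − 2cos(2πl/n))` → inverse FFT; all
symbol entries are ≥ 1, so the matrix is invertible for any h. Symbols are
cached per (n, h, d) and invalidated when h changes.

Defaults (units of dimensionless model time): h = 0.2; inner fixed-point
tolerance ε_l = 10⁻³ on the relative update of the stacked species vector;
steady-state criterion `‖f(v) + D L v‖_∞ ≤ ε_k = 10⁻⁶` checked every
δt = 100; final time T_f = 2000 for grids up to 64, 5000 for larger grids
(patterns stop changing substantially before these times even when the
residual criterion is not met). The inner convergence norm acts on the
stacked vector of all species — per-species norms would differ only in
degenerate cases, and the stacked form reduces to the scalar one for N = 1;
this is a recorded choice, as is the stacked ∞-norm in the residual.

An analytic step bound combining invertibility and contraction of the
fixed-point map is provided (`step_size_bound`, with λ_max(L) = 8 for the
torus stencil) but is deliberately conservative; in practice the integrator
detects divergence (more than 50 inner iterations, or non-finite values)
and halves h, keeping the halved step from then on. h underflowing 10⁻⁶ is
a hard error.

Initial conditions draw every grid value independently from
`U[0.9 uᵢ*, 1.1 uᵢ*]` (PCG64, seeded); this converges quickly while
producing large pattern variability across seeds. In a batch, pattern i
uses seed `base_seed + i`, recorded in its provenance.

## Resistance-distance histograms

Only species 1 is featurized: the two species' patterns are rescaled
versions of each other, so their RDHs are redundant.

Edges of the torus grid get weight 1 when both endpoints are on the same
side of the grid-mean concentration and ε = 0.003 otherwise. The small
interface weight penalizes current across plateau boundaries; much smaller
values saturate long-range resistances, much larger values stop resolving
the geometry at small scales.

Effective resistances are defined through `K = (J + L_G)⁻¹` with
`R(v,v′) = K_vv + K_v′v′ − 2K_vv′`; the all-ones contributions cancel in
the difference, so the implementation uses a grounded-node inverse of the
sparse Laplacian instead (node 0 removed, SuperLU with symmetric
minimum-degree ordering, dense columns recovered in one multi-RHS solve).
This is O(m²) memory for an m-node grid — 134 MB at 64×64 — and avoids a
dense O(m³) inversion.

The RDH collects `R(v,v′)` for every source node v of the undersampled
grid V_t (t = 1 by default: no undersampling) and every v′ within toroidal
Euclidean distance r of v (v′ ≠ v), drops values above a ceiling R_max,
and bins the rest uniformly on `[0, R_max]` into B = 12 bins (numpy
half-open bins, last bin closed), normalized to total mass 1. The toroidal
minimal-image distance is a choice consistent with the periodic boundary
conditions. R_max is calibrated per batch as the maximum over patterns of
the per-pattern 99% quantile of collected values: occasional very large
resistances stem from numerical inaccuracies, and including them would
push most of the histogram mass into the lowest bins. The radius r sets
the spatial scale of the descriptor; r = 8 (with 64×64 grids) is the
default used throughout.

RDHs are exactly invariant to cyclic shifts, 90° rotations, transposition
and to reflecting the field about its mean. Two scalar features break the
symmetries deliberately: the maximal concentration c_m (location of the
right-most peak of a 25-bin concentration histogram; a peak must be a
local maximum holding at least 1 % of the pixels, which discards isolated
numerically inflated pixels — the floor value is our choice) and the
number n_c of connected components of the subgraph on nodes at or above
the mean (the threshold "grid mean" is likewise a choice).

## Kernels

* Symmetric χ² kernel `Σ xᵢx′ᵢ/(xᵢ+x′ᵢ)` and the exponential χ² kernel
  `exp(−χ²/γ)`; 0/0 summands contribute 0 (the limit of the expression).
* Wasserstein kernel `exp(−d²_W/γ)` with ground cost `(i−j)²` on bin
  indices, so distances are in units of bins. The squared distance is
  computed exactly by merging the two cumulative-sum breakpoint sequences
  and summing (Δcumulative)·(quantile-index difference)² over segments;
  zero-mass segments are skipped, which handles ties in the cumulative
  values (the monotonicity caveat of generalized inverse CDFs). The
  implementation is checked against the transport linear program in the
  tests.
* Gaussian kernel `exp(−‖y−y′‖²/γ)` for output (parameter) vectors.

## Support-vector regression

The ε-insensitive primal (no bias term — normalized nonnegative targets in
[0, 1] make the offset dispensable) is solved through its exact dual: with
`β = λα`, the dual is a box-constrained problem
`min (1/2λ)βᵀKβ − yᵀβ + ε‖β‖₁, |βᵢ| ≤ 1`, solved by cyclic coordinate
descent with closed-form soft-threshold/clip updates. This replaces a
general-purpose QP solver: the iteration is monotone, needs no tuning, and
strong duality recovers the primal optimum exactly (verified against an
independent SLSQP solve of the primal in the tests). A 10⁻¹⁰ diagonal
jitter guards marginally indefinite Gram matrices. The tube width defaults
to ε = 0.01 on normalized targets and is exposed as a hyperparameter; the
regularization λ and kernel scale γ are selected on the validation grid.

## Operator-valued-kernel joint regression

For vector targets the prediction needs three finite objects built from
the input Gram K_n (Wasserstein) and output Gram L_n (Gaussian on
normalized targets):

    T_n = L_n − (K_n + nεI)⁻¹K_nL_n             (ε = 10⁻⁴ by default)
    (K_n ⊗ T_n + nλI) u = vec(I_n)
    v(x) = vec(T_n · unvec(u) · k_x)

The covariance-operator form of the kernel is folded analytically into
T_n and never materialized. The Kronecker system is solved matrix-free:
GMRES on `X ↦ T_n X K_nᵀ + nλX` (restart 50, relative tolerance 10⁻⁸, the
returned residual re-verified by direct application); vectorization is
column-major throughout. The predicted parameter vector solves the
pre-image problem `min_y 1 − 2Σᵢ vᵢ exp(−‖y−yᵢ‖²/γ_out)` by gradient
descent with Armijo backtracking, initialized at the training target with
the largest vᵢ (the dominant bump of the mixture; ties go to the lowest
index). γ_out is tuned on the validation grid jointly with the input γ
and λ.

## Feedforward networks

ReLU hidden layers, affine output, Adam on mean-squared loss, batch size
32, learning rate 10⁻³, He initialization, inputs standardized with
training-split statistics. Training keeps the weight snapshot with minimal
validation loss (evaluated every 200 steps) and stops early after a
patience budget without improvement; the step/patience schedule scales
with dataset size: (4·10⁵, 10⁵) up to 50 points, (2·10⁵, 5·10⁴) for
mid-sized sets, (10⁵, 2·10⁴) from 5000 points. Architectures are searched
over depths 0–3 and widths {8, …, 128} on validation NRMSE. The networks
are implemented directly on numpy arrays — at these sizes (a dozen inputs,
a few thousand weights) explicit forward/backward passes are simple,
dependency-free and bit-reproducible under a seed.

## Evaluation protocol

Targets are normalized per column by their maximum over the dataset at
hand; NRMSE (RMSE / mean target) is computed on the normalized targets,
which matters only for multi-target reports (it equalizes the columns'
weights). Each dataset splits 60/20/20 into train/validation/test; the
validation split selects hyperparameters on a grid (γ ∈ {0.01, 0.03, 0.1,
0.3, 1, 3}, λ log-spaced over [10⁻⁴, 1], γ_out like γ; these grids are our
defaults — an optional refinement pass shrinks the grid ×3 around the
optimum), ties broken lexicographically; the test split is scored once.
For dataset sizes m ≤ 500 the NRMSE is averaged over the ⌊P/m⌋ disjoint
subsets of a pool of P patterns, each subset independently normalized,
split and trained.

## Synthetic data and what the tests show

All data are simulated by the package itself; there is no external input.
The generator reproduces the study conditions: the single-parameter sweep
draws c ~ U[0, 1.15] with a = 0.02, b = 1, δ = 100, s = 0.25 on 64×64
grids; the four-parameter sweep draws (a, b, c, δ) uniformly from
[0.01, 0.7] × [0.4, 2] × [0.02, 7] × [20, 200] with s = 0.4 fixed, and
rejects draws that fail the linear Turing-instability test (the analytic
test is much cheaper than simulating and is re-validated by the recorded
pattern amplitudes). What the simulations do **not** emulate: measurement
noise, non-periodic boundaries, non-square domains, model mismatch —
passing tests therefore demonstrate recoverability of parameters from
clean simulated steady states, not robustness to experimental imaging.

Problem sizes: the test suite exercises the full pipeline on a 30-pattern
pool at 32×32 with final time 500 (trend-level checks), and the acceptance
script reruns the single-parameter experiment on a 100-pattern pool at
64×64 with the full integrator settings and 5 disjoint 20-point subsets —
these pool sizes are the package's scaled default for a single-workstation
run; the protocol itself is unchanged at larger pools.

## Numerical edge cases and limitations

* Constant fields: every value is "high" relative to the mean, all edge
  weights are 1, the concentration histogram degenerates to one bin (c_m
  returns the constant), n_c = 1.
* Disconnected pattern graphs cannot occur for ε > 0 but are rejected
  explicitly for general graph inputs.
* Histograms off the simplex by more than 10⁻⁹ are rejected by the
  transport code (renormalized below that).
* The SVR QP is practical to a few thousand training points; beyond that
  coordinate descent slows markedly (the study protocol never exceeds
  3000).
* The equilibrium solve, and hence dataset generation, covers the
  Gierer–Meinhardt family; other kinetics require supplying the
  equilibrium explicitly.
* Extremely short or long pattern wavelengths relative to the grid degrade
  RDHs (discretization artefacts / close-up views); the sweep ranges above
  avoid both regimes.
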