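# Methods

## Two-timescale model and IMEX discretization

The package models parcellated brain activity as a discrete linear system
in which each scan's state depends both on the *concurrent* state (fast,
within-scan interactions) and on the *previous* scan (slow, lagged
interactions):

    x(k) = Q x(k) + A x(k-1) + B1 u(k) + B2 u(k-1),      Q_ii = 0.

The form is derived by splitting each sampling period `Δt` into a slow
sub-interval `Δt − τ` (explicit Euler) and a fast sub-interval `τ`
(implicit Euler), with the ratio `(Δt − τ)/τ = 1/ε` set by the timescale
separation `ε ∈ (0,1)`. Eliminating the unobserved mid-interval state
gives the closed-form block mapping `Q = τF_f`, `A = I + (Δt−τ)F_s`,
`B1 = τG_f`, `B2 = (Δt−τ)G_s`, which `imex_discretize` applies and
`continuous_from_signature` inverts exactly. Users supply `ε`
(`τ = Δt·ε/(1+ε)` is derived); simulation fixtures default to `ε = 0.2`,
an arbitrary but numerically comfortable separation. The zero-diagonal
constraint on `Q` excludes instantaneous self-loops, which would be
indistinguishable from rescaling a region's own signal.

Simulation solves the implicit relation each step,
`(I − Q) x(k) = A x(k−1) + B1 u(k) + B2 u(k−1)`, adds iid Gaussian noise
of standard deviation `noise_sd` to the state rows, and refuses systems
whose `(I − Q)` condition number reaches 1e12.

## Identification and what it can (and cannot) determine

Given one recording, the blocks are fit on the transitions `k = 1..T` by
minimizing a regularized one-step criterion with `Q_ii = 0` enforced by
excluding each state's own contemporaneous value from its regression.
Two modes are provided:

- `ridge` (default): squared criterion
  `‖E‖_F² + λ²(‖Q‖_F² + ‖A‖_F² + ‖B1‖_F² + ‖B2‖_F²)`, solved row-wise in
  closed form — deterministic and fast.
- `stated`: unsquared criterion `λ(‖Q‖_F + ‖A‖_F + ‖B1‖_F + ‖B2‖_F) + ‖E‖_F`,
  solved by majorize–minimize: each Frobenius norm is majorized by
  `‖M‖²/(2c) + c/2` at the current iterate, making every sweep a weighted
  row-wise ridge solve; the surrogate is tight at the iterate so the
  objective decreases monotonically. Iteration stops when the objective
  stalls within 1e-8 (relative), with a warning and the final gap on
  non-convergence.

Both modes coincide with ordinary least squares as `λ → 0`. `B1` pairs
with the *current* inputs `u(k)` and `B2` with the lagged `u(k−1)`,
consistent with the fast/slow roles of the gains (`B1 = τG_f` acts within
the scan interval).

**Partial identifiability.** For noise-free data the current states
satisfy `X^{1:T} = Â X^{0:T−1} + B̂1 U^{1:T} + B̂2 U^{0:T−1}` exactly
(`Â = (I−Q)⁻¹A`, etc.), so the stacked regressor matrix has rank `m + 2n`
and the criterion has an `(m−1)`-dimensional affine family of exact
minimizers per state row: `(Q_i + c, A_i − cÂ, B1_i − cB̂1, B2_i − cB̂2)`
for any row vector `c` with `c_i = 0`. Consequences, all covered by the
test suite:

- the one-step residual and the *reduced form* `(Â, B̂1, B̂2)` are
  determined uniquely (recovered to machine precision on noise-free
  data), but the structural split of `Â` into `(Q, A)` is not — the
  `λ → 0` fit returns the minimum-norm representative;
- for `m = 1` there is no concurrent coupling and the structural blocks
  themselves are recovered;
- with iid process noise the contemporaneous regressors are endogenous
  and the estimate is biased toward the reduced form (`Q̂ → 0` as
  `T → ∞`).

Fingerprinting is unaffected by this: it consumes the estimated blocks as
*signatures*, and those are deterministic, subject-stable functions of the
data. Recovery-style tests are therefore stated on the reduced form (or on
`m = 1`), and the structural-recovery experiment in the acceptance suite
reports the measured (large) error honestly.

## Subject fingerprinting

`modal_decompose` eigendecomposes the estimated `A` (feature mode `slow`),
optionally also `Q` (`full`), or the `A` of a one-timescale refit with
`Q = 0, B1 = 0` forced (`single`; the refit happens in
`identify_signature(..., single_timescale=True)` because it needs the raw
series, which a signature no longer carries). Complex conjugate eigenpairs
are replaced by the real/imaginary parts of one member — a real basis for
the same invariant plane — and every vector is canonicalized: unit norm,
entry of largest magnitude made positive (ties to the lowest index).
Canonicalization matters because the cosine distance is not sign-invariant
and eigenvectors carry an arbitrary sign/phase; without it identical
systems can appear maximally distant. Near-defective matrices
(eigenvector condition number ≥ 1e10) fall back to orthogonal real Schur
vectors with a warning.

The distance between two mode sets is
`min_π Σ_i (1 − cos(x_i, y_π(i)))`, computed exactly with the Hungarian
algorithm (`scipy.optimize.linear_sum_assignment`), not greedily; a
brute-force enumeration oracle cross-checks it for ≤ 7 vectors.
Eigenvalues are computed and stored but never enter the distance: all
modes are treated as equally informative. Identification returns the
argmin-distance label with lexicographic tie-breaking and the full
ranking. The evaluation harness takes each run/condition in turn as the
reference database with all other runs as queries, so reference and query
sets are always disjoint.

## Task fingerprinting

`build_signature_graph` uses rows of `R` as node features and
row-normalized `|A|` as the weighted directed adjacency (entry `(i, j)` is
the edge `j → i`; each row of `|A|` is divided by its absolute sum so
incoming influence sums to one; symmetric and max-abs normalizations are
available). The classifier is a five-layer attention network: GATv2 block
(4 heads × 32 features) summed with a 128-channel linear skip, top-k node
pooling at ratio 0.8 (projection score, tanh gate, stable ties to the
lowest node index), a second GATv2 block (2 heads × 32) with a 64-channel
skip, global mean pooling, and a linear log-softmax head (8 classes by
default). Attention logits follow the GATv2 form
`a^T LeakyReLU(W_s x_j + W_t x_i + w_e·adj_ij)`; the scalar edge weight is
consumed as an edge feature by default (configurable). Self-loops always
attend. Attention dropout is 0.30 and 10% of edges are dropped per epoch
during training only; surviving edge weights are not rescaled.

The network runs on a small reverse-mode autodiff engine written for this
package (`causalfp.nn`): dense batched tensors, finite-difference-verified
gradients, and an Adam optimizer. Training minimizes the negative
log-likelihood with Adam (learning rate 1e-3, batch size 32, up to 200
epochs) and early-stops on a 20%-validation split with patience 20,
restoring the best parameters; everything is reproducible from one seed.
Batches assume all graphs share a node count, which holds for cohorts
from a fixed parcellation.

## Reachability landscape

`to_state_evolution_form` folds the concurrent block into the explicit
recursion `x(t) = Âx(t−1) + B̂1u(t) + B̂2u(t−1)` by linear solves. With
`x(0) = 0`, inputs `u(0..T_M−1)` and `u(T_M) ≜ 0` (the input window is
respected; the final scan receives no fresh concurrent drive), the
terminal state is `x(T_M) = Σ_k M_k u(k)` with
`M_k = [k≥1]Â^{T_M−k}B̂1 + Â^{T_M−1−k}B̂2`. Maximizing each entry
decouples by region:

- **energy model** (default): `‖U‖ ≤ 1` as total input energy
  (vectorized ℓ2); the maximum for region `i` is the ℓ2 norm of row `i` of
  `[M_0 … M_{T_M−1}]`, attained by the input sequence aligned with that
  row. This closed form matches the "bounded energy" reading.
- **box model**: `|u| ≤ 1` entrywise, the linear-programming-natural
  reading; the maximum is the row's ℓ1 norm. Box values dominate energy
  values entrywise.

Powers of `Â` are accumulated iteratively, never via eigendecomposition.
Energy values are invariant to orthogonal recombination of the input
channels applied jointly to `B̂1` and `B̂2`.

**Horizon monotonicity is conditional.** When `B̂1 = 0`, a longer horizon
can replay any shorter input schedule shifted one step, so values are
entrywise non-decreasing in `T_M` (tested). With a concurrent channel the
nesting breaks at the first step — `u(0)` acts only through the lagged
gain because `x(0)` is pinned to rest, so extending the horizon perturbs
that boundary block by `Â^{T_M}B̂1`, which can cancel row mass — and the
maximum can genuinely dip as the horizon grows (about three quarters of
random stable test systems show a dip somewhere in `T_M = 1..8`). The
acceptance suite reports the worst observed dip rather than asserting a
monotonicity that does not hold.

`landscape_grid` min-max normalizes (constant vectors map to all ones)
and fills a 12×12 grid row-major in atlas index order, masking unused
cells; a 90-region atlas fills 90 cells and masks 54. The spatial order is
atlas order, not an anatomical embedding — a display choice only.

## Synthetic cohorts

`generate_cohort` emulates a multi-subject, multi-task, two-run study.
One base system is drawn; subjects add perturbations to `A` and `Q`
(scale `subject_spread`), tasks perturb `B1`/`B2` (scale `task_spread`)
and, at half scale, `A`; runs differ by input/noise realizations and — when
`fast_noise_sd > 0` — by run-level perturbations of the fast blocks
`(Q, B1)`, emulating the poorer run-to-run stability of sub-second
interactions relative to slow hemodynamics. Every generated system is
rescaled so `Â` has spectral radius exactly `stability_margin` (default
0.9); the rescaling is scalar on `A`, leaving slow-mode eigenvector
directions untouched. Inputs are iid standard normal (persistently
exciting); measurement noise is iid Gaussian on the state rows.

Defaults: `m = 16`, `n = 4`, `T = 300` scans at `Δt = 0.72` s — deliberately
modest next to a real 100-parcel, 1190-scan acquisition so whole cohorts
identify in seconds; every pipeline stage is dimension-generic and the
suite separately checks the full 90 × 200 signature shape.
`subject_spread = 0.5` and `noise_sd = 0.1` (10% of the O(1) signal scale)
place cross-run subject identifiability in the high-accuracy regime that
well-preprocessed resting recordings exhibit; the feature-mode comparison
uses `fast_noise_sd = 0.3 > noise_sd = 0.05`, i.e. fast-block run
variability well above measurement noise.

What the generator does **not** emulate: hemodynamic convolution,
spatially correlated or temporally autocorrelated noise, scanner drift,
motion artifacts, or non-stationarity within a run. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline under the model's own assumptions, not performance on real BOLD
data.

## Numerical choices

- `(I − Q)` solves fail loudly at condition number 1e12, reporting the
  number.
- Eigenvector canonicalization ties break to the lowest row index;
  assignment and argmax ties to the lowest index / lexicographically
  smallest label.
- Ridge solves use Cholesky-backed `solve` on the Gram matrix
  (`λ = 0` falls back to `lstsq`, i.e. the pseudo-inverse solution).
- Identification warns when `T < 2m + 2n` (under-determined) and when the
  stated-mode solver exhausts its sweep budget.
- Degenerate cases are first-class: `n = 0` gives `m×0` input blocks
  throughout; all-zero adjacency rows produce no edges; constant
  reachability vectors normalize to all ones.

## Known limitations

- The structural `(Q, A)` split is not identifiable from a single run
  (see above); interpret the blocks as signatures, not as estimates of a
  ground-truth concurrent network.
- Least squares with contemporaneous regressors is biased under process
  noise; recovery-style guarantees hold only for the reduced form.
- The classifier trains on CPU-sized problems; very large cohorts or
  parcellations would want a GPU framework.
- The paper-scale accuracies quoted in the README examples are synthetic
  analogs; real-data performance depends on preprocessing and acquisition
  choices outside this package's scope.
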