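# Methods

## The algorithm

`batchlm` fits *n_fits* small datasets, all of the same length and sharing
one model function and one coordinate grid, by running an independent
Levenberg–Marquardt (LM) iteration for every fit, vectorized across the
batch. One cycle per fit:

1. evaluate model values `f(a)` and the analytic Jacobian `J = ∂f/∂a`;
2. build the chi-square χ²(a), its gradient ∇χ² and the Gauss–Newton
   Hessian H (second partial derivatives of the model dropped);
3. damp the Hessian diagonal, `H'_kk = H_kk (1 + λ)`, off-diagonal
   unchanged;
4. solve `H' δ = −∇χ²` by Gauss–Jordan elimination with partial pivoting;
5. evaluate χ² at the trial point `a + δ`: if it decreased, accept the
   step and divide λ by v; otherwise keep `a`, reuse ∇χ² and H, and
   multiply λ by v;
6. declare convergence when `|δ_j| / (r + |a_j|) < ε` for every parameter
   j.

Each fit carries its own λ, iteration counter and terminal state
(`converged`, `max_iterations`, `singular_hessian`,
`invalid_model_value`), so a batch may mix outcomes.

### Estimators

With data `z_n`, model values `f_n`, Jacobian `J_nk`:

| estimator | χ² | ∇χ²_k | H_kl (Gauss–Newton) |
|---|---|---|---|
| `lse` | Σ (f−z)² | 2 Σ (f−z) J_k | 2 Σ J_k J_l |
| `wlse` | Σ ((f−z)/σ_n)² | 2 Σ (f−z) J_k / σ_n² | 2 Σ J_k J_l / σ_n² |
| `mle` | 2[Σ(f−z) − Σ_{z≠0} z ln(f/z)] | 2 Σ (1 − z/f) J_k | 2 Σ (z/f²) J_k J_l |

The `mle` objective is twice the Poisson deviance: the correct
maximum-likelihood objective when the data are counts. Its gradient and
Hessian follow from differentiating the deviance and dropping the
second-derivative terms of the model, exactly parallel to the least-squares
Gauss–Newton approximation; both were validated against central finite
differences of the objective before being wired into the engine. The
leading factor 2 is kept in all three so that χ², ∇χ² and H are mutually
consistent (it cancels inside the LM step).

Model values `f ≤ 0` are outside the Poisson likelihood's domain. They are
not clamped: a fit whose current or trial point produces such values is
terminated with state `invalid_model_value`. Clamping would silently bias
the estimates; for a Gaussian peak on a positive background the domain is
only left when the offset is driven negative, which the caller can detect
from the state code. Under `mle` with a large-amplitude peak on a faint
background a notable fraction of fits can terminate this way when an early
step overshoots the offset; the surviving fits carry no selection bias on
the center parameters (verified against the weighted-least-squares fits of
the identical data).

### Convergence and the damping schedule

Defaults: λ₀ = 10⁻³ and v = 10 (Marquardt's classical choices — the
schedule only needs λ to shrink in the Newton regime and grow fast under
rejection), r = 10⁻³, ε = 10⁻⁵, at most 25 solve/trial cycles per fit.
Every cycle, accepted or rejected, increments the iteration counter; this
makes iteration counts comparable with MINPACK's Jacobian-evaluation count,
which we use as the reference's iteration proxy.

The relative-step test runs on **every** computed δ, accepted or rejected.
For an accepted step this is the usual rule. For a rejected step it is a
termination test: λ has already been inflated until the damped step shrank
below tolerance, so no χ²-decreasing move of relevant size remains — the
iterate is a numerical minimum (MINPACK's `xtol` terminates the same way).
Testing only accepted steps deadlocks in single precision: near the
optimum, χ² improvements fall below the float32 ulp of χ² itself, every
trial is rejected as "not strictly smaller", and the fit would burn its
whole iteration budget despite being converged.

λ is unbounded above; `max_iterations` bounds the loop instead. Rejected
steps reuse ∇χ² and H (only the diagonal damping changes), so a rejected
cycle costs one model evaluation, not two.

### Linear solver

The damped normal equations of all fits are reduced simultaneously: one
Gauss–Jordan elimination to reduced row echelon form on the augmented
matrices, vectorized over the batch. Partial pivoting picks the
largest-magnitude pivot in each column; equal magnitudes resolve to the
lowest row index, making the elimination fully deterministic. A system
whose best pivot falls below `pivot_tol` (default 10⁻¹² in double, 10⁻⁶ in
single precision — near the machine-epsilon scale of each mode) is flagged
singular, its solution NaN-filled, and the fit terminates with
`singular_hessian`.

### Chunking and reproducibility

Batches larger than a memory budget (default 256 MiB of iteration working
set) are processed in contiguous chunks. Every per-fit quantity depends
only on that fit's own row — elementwise arithmetic plus reductions along
the point axis — so results are **bitwise** independent of the chunk
partition and of which other fits share the batch, per precision mode. All
simulation randomness flows from a single integer seed through
`numpy.random.default_rng`; the simulate → fit → report pipeline is
byte-reproducible from one config.

### Precision modes

`double` (default) runs the whole iteration in float64. `single` casts
data, coordinates and all iteration arithmetic to float32, mimicking
GPU-style single-precision fitting. Converged single-precision results
match double precision to ~10⁻⁴ relative at moderate SNR; the modes drift
apart as SNR rises and the attainable χ² contrast falls below float32
resolution.

## Models

Registered at run time behind one contract: `(params (n_fits × n_params),
coords) → (values (n_fits × n_points), jacobian (n_fits × n_points ×
n_params))` with analytic partials. Built-ins:

- `gauss2d` — `A exp(−((x−x₀)² + (y−y₀)²)/(2σ²)) + B`, parameters
  `(A, x₀, y₀, σ, B)`: the isotropic 2D Gaussian-plus-offset used for
  single-molecule spot fitting. Pixel centers at integers 0..s−1, 0-based,
  row-major flattening (point n = row·s + col has y = row, x = col).
- `gauss1d` — the 1D analogue `(A, x₀, σ, B)`, mainly for unit tests.
- `linear` — `slope·x + intercept`; LM is exact in one Newton step for a
  linear model, which pins down the engine's step computation in tests.

Numerical differentiation is deliberately not offered as a production
Jacobian: every registered model must supply analytic partials, which are
cross-checked against central finite differences in the test suite.

## Synthetic data

`make_gauss2d_batch` emulates the standard spot-fitting characterization
protocol: 5×5-pixel (configurable) images of one Gaussian peak, true
center jittered uniformly within ±0.5 px of the grid center, defaults
A = 500, σ = 1 px, B = 10 — typical localization-microscopy scales. Noise
models:

- `gaussian` — additive i.i.d. noise with std `A/SNR`; the SNR is defined
  against the peak amplitude above background.
- `poisson` — each pixel drawn from a Poisson law with mean equal to the
  noise-free model value.
- `none` — noise-free (oracle recovery tests).

Initial guesses perturb the truth: A, σ, B scaled by Uniform(0.9, 1.1),
centers shifted by Uniform(−1, 1) px. All ranges are configurable
(`SimSpec`, `PerturbRule`).

What this generator does **not** emulate: pixel integration of the PSF
(values are sampled at pixel centers, matching the fitted model exactly,
so there is no model-mismatch bias), camera gain/read-noise/EMCCD excess
noise, sCMOS per-pixel variance, emitter blinking, or overlapping spots.
Passing tests therefore demonstrate the correctness of the optimizer and
estimators under the stated noise models — not end-to-end accuracy on real
camera data, where model mismatch dominates.

## Validation experiments

- **Zero-noise recovery**: 100 noise-free fits from ±10% perturbed starts
  recover the truth to < 10⁻⁶ relative.
- **Reference equivalence**: `scipy.optimize.least_squares(method='lm')`
  (the MINPACK lmder wrapper) solves the identical problems from identical
  initials; ≥99% of converged SNR=10 fits agree to 10⁻⁴ relative, and
  median iteration counts differ by ≤1.
- **Accuracy**: at SNR=20, n=10,000, center estimates are unbiased
  (|bias| < 3·SEM) and the engine-vs-MINPACK parameter distributions
  coincide (mean paired difference < 1% of the Monte-Carlo precision).
  Amplitude, width and offset do carry a small *estimator* bias versus
  truth (the ordinary O(noise²) nonlinearity bias, ~0.4% on A at SNR=20);
  it is identical in both optimizers and is not an implementation artifact.
- **Estimator comparison** (Poisson noise, identical data per estimator):
  at A=50 on B=10 the MLE localizes ~7% better than unweighted LSE; at
  A=10⁴ MLE and the √z-weighted LSE agree within 0.5%. The *unweighted*
  LSE stays ~20–30% worse than MLE at any amplitude — the variance ratio is
  scale-invariant under Poisson statistics, so "equivalence at large
  counts" is a statement about the weighted estimator.
- **Precision scaling**: fitted-x₀ std falls monotonically with SNR and
  follows 1/SNR within a few percent over SNR ∈ {5, …, 100}.

Problem sizes in the shipped experiments (10,000-fit Monte-Carlo batches,
1,000-fit reference comparisons, 3,000 fits per SNR point) were chosen so
that each statistical assertion has comfortable power while a full
validation run stays in the seconds-to-minutes range on one CPU core.

## Known limitations

- No box constraints or fixed-parameter masks; out-of-domain excursions
  under `mle` terminate the fit rather than being projected back.
- No mixed Gaussian/Poisson (sCMOS) likelihood.
- Only symmetric Gaussian, 1D Gaussian and linear models are built in;
  elliptical/rotated Gaussians and spline PSFs must be registered by the
  user with analytic partials.
- Spot *detection* is out of scope: ROI extraction requires caller-supplied
  center coordinates.
- Single-precision mode emulates the arithmetic width of GPU fitting, not
  its exact operation order; bitwise agreement with any GPU implementation
  is not expected.
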