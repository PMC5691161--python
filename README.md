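# batchlm

Batched Levenberg–Marquardt curve fitting: fit very large numbers of
*small, same-shaped* datasets to one shared model function, each dataset
with its own starting parameters. The motivating workload is
single-molecule localization microscopy (STORM/PALM), where reconstructing
one image means fitting millions of 5×5- or 7×7-pixel spots to a 2D
Gaussian point-spread function — but the engine is general: any model with
analytic partial derivatives can be registered at run time.

Three goodness-of-fit estimators are built in:

- **LSE** — unweighted least squares, χ² = Σₙ (fₙ(a) − zₙ)²
- **WLSE** — weighted least squares, χ² = Σₙ ((fₙ(a) − zₙ)/σₙ)² with
  per-point standard deviations σₙ
- **MLE** — twice the Poisson deviance,
  χ² = 2[Σₙ (fₙ − zₙ) − Σ_{zₙ≠0} zₙ ln(fₙ/zₙ)],
  the maximum-likelihood objective for photon-counting data, which
  localizes measurably better than least squares at low counts

Each fit runs the classical damped Gauss–Newton iteration: Hessian diagonal
scaled by (1 + λ), normal equations solved by Gauss–Jordan elimination with
partial pivoting, λ divided by v after an accepted step and multiplied by v
after a rejected one, convergence when |δⱼ|/(r + |aⱼ|) < ε for every
parameter. All fits advance in lock-step as vectorized numpy batch
operations; large batches are processed in chunks, and results are bitwise
independent of the chunking and of which other fits share the batch.

## Worked example

```python
from batchlm import BatchedCurveFit, SimSpec

# 1,000 simulated 5x5-pixel spots: amplitude 500 on background 10,
# sigma 1 px, additive Gaussian noise at SNR = 10, randomized starts
model = BatchedCurveFit.from_simulation(
    SimSpec(n_fits=1000, noise="gaussian", snr=10.0, seed=42),
    estimator="lse",
)
res = model.fit()
print(res.summary())
```

```
Batched Levenberg-Marquardt fit
==============================================
model:       gauss2d (5 parameters)
estimator:   lse
fits:        1000 (25 points each)
states:      converged=997, max_iterations=3
iterations:  median 11, max 25

converged-fit parameter estimates:
             mean      std      min     max
amplitude 506.556  41.4591  387.063 648.876
x0        2.00041 0.302968    1.348 2.76308
y0        2.00861 0.299517  1.36079 2.68542
sigma     1.00963 0.110186 0.720681  1.5774
offset    7.26506  26.8402 -137.624 73.9273

chi2 (converged): median 48030.6
```

997 of 1,000 fits converged, in a median of 11 damped-Newton cycles. The
spread of `x0` (0.30 px) mixes the true ±0.5 px center jitter with the fit
error; scoring against the known truth separates them:

```python
print(res.precision_accuracy())
```

```
converged 997/1000 fits; median iterations 11 (IQR 9-13)
parameter      bias  precision      rmse      sem
amplitude  6.556473  41.459052 41.953740 1.313021
       x0  0.003358   0.084691  0.084715 0.002682
       y0 -0.000057   0.081670  0.081629 0.002587
    sigma  0.009630   0.110186  0.110551 0.003490
   offset -2.734945  26.840245 26.965833 0.850039
```

At SNR = 10 the spot centers are localized to 0.085 px (one standard
deviation) with no meaningful bias; amplitude and offset show the small
O(noise²) bias inherent to nonlinear least squares.

The same engine is exposed functionally (`batchlm.fit`,
`batchlm.fit_arrays`) and as a CLI pipeline:

```bash
batchlm simulate --config sim.yaml --out batch.h5
batchlm fit --in batch.h5 --model gauss2d --estimator mle --out results.csv
batchlm extract --stack movie.tif --rois rois.csv --size 7 --out batch.h5
batchlm report --results results.csv --truth batch.truth.csv --out report/
```

`extract` cuts square ROI patches around given spot centers out of a TIFF
stack and auto-estimates starting parameters (offset = patch minimum,
amplitude = max − min, center = intensity centroid, σ = s/4).

See `docs/methods.md` for the algorithm, estimator formulas, conventions
and limitations.

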