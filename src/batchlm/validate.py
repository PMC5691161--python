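"""Validation experiments: precision/accuracy, estimator comparison,
reference-optimizer equivalence.

These routines reproduce the standard characterization protocol for a spot
fitter: fit large simulated batches with known ground truth, report the
per-parameter bias (accuracy), the standard deviation of the error
(precision) and the RMSE, compare the Poisson-MLE and least-squares
estimators on identical data, and check the engine head-to-head against an
established trust-region/Levenberg-Marquardt reference
(`scipy.optimize.least_squares`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .engine import FitBatch, FitConfig, FitResult, FitState, fit
from .models import ModelSpec, get_model
from .simulate import SimSpec, SimTruth, make_gauss2d_batch

__all__ = [
    "PrecisionReport",
    "precision_accuracy",
    "compare_estimators",
    "reference_equivalence",
    "reference_fit",
]


@dataclass
class PrecisionReport:
    """Per-parameter accuracy/precision statistics for one fitted batch.

    ``bias`` is the mean of (fitted - true), ``precision`` the standard
    deviation of that error and ``rmse`` the root-mean-square error, each a
    vector over parameters. Only converged fits enter the statistics;
    ``state_counts`` reports everything.
    """

    param_names: tuple[str, ...]
    bias: np.ndarray
    precision: np.ndarray
    rmse: np.ndarray
    n_converged: int
    n_total: int
    state_counts: dict[str, int]
    iteration_median: float
    iteration_iqr: tuple[float, float]

    @property
    def sem(self) -> np.ndarray:
        """Standard error of the per-parameter bias estimate."""
        if self.n_converged == 0:
            return np.full_like(self.bias, np.nan)
        return self.precision / np.sqrt(self.n_converged)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.param_names),
                "bias": self.bias,
                "precision": self.precision,
                "rmse": self.rmse,
                "sem": self.sem,
            }
        )

    def __str__(self) -> str:
        lines = [
            f"converged {self.n_converged}/{self.n_total} fits; "
            f"median iterations {self.iteration_median:.0f} "
            f"(IQR {self.iteration_iqr[0]:.0f}-{self.iteration_iqr[1]:.0f})",
            self.to_dataframe().to_string(index=False),
        ]
        return "\n".join(lines)


def precision_accuracy(
    results: FitResult,
    truth: SimTruth,
    param_names: tuple[str, ...] | None = None,
) -> PrecisionReport:
    """Accuracy (bias) and precision (error spread) against ground truth.

    Errors are fitted minus true, per parameter, over converged fits only.
    """
    true_params = np.asarray(truth.true_params)
    if results.n_fits != true_params.shape[0]:
        raise ValueError("results and truth are not aligned")
    if param_names is None:
        param_names = get_model("gauss2d").param_names \
            if true_params.shape[1] == 5 else tuple(
                f"p{k}" for k in range(true_params.shape[1]))
    conv = results.converged
    err = results.params[conv] - true_params[conv]
    if err.shape[0] > 0:
        bias = err.mean(axis=0)
        precision = err.std(axis=0, ddof=1) if err.shape[0] > 1 else np.zeros(err.shape[1])
        rmse = np.sqrt(np.mean(err * err, axis=0))
    else:
        bias = precision = rmse = np.full(true_params.shape[1], np.nan)
    iters = results.n_iterations
    return PrecisionReport(
        param_names=tuple(param_names),
        bias=bias,
        precision=precision,
        rmse=rmse,
        n_converged=int(conv.sum()),
        n_total=results.n_fits,
        state_counts=results.state_counts(),
        iteration_median=float(np.median(iters)),
        iteration_iqr=(
            float(np.percentile(iters, 25)),
            float(np.percentile(iters, 75)),
        ),
    )


def compare_estimators(
    spec: SimSpec,
    estimators: list[str] = ["lse", "mle"],
    config: FitConfig | None = None,
) -> dict[str, PrecisionReport]:
    """Fit one simulated batch with several estimators on identical data.

    The batch (data, truth and initial guesses) is generated once; each
    estimator then fits exactly the same inputs, so precision differences
    reflect the estimator alone. With Poisson noise, weighted least squares
    uses sqrt(max(data, 1)) as the per-point standard deviation.
    """
    base = config or FitConfig()
    batch, truth = make_gauss2d_batch(spec)
    reports: dict[str, PrecisionReport] = {}
    for est in estimators:
        b = batch
        if est == "wlse":
            sigma = np.sqrt(np.maximum(batch.data, 1.0))
            b = FitBatch(
                data=batch.data,
                initial_params=batch.initial_params,
                coords=batch.coords,
                sigma=sigma,
            )
        cfg = FitConfig(**{**base.__dict__, "estimator": est})
        res = fit(b, "gauss2d", cfg)
        reports[est] = precision_accuracy(res, truth)
    return reports


def reference_fit(
    batch: FitBatch,
    model: str | ModelSpec,
    sigma: np.ndarray | None = None,
    **ls_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit each dataset with scipy's trust-region least-squares reference.

    Solves the identical (weighted) least-squares problem from identical
    initial guesses, one fit at a time, using the analytic Jacobian.
    Returns ``(params, n_jacobian_evaluations)``; the Jacobian-evaluation
    count is the closest available analogue of an iteration count.
    """
    spec = model if isinstance(model, ModelSpec) else get_model(model)
    coords = batch.resolved_coords(spec)
    params = np.empty_like(batch.initial_params)
    njev = np.zeros(batch.n_fits, dtype=int)
    opts = dict(method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    opts.update(ls_kwargs)
    for i in range(batch.n_fits):
        z = batch.data[i]
        w = None if sigma is None else 1.0 / sigma[i]

        def residual(a):
            v, _ = spec.eval(a[None, :], coords, check=False)
            r = v[0] - z
            return r if w is None else r * w

        def jacobian(a):
            _, j = spec.eval(a[None, :], coords, check=False)
            return j[0] if w is None else j[0] * w[:, None]

        sol = least_squares(
            residual, batch.initial_params[i], jac=jacobian, **opts
        )
        params[i] = sol.x
        njev[i] = sol.njev if sol.njev is not None else sol.nfev
    return params, njev


def reference_equivalence(
    batch: FitBatch,
    model: str | ModelSpec = "gauss2d",
    config: FitConfig | None = None,
    rel_tol: float = 1e-4,
    **ls_kwargs,
) -> dict:
    """Head-to-head agreement between the batch engine and the reference.

    Both optimizers solve the identical least-squares problem from identical
    initials. Reports the per-fit maximum relative parameter difference, the
    fraction of converged fits agreeing within ``rel_tol``, and median
    iteration counts for both.
    """
    config = config or FitConfig()
    res = fit(batch, model, config)
    ref_params, ref_iters = reference_fit(batch, model, sigma=batch.sigma,
                                          **ls_kwargs)
    denom = np.maximum(np.abs(ref_params), 1e-12)
    rel_diff = np.max(np.abs(res.params - ref_params) / denom, axis=1)
    conv = res.converged
    agree = rel_diff[conv] < rel_tol
    return {
        "rel_diff": rel_diff,
        "fraction_within_tol": float(agree.mean()) if conv.any() else 0.0,
        "n_converged": int(conv.sum()),
        "n_total": res.n_fits,
        "median_iterations": float(np.median(res.n_iterations)),
        "median_iterations_reference": float(np.median(ref_iters)),
        "results": res,
        "reference_params": ref_params,
    }
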