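"""Model/Results front-end for batched curve fitting.

:class:`BatchedCurveFit` is constructed from the data (plus initial
guesses), holds the model choice and estimator, and its :meth:`fit` returns
a :class:`BatchedCurveFitResults` carrying the estimates, termination
states, chi-square values and iteration counts, with a ``summary()`` table
in the style of statistical modelling packages.

    >>> model = BatchedCurveFit(data, initial_params, model="gauss2d")
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import FitBatch, FitConfig, FitResult, FitState, fit as _fit
from .models import get_model
from .simulate import SimSpec, SimTruth, make_gauss2d_batch
from .validate import PrecisionReport, precision_accuracy

__all__ = ["BatchedCurveFit", "BatchedCurveFitResults"]


class BatchedCurveFit:
    """Batched nonlinear curve-fitting model.

    Parameters
    ----------
    data : (n_fits, n_points) array
        One dataset per row; all fits share the model and data size.
    initial_params : (n_fits, n_params) array
        Unique starting parameters for each fit.
    model : str or ModelSpec
        Registered model id ('gauss2d', 'gauss1d', 'linear') or a spec.
    coords : tuple of arrays, optional
        Shared coordinate grid; defaults to the model's canonical grid
        (integer pixel centers, row-major for 2D).
    sigma : (n_fits, n_points) array, optional
        Per-point standard deviations for weighted least squares.
    estimator : {'lse', 'wlse', 'mle'}
    """

    def __init__(
        self,
        data,
        initial_params,
        model="gauss2d",
        coords=None,
        sigma=None,
        estimator="lse",
        truth: SimTruth | None = None,
    ):
        self.model_spec = model if not isinstance(model, str) else get_model(model)
        self.batch = FitBatch(
            data=data, initial_params=initial_params, coords=coords, sigma=sigma
        )
        self.batch.validate_for(self.model_spec)
        self.estimator = estimator
        self.truth = truth

    @classmethod
    def from_simulation(cls, spec: SimSpec, estimator="lse") -> "BatchedCurveFit":
        """Build the model from a synthetic batch; keeps the ground truth."""
        batch, truth = make_gauss2d_batch(spec)
        obj = cls.__new__(cls)
        obj.model_spec = get_model("gauss2d")
        obj.batch = batch
        obj.estimator = estimator
        obj.truth = truth
        return obj

    @property
    def n_fits(self) -> int:
        return self.batch.n_fits

    def fit(self, config: FitConfig | None = None, **overrides
            ) -> "BatchedCurveFitResults":
        """Run the batched Levenberg-Marquardt iteration.

        Keyword overrides (e.g. ``max_iterations=50``, ``conv_eps=1e-8``)
        update the default :class:`FitConfig`; ``estimator`` defaults to the
        model's choice.
        """
        if config is None:
            overrides.setdefault("estimator", self.estimator)
            config = FitConfig(**overrides)
        raw = _fit(self.batch, self.model_spec, config)
        return BatchedCurveFitResults(self, raw, config)


class BatchedCurveFitResults:
    """Estimates and diagnostics from a batched fit."""

    def __init__(self, model: BatchedCurveFit, raw: FitResult, config: FitConfig):
        self.model = model
        self.raw = raw
        self.config = config

    params = property(lambda self: self.raw.params)
    states = property(lambda self: self.raw.states)
    chi2 = property(lambda self: self.raw.chi2)
    n_iterations = property(lambda self: self.raw.n_iterations)
    converged = property(lambda self: self.raw.converged)

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.model.model_spec.param_names

    def to_dataframe(self) -> pd.DataFrame:
        from .io import results_frame

        return results_frame(self.raw, self.param_names)

    def precision_accuracy(self, truth: SimTruth | None = None) -> PrecisionReport:
        """Bias/precision report against ground truth (simulated batches)."""
        truth = truth or self.model.truth
        if truth is None:
            raise ValueError("no ground truth attached to this model")
        return precision_accuracy(self.raw, truth, self.param_names)

    def summary(self) -> str:
        """Human-readable run summary: states, iterations, estimates."""
        counts = self.raw.state_counts()
        conv = self.converged
        lines = [
            "Batched Levenberg-Marquardt fit",
            "=" * 46,
            f"model:       {self.model.model_spec.model_id}"
            f" ({self.model.model_spec.n_params} parameters)",
            f"estimator:   {self.config.estimator}",
            f"fits:        {self.raw.n_fits}"
            f" ({self.model.batch.n_points} points each)",
            f"states:      " + ", ".join(f"{k}={v}" for k, v in counts.items()),
            f"iterations:  median {np.median(self.n_iterations):.0f}, "
            f"max {self.n_iterations.max()}",
        ]
        if conv.any():
            est = self.params[conv]
            chi2 = self.chi2[conv]
            table = pd.DataFrame(
                {
                    "mean": est.mean(axis=0),
                    "std": est.std(axis=0, ddof=1) if conv.sum() > 1 else 0.0,
                    "min": est.min(axis=0),
                    "max": est.max(axis=0),
                },
                index=list(self.param_names),
            )
            lines += [
                "",
                "converged-fit parameter estimates:",
                table.to_string(float_format=lambda v: f"{v:.6g}"),
                "",
                f"chi2 (converged): median {np.median(chi2):.6g}",
            ]
        return "\n".join(lines)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")
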