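"""The batched Levenberg-Marquardt engine.

Runs the full damped Gauss-Newton iteration independently for every fit in a
batch: build the gradient and Gauss-Newton Hessian of the chosen chi-square,
damp the Hessian diagonal by (1 + lambda), solve the normal equations by
Gauss-Jordan elimination, evaluate the trial chi-square, and accept or
reject. On acceptance lambda shrinks by the factor v and convergence is
tested on the accepted step; on rejection the parameters stay put, the
gradient and Hessian are reused, and lambda grows by v. Each fit carries its
own lambda, iteration counter and terminal state, so one batch may contain
converged, still-running and failed fits at the same time.

Large batches are processed in chunks. Chunking is purely an execution
detail: every per-fit quantity depends only on that fit's own row, so
results are bitwise identical for any chunk partition (in a fixed precision
mode) and are unaffected by which other fits share the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .estimators import ESTIMATORS, gradient_hessian, mle_invalid_mask
from .models import Coords, ModelSpec, get_model
from .solver import DEFAULT_PIVOT_TOL, gauss_jordan_solve

__all__ = [
    "FitConfig",
    "FitBatch",
    "FitResult",
    "FitState",
    "fit",
    "fit_arrays",
    "damp_hessian",
    "check_convergence",
    "plan_chunks",
]

logger = logging.getLogger("batchlm")


class FitState:
    """Integer termination codes, one per fit."""

    CONVERGED = 0
    MAX_ITERATIONS = 1
    SINGULAR_HESSIAN = 2
    INVALID_MODEL_VALUE = 3

    NAMES = {
        CONVERGED: "converged",
        MAX_ITERATIONS: "max_iterations",
        SINGULAR_HESSIAN: "singular_hessian",
        INVALID_MODEL_VALUE: "invalid_model_value",
    }

    @classmethod
    def to_names(cls, states: np.ndarray) -> np.ndarray:
        return np.array([cls.NAMES[int(s)] for s in np.asarray(states).ravel()])


@dataclass(frozen=True)
class FitConfig:
    """Estimator choice and all Levenberg-Marquardt tuning constants.

    Parameters
    ----------
    estimator : {'lse', 'wlse', 'mle'}
    lambda_init : float
        Initial damping factor lambda; small values start the iteration in
        the Newton regime.
    lambda_factor : float
        The constant factor v (> 1) by which lambda is decreased after an
        accepted step and increased after a rejected one.
    conv_r : float
        The small positive constant r in the convergence test
        |delta_j| / (r + |a_j|) < eps (guards against division by zero).
    conv_eps : float
        The convergence threshold eps.
    max_iterations : int
        Upper bound on solve/trial cycles per fit (accepted or rejected).
    chunk_size : int or 'auto'
        Number of fits processed per pass; 'auto' bounds the working set by
        ``chunk_memory_budget`` bytes.
    precision_mode : {'double', 'single'}
        Floating-point width of the iteration arithmetic.
    pivot_tol : float or None
        Singularity threshold for the linear solver; None picks the default
        for the precision mode.
    chunk_memory_budget : int
        Approximate bytes of Jacobian storage allowed per chunk in 'auto'.
    """

    estimator: str = "lse"
    lambda_init: float = 1e-3
    lambda_factor: float = 10.0
    conv_r: float = 1e-3
    conv_eps: float = 1e-5
    max_iterations: int = 25
    chunk_size: int | str = "auto"
    precision_mode: str = "double"
    pivot_tol: float | None = None
    chunk_memory_budget: int = 256 * 2**20

    def __post_init__(self):
        if self.estimator not in ESTIMATORS:
            raise ValueError(
                f"unknown estimator '{self.estimator}'; choose from {ESTIMATORS}"
            )
        if not self.lambda_factor > 1:
            raise ValueError("lambda_factor v must be > 1")
        if not self.conv_r > 0:
            raise ValueError("conv_r must be > 0")
        if not self.conv_eps > 0:
            raise ValueError("conv_eps must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.precision_mode not in ("double", "single"):
            raise ValueError("precision_mode must be 'double' or 'single'")
        if self.chunk_size != "auto" and int(self.chunk_size) < 1:
            raise ValueError("chunk_size must be >= 1 or 'auto'")

    @property
    def dtype(self):
        return np.float64 if self.precision_mode == "double" else np.float32

    @property
    def effective_pivot_tol(self) -> float:
        if self.pivot_tol is not None:
            return self.pivot_tol
        return DEFAULT_PIVOT_TOL[self.precision_mode]


@dataclass
class FitBatch:
    """Many same-shaped datasets destined for one shared model function.

    ``data`` is ``(n_fits, n_points)``, ``initial_params`` is
    ``(n_fits, n_params)`` — one starting vector per fit — and ``coords``
    is the single coordinate grid shared by every fit. ``sigma`` holds
    optional per-point standard deviations for weighted least squares.
    """

    data: np.ndarray
    initial_params: np.ndarray
    coords: Coords | None = None
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.initial_params = np.atleast_2d(
            np.asarray(self.initial_params, dtype=float)
        )
        if self.initial_params.shape[0] != self.data.shape[0]:
            raise ValueError(
                f"initial_params has {self.initial_params.shape[0]} rows but "
                f"data has {self.data.shape[0]} fits"
            )
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.data.shape:
                raise ValueError(
                    f"sigma shape {self.sigma.shape} != data shape {self.data.shape}"
                )
        if self.coords is not None:
            self.coords = tuple(np.asarray(c, dtype=float) for c in self.coords)
            for c in self.coords:
                if c.shape != (self.data.shape[1],):
                    raise ValueError(
                        "each coordinate array must have length n_points"
                    )

    @property
    def n_fits(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]

    def validate_for(self, model: ModelSpec) -> None:
        if self.initial_params.shape[1] != model.n_params:
            raise ValueError(
                f"model '{model.model_id}' expects {model.n_params} parameters, "
                f"got {self.initial_params.shape[1]}"
            )
        if self.n_points < model.n_params:
            raise ValueError(
                f"underdetermined batch: n_points={self.n_points} < "
                f"n_params={model.n_params}"
            )

    def resolved_coords(self, model: ModelSpec) -> Coords:
        if self.coords is not None:
            return self.coords
        return model.default_coords(self.n_points)


@dataclass
class FitResult:
    """Per-fit outcome of a batched Levenberg-Marquardt run."""

    params: np.ndarray
    states: np.ndarray
    chi2: np.ndarray
    n_iterations: np.ndarray

    @property
    def n_fits(self) -> int:
        return self.params.shape[0]

    @property
    def converged(self) -> np.ndarray:
        return self.states == FitState.CONVERGED

    def state_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.states == code))
            for code, name in FitState.NAMES.items()
            if np.any(self.states == code)
        }


def damp_hessian(hessian: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Multiply the Hessian diagonal by (1 + lambda), per fit.

    Off-diagonal elements are untouched; ``lam`` broadcasts over the batch.
    """
    hessian = np.asarray(hessian)
    lam = np.asarray(lam, dtype=hessian.dtype)
    damped = hessian.copy()
    p = hessian.shape[-1]
    diag = np.arange(p)
    damped[..., diag, diag] *= 1.0 + lam[..., None]
    return damped


def check_convergence(
    delta: np.ndarray, params: np.ndarray, r: float, eps: float
) -> np.ndarray:
    """True per fit iff |delta_j| / (r + |a_j|) < eps for ALL parameters j."""
    if not (r > 0 and eps > 0):
        raise ValueError("r and eps must be positive")
    ratio = np.abs(delta) / (r + np.abs(params))
    return np.all(ratio < eps, axis=-1)


def plan_chunks(n_fits: int, chunk_size: int | str, *, bytes_per_fit: int = 0,
                memory_budget: int = 256 * 2**20) -> list[tuple[int, int]]:
    """Contiguous, disjoint index ranges covering 0..n_fits exactly once.

    'auto' sizes chunks so the per-chunk working set stays within the
    memory budget.
    """
    if n_fits < 1:
        return []
    if chunk_size == "auto":
        if bytes_per_fit <= 0:
            size = n_fits
        else:
            size = max(1, min(n_fits, memory_budget // bytes_per_fit))
    else:
        size = int(chunk_size)
        if size < 1:
            raise ValueError("chunk_size must be >= 1")
    starts = range(0, n_fits, size)
    return [(s, min(s + size, n_fits)) for s in starts]


def _objective(model, params, coords, data, sigma, estimator, dtype):
    """Evaluate chi2 / gradient / Hessian plus per-fit validity at params."""
    values, jac = model.eval(params, coords, check=False)
    values = values.astype(dtype, copy=False)
    jac = jac.astype(dtype, copy=False)
    ev = gradient_hessian(values, jac, data, estimator, sigma)
    if estimator == "mle":
        invalid = mle_invalid_mask(values)
    else:
        invalid = ~np.isfinite(ev.chi2)
    return ev, invalid


def _fit_chunk(
    model: ModelSpec,
    data: np.ndarray,
    coords: Coords,
    sigma: np.ndarray | None,
    initial: np.ndarray,
    config: FitConfig,
) -> FitResult:
    dtype = config.dtype
    n, p = initial.shape
    data = data.astype(dtype, copy=False)
    if sigma is not None:
        sigma = sigma.astype(dtype, copy=False)
    coords = tuple(c.astype(dtype, copy=False) for c in coords)
    params = initial.astype(dtype, copy=True)
    lam = np.full(n, config.lambda_init, dtype=dtype)
    v = dtype(config.lambda_factor)
    n_iter = np.zeros(n, dtype=np.int64)
    states = np.full(n, -1, dtype=np.int64)

    ev, invalid = _objective(
        model, params, coords, data, sigma, config.estimator, dtype
    )
    chi2 = ev.chi2.copy()
    grad = ev.gradient
    hess = ev.hessian
    states[invalid] = FitState.INVALID_MODEL_VALUE
    active = states < 0

    while np.any(active):
        act = np.flatnonzero(active)
        h_damped = damp_hessian(hess[act], lam[act])
        delta, sing = gauss_jordan_solve(
            h_damped, -grad[act], config.effective_pivot_tol
        )
        n_iter[act] += 1

        # Singular normal equations are terminal for the affected fits.
        sing_idx = act[sing]
        states[sing_idx] = FitState.SINGULAR_HESSIAN
        ok = act[~sing]
        if ok.size == 0:
            active = states < 0
            continue
        delta = delta[~sing]

        trial = params[ok] + delta
        trial_ev, trial_invalid = _objective(
            model, trial, coords, data[ok],
            None if sigma is None else sigma[ok],
            config.estimator, dtype,
        )
        # A trial point outside the estimator's domain (f <= 0 under the
        # Poisson likelihood) terminates that fit.
        inv_idx = ok[trial_invalid]
        states[inv_idx] = FitState.INVALID_MODEL_VALUE
        valid = ~trial_invalid
        ok = ok[valid]
        if ok.size:
            delta_v = delta[valid]
            trial_chi2 = trial_ev.chi2[valid]
            with np.errstate(invalid="ignore"):
                accept = trial_chi2 < chi2[ok]
            acc = ok[accept]
            rej = ok[~accept]
            if acc.size:
                sel = np.flatnonzero(valid)[accept]
                params[acc] = trial[sel]
                chi2[acc] = trial_ev.chi2[sel]
                grad[acc] = trial_ev.gradient[sel]
                hess[acc] = trial_ev.hessian[sel]
                lam[acc] = lam[acc] / v
            if rej.size:
                lam[rej] = lam[rej] * v
            # The step-size test runs on every computed delta, accepted or
            # rejected: a rejected step that is already below tolerance
            # means no within-tolerance descent remains (lambda has damped
            # the step to nothing), which is a numerical minimum.
            conv = check_convergence(
                delta_v, params[ok], config.conv_r, config.conv_eps
            )
            states[ok[conv]] = FitState.CONVERGED

        exhausted = (states < 0) & (n_iter >= config.max_iterations)
        states[exhausted] = FitState.MAX_ITERATIONS
        active = states < 0

    return FitResult(
        params=params,
        states=states,
        chi2=chi2,
        n_iterations=n_iter,
    )


def fit(
    batch: FitBatch,
    model_id: str | ModelSpec,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit every dataset in the batch to the shared model function.

    Iterates the damped Gauss-Newton cycle per fit until convergence,
    failure, or ``max_iterations``. Results are independent of the chunk
    partition and of which other fits share the batch.
    """
    config = config or FitConfig()
    model = model_id if isinstance(model_id, ModelSpec) else get_model(model_id)
    batch.validate_for(model)
    if config.estimator == "wlse" and batch.sigma is None:
        raise ValueError("estimator 'wlse' requires batch.sigma")
    if config.estimator == "mle" and np.any(batch.data < 0):
        raise ValueError("estimator 'mle' requires non-negative data")
    coords = batch.resolved_coords(model)

    itemsize = np.dtype(config.dtype).itemsize
    bytes_per_fit = batch.n_points * (model.n_params + 2) * itemsize * 3
    chunks = plan_chunks(
        batch.n_fits,
        config.chunk_size,
        bytes_per_fit=bytes_per_fit,
        memory_budget=config.chunk_memory_budget,
    )
    results = []
    for lo, hi in chunks:
        logger.debug("fitting chunk [%d:%d)", lo, hi)
        results.append(
            _fit_chunk(
                model,
                batch.data[lo:hi],
                coords,
                None if batch.sigma is None else batch.sigma[lo:hi],
                batch.initial_params[lo:hi],
                config,
            )
        )
    out = FitResult(
        params=np.concatenate([r.params for r in results]),
        states=np.concatenate([r.states for r in results]),
        chi2=np.concatenate([r.chi2 for r in results]),
        n_iterations=np.concatenate([r.n_iterations for r in results]),
    )
    counts = out.state_counts()
    logger.info(
        "fit complete: %d fits, states %s, median iterations %.0f",
        out.n_fits, counts, float(np.median(out.n_iterations)),
    )
    return out


def fit_arrays(
    data: np.ndarray,
    weights: np.ndarray | None,
    model_id: str,
    initial_params: np.ndarray,
    tolerance: float = 1e-5,
    max_iterations: int = 25,
    estimator_id: str = "lse",
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flat array-in / array-out entry point.

    ``weights`` are per-point standard deviations (used when
    ``estimator_id='wlse'``). Returns ``(params, states, chi2, n_iterations)``
    with integer state codes (see :class:`FitState`).
    """
    batch = FitBatch(data=data, initial_params=initial_params, sigma=weights)
    config = FitConfig(
        estimator=estimator_id,
        conv_eps=tolerance,
        max_iterations=max_iterations,
        **kwargs,
    )
    res = fit(batch, model_id, config)
    return res.params, res.states, res.chi2, res.n_iterations
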