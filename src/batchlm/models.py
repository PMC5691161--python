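"""Fit model functions with analytic Jacobians, evaluated batch-wise.

Every model follows one contract: given a parameter matrix of shape
``(n_fits, n_params)`` and a coordinate grid of ``n_points`` points, it
returns the model values ``(n_fits, n_points)`` and the Jacobian
``(n_fits, n_points, n_params)`` whose column *k* is the analytic partial
derivative with respect to parameter *k*.

Coordinate conventions are fixed once and documented here: pixel centers sit
at the integers ``0 .. s-1`` on each axis, 0-based, and 2D grids are
flattened row-major (the point index runs fastest over columns / x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "InvalidParameterError",
    "get_model",
    "register_model",
    "available_models",
    "square_grid",
]


class InvalidParameterError(ValueError):
    """A parameter vector violates a model precondition (e.g. sigma <= 0)."""

    def __init__(self, message: str, fit_indices: np.ndarray | None = None):
        super().__init__(message)
        self.fit_indices = fit_indices


Coords = tuple[np.ndarray, ...]


@dataclass(frozen=True)
class ModelSpec:
    """A registered model function and its analytic derivatives.

    Parameters
    ----------
    model_id : str
        Registry key, also the CLI string for this model.
    n_params : int
        Length of one parameter vector.
    dimensionality : int
        1 for curves on a 1D axis, 2 for images on a pixel grid.
    param_names : tuple of str
        Names in parameter-vector order; used for result tables.
    eval_fn : callable
        ``eval_fn(params, coords, check) -> (values, jacobian)``.
    default_coords_fn : callable or None
        Builds a default coordinate grid from ``n_points`` when the caller
        supplies none (square grid for 2D models, 0..n-1 for 1D).
    """

    model_id: str
    n_params: int
    dimensionality: int
    param_names: tuple[str, ...]
    eval_fn: Callable[..., tuple[np.ndarray, np.ndarray]] = field(repr=False)
    default_coords_fn: Callable[[int], Coords] | None = field(
        default=None, repr=False
    )

    def eval(
        self,
        params: np.ndarray,
        coords: Coords,
        check: bool = True,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate values and Jacobian for a whole batch of parameter vectors.

        ``check=False`` skips precondition validation; the fit engine uses it
        for trial points, where out-of-domain parameters are handled by the
        accept/reject logic rather than by raising.
        """
        params = np.atleast_2d(np.asarray(params))
        if params.shape[1] != self.n_params:
            raise ValueError(
                f"model '{self.model_id}' expects {self.n_params} parameters, "
                f"got {params.shape[1]}"
            )
        return self.eval_fn(params, coords, check)

    def default_coords(self, n_points: int) -> Coords:
        if self.default_coords_fn is None:
            raise ValueError(f"model '{self.model_id}' has no default grid")
        return self.default_coords_fn(n_points)


def square_grid(side: int) -> Coords:
    """Row-major flattened integer pixel grid of a ``side x side`` image.

    Returns ``(x, y)`` with ``x`` varying fastest, i.e. point
    ``n = row * side + col`` has ``y = row`` and ``x = col``.
    """
    y, x = np.mgrid[0:side, 0:side]
    return x.ravel().astype(float), y.ravel().astype(float)


def _square_from_npoints(n_points: int) -> Coords:
    side = int(round(np.sqrt(n_points)))
    if side * side != n_points:
        raise ValueError(
            f"cannot infer a square grid from n_points={n_points}; "
            "pass coordinates explicitly"
        )
    return square_grid(side)


def _line_from_npoints(n_points: int) -> Coords:
    return (np.arange(n_points, dtype=float),)


def _eval_gauss2d(
    params: np.ndarray, coords: Coords, check: bool
) -> tuple[np.ndarray, np.ndarray]:
    x, y = coords
    amp = params[:, 0:1]
    x0 = params[:, 1:2]
    y0 = params[:, 2:3]
    sig = params[:, 3:4]
    off = params[:, 4:5]
    if check:
        bad = np.flatnonzero(params[:, 3] <= 0)
        if bad.size:
            raise InvalidParameterError(
                f"gauss2d requires sigma > 0; violated by fit indices "
                f"{bad.tolist()}",
                fit_indices=bad,
            )
    dx = x[None, :] - x0
    dy = y[None, :] - y0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        inv_s2 = 1.0 / (sig * sig)
        expo = np.exp(-0.5 * (dx * dx + dy * dy) * inv_s2)
        values = amp * expo + off
        jac = np.empty(values.shape + (5,), dtype=values.dtype)
        jac[..., 0] = expo
        jac[..., 1] = amp * expo * dx * inv_s2
        jac[..., 2] = amp * expo * dy * inv_s2
        jac[..., 3] = amp * expo * (dx * dx + dy * dy) / (sig**3)
        jac[..., 4] = 1.0
    return values, jac


def _eval_gauss1d(
    params: np.ndarray, coords: Coords, check: bool
) -> tuple[np.ndarray, np.ndarray]:
    (x,) = coords
    amp = params[:, 0:1]
    x0 = params[:, 1:2]
    sig = params[:, 2:3]
    off = params[:, 3:4]
    if check:
        bad = np.flatnonzero(params[:, 2] <= 0)
        if bad.size:
            raise InvalidParameterError(
                f"gauss1d requires sigma > 0; violated by fit indices "
                f"{bad.tolist()}",
                fit_indices=bad,
            )
    dx = x[None, :] - x0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        inv_s2 = 1.0 / (sig * sig)
        expo = np.exp(-0.5 * dx * dx * inv_s2)
        values = amp * expo + off
        jac = np.empty(values.shape + (4,), dtype=values.dtype)
        jac[..., 0] = expo
        jac[..., 1] = amp * expo * dx * inv_s2
        jac[..., 2] = amp * expo * dx * dx / (sig**3)
        jac[..., 3] = 1.0
    return values, jac


def _eval_linear(
    params: np.ndarray, coords: Coords, check: bool
) -> tuple[np.ndarray, np.ndarray]:
    (x,) = coords
    slope = params[:, 0:1]
    intercept = params[:, 1:2]
    values = slope * x[None, :] + intercept
    jac = np.empty(values.shape + (2,), dtype=values.dtype)
    jac[..., 0] = x[None, :]
    jac[..., 1] = 1.0
    return values, jac


_REGISTRY: dict[str, ModelSpec] = {}


def register_model(spec: ModelSpec) -> None:
    """Register a model at run time; models are not compiled in."""
    _REGISTRY[spec.model_id] = spec


def available_models() -> Sequence[str]:
    return sorted(_REGISTRY)


def get_model(model_id: str) -> ModelSpec:
    """Look up a registered model by id; unknown ids list the valid ones."""
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model '{model_id}'; available models: "
            f"{', '.join(available_models())}"
        ) from None


register_model(
    ModelSpec(
        model_id="gauss2d",
        n_params=5,
        dimensionality=2,
        param_names=("amplitude", "x0", "y0", "sigma", "offset"),
        eval_fn=_eval_gauss2d,
        default_coords_fn=_square_from_npoints,
    )
)
register_model(
    ModelSpec(
        model_id="gauss1d",
        n_params=4,
        dimensionality=1,
        param_names=("amplitude", "x0", "sigma", "offset"),
        eval_fn=_eval_gauss1d,
        default_coords_fn=_line_from_npoints,
    )
)
register_model(
    ModelSpec(
        model_id="linear",
        n_params=2,
        dimensionality=1,
        param_names=("slope", "intercept"),
        eval_fn=_eval_linear,
        default_coords_fn=_line_from_npoints,
    )
)
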