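"""Goodness-of-fit estimators: chi-square values, gradients and Hessians.

Three estimators are supported, selected by the strings ``lse``, ``wlse``
and ``mle``:

* ``lse`` — unweighted least squares, chi2 = sum (f_n - z_n)^2
* ``wlse`` — weighted least squares with per-point standard deviations
  sigma_n, chi2 = sum ((f_n - z_n) / sigma_n)^2
* ``mle`` — twice the Poisson deviance,
  chi2 = 2 [ sum (f_n - z_n) - sum_{z_n != 0} z_n ln(f_n / z_n) ],
  the maximum-likelihood objective for Poisson-distributed counts.

Gradients and Hessians are those of the chi-square with second partial
derivatives of the model dropped (the Gauss-Newton approximation):

* LSE:  grad_k = 2 sum (f-z) J_k,          H_kl = 2 sum J_k J_l
* WLSE: the same sums with 1/sigma^2 inside both
* MLE:  grad_k = 2 sum (1 - z/f) J_k,      H_kl = 2 sum (z/f^2) J_k J_l

The leading factor 2 is kept everywhere so the gradient and Hessian are the
exact derivatives of the chi-square expressions above (it cancels in the
damped-Newton step itself).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ESTIMATORS",
    "ObjectiveEval",
    "chi2_lse",
    "chi2_mle",
    "gradient_hessian",
    "mle_invalid_mask",
]

ESTIMATORS = ("lse", "wlse", "mle")


@dataclass
class ObjectiveEval:
    """Per-fit chi-square, gradient (n_params) and symmetric Hessian (p x p)."""

    chi2: np.ndarray
    gradient: np.ndarray
    hessian: np.ndarray


def _check_sigma(sigma: np.ndarray) -> None:
    if np.any(sigma <= 0):
        raise ValueError("weighted least squares requires all sigma_n > 0")


def chi2_lse(
    f: np.ndarray, z: np.ndarray, sigma: np.ndarray | None = None
) -> np.ndarray:
    """Per-fit (weighted) least-squares chi-square.

    Unweighted: ``sum((f - z)**2)``; with ``sigma`` given, each residual is
    divided by its standard deviation first.
    """
    f = np.asarray(f)
    z = np.asarray(z)
    if f.shape != z.shape:
        raise ValueError(f"shape mismatch: f {f.shape} vs z {z.shape}")
    r = f - z
    if sigma is not None:
        sigma = np.asarray(sigma)
        _check_sigma(sigma)
        r = r / sigma
    return np.sum(r * r, axis=-1)


def mle_invalid_mask(f: np.ndarray) -> np.ndarray:
    """Per-fit flag: model values unusable under the Poisson likelihood."""
    return np.any(~(f > 0), axis=-1)


def chi2_mle(f: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-fit Poisson-deviance chi-square (2x the deviance).

    Points with ``z_n = 0`` contribute only through the ``f_n - z_n`` term.
    Fits containing any ``f_n <= 0`` are outside the likelihood's domain and
    get NaN; the fit engine maps that to a failure state.
    """
    f = np.asarray(f, dtype=float)
    z = np.asarray(z, dtype=float)
    if f.shape != z.shape:
        raise ValueError(f"shape mismatch: f {f.shape} vs z {z.shape}")
    invalid = mle_invalid_mask(f)
    with np.errstate(divide="ignore", invalid="ignore"):
        # log(f) - log(z) rather than log(f/z): immune to overflow of the
        # ratio when z is subnormal
        safe_f = np.where(f > 0, f, 1.0)
        safe_z = np.where(z != 0, z, 1.0)
        log_term = np.where(
            z != 0, z * (np.log(safe_f) - np.log(safe_z)), 0.0
        )
        chi2 = 2.0 * (np.sum(f - z, axis=-1) - np.sum(log_term, axis=-1))
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.ndim == 0:
        return np.where(invalid, np.nan, chi2)[()]
    chi2[invalid] = np.nan
    return chi2


def gradient_hessian(
    f: np.ndarray,
    jacobian: np.ndarray,
    z: np.ndarray,
    estimator: str,
    sigma: np.ndarray | None = None,
) -> ObjectiveEval:
    """Chi-square, gradient and Gauss-Newton Hessian for a batch.

    Parameters
    ----------
    f, z : (n_fits, n_points)
        Model values and data.
    jacobian : (n_fits, n_points, n_params)
        Analytic partial derivatives of the model.
    estimator : {'lse', 'wlse', 'mle'}
    sigma : (n_fits, n_points), optional
        Per-point standard deviations; required for 'wlse'.
    """
    f = np.asarray(f)
    z = np.asarray(z)
    jacobian = np.asarray(jacobian)
    if f.shape != z.shape or jacobian.shape[:2] != f.shape:
        raise ValueError("inconsistent shapes among f, z and jacobian")
    if estimator == "lse":
        r = f - z
        chi2 = np.sum(r * r, axis=-1)
        grad = 2.0 * np.einsum("np,npk->nk", r, jacobian)
        hess = 2.0 * np.einsum("npk,npl->nkl", jacobian, jacobian)
    elif estimator == "wlse":
        if sigma is None:
            raise ValueError("estimator 'wlse' requires per-point sigma")
        sigma = np.asarray(sigma)
        _check_sigma(sigma)
        w = 1.0 / (sigma * sigma)
        r = f - z
        chi2 = np.sum(w * r * r, axis=-1)
        grad = 2.0 * np.einsum("np,npk->nk", w * r, jacobian)
        hess = 2.0 * np.einsum("np,npk,npl->nkl", w, jacobian, jacobian)
    elif estimator == "mle":
        chi2 = chi2_mle(f, z)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = z / f
            grad = 2.0 * np.einsum("np,npk->nk", 1.0 - ratio, jacobian)
            hess = 2.0 * np.einsum("np,npk,npl->nkl", ratio / f, jacobian, jacobian)
    else:
        raise ValueError(
            f"unknown estimator '{estimator}'; choose from {ESTIMATORS}"
        )
    # enforce exact symmetry (einsum's summation order differs between the
    # kl and lk elements by rounding)
    hess = 0.5 * (hess + np.transpose(hess, (0, 2, 1)))
    return ObjectiveEval(chi2=chi2, gradient=grad, hessian=hess)
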