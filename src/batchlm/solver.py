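"""Batched Gauss-Jordan elimination with partial pivoting.

Solves many small dense linear systems ``A x = b`` at once — one per fit —
by reducing each augmented matrix ``[A | b]`` to reduced row echelon form.
Partial pivoting (row swapping) selects the largest-magnitude pivot in each
column; when two candidates tie, the lowest row index wins. A system whose
best available pivot falls below ``pivot_tol`` is flagged singular, its
solution set to NaN, and it takes no further part in the elimination.

All fits in a batch go through identical elementwise arithmetic, so solving
a batch is bitwise identical to solving each system alone.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gauss_jordan_solve", "DEFAULT_PIVOT_TOL"]

DEFAULT_PIVOT_TOL = {"double": 1e-12, "single": 1e-6}


def gauss_jordan_solve(
    matrices: np.ndarray,
    rhs: np.ndarray,
    pivot_tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve a batch of p x p systems by Gauss-Jordan with partial pivoting.

    Parameters
    ----------
    matrices : (n_fits, p, p)
    rhs : (n_fits, p)
    pivot_tol : float
        Magnitude below which a selected pivot marks the system singular.

    Returns
    -------
    solutions : (n_fits, p)
        NaN-filled for singular systems.
    singular : (n_fits,) bool
    """
    if pivot_tol <= 0:
        raise ValueError("pivot_tol must be positive")
    matrices = np.asarray(matrices)
    rhs = np.asarray(rhs)
    if matrices.ndim != 3 or matrices.shape[1] != matrices.shape[2]:
        raise ValueError(f"matrices must be (n_fits, p, p), got {matrices.shape}")
    n, p, _ = matrices.shape
    if rhs.shape != (n, p):
        raise ValueError(
            f"rhs shape {rhs.shape} does not match matrices {matrices.shape}"
        )
    dtype = np.result_type(matrices.dtype, rhs.dtype, np.float32)
    aug = np.concatenate([matrices, rhs[:, :, None]], axis=2).astype(dtype, copy=True)
    singular = np.zeros(n, dtype=bool)
    idx = np.arange(n)

    for col in range(p):
        # Largest-magnitude pivot among rows not yet used; argmax takes the
        # first maximum, i.e. the lowest row index on ties.
        pivot_row = col + np.argmax(np.abs(aug[:, col:, col]), axis=1)
        pivot_val = aug[idx, pivot_row, col]
        singular |= np.abs(pivot_val) < pivot_tol
        active = np.flatnonzero(~singular)
        if active.size == 0:
            break
        pr = pivot_row[active]
        swap = pr != col
        sw = active[swap]
        if sw.size:
            tmp = aug[sw, pr[swap]].copy()
            aug[sw, pr[swap]] = aug[sw, col]
            aug[sw, col] = tmp
        block = aug[active]
        block[:, col, :] /= block[:, col, col, None]
        factors = block[:, :, col].copy()
        factors[:, col] = 0.0
        block -= factors[:, :, None] * block[:, col, None, :]
        aug[active] = block

    solutions = aug[:, :, p].copy()
    solutions[singular] = np.nan
    return solutions, singular
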