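import numpy as np
import pytest

from batchlm.models import get_model, square_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


def finite_difference_jacobian(model, params, coords):
    """Central-difference Jacobian of a model's value output.

    Step per parameter: 1e-6 * (1 + |a_k|).
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    n, p = params.shape
    v0, _ = model.eval(params, coords, check=False)
    jac = np.empty(v0.shape + (p,))
    for k in range(p):
        h = 1e-6 * (1.0 + np.abs(params[:, k]))
        up = params.copy()
        dn = params.copy()
        up[:, k] += h
        dn[:, k] -= h
        vu, _ = model.eval(up, coords, check=False)
        vd, _ = model.eval(dn, coords, check=False)
        jac[..., k] = (vu - vd) / (2 * h[:, None])
    return jac


def random_gauss2d_params(rng, n, side=5):
    """Well-behaved random 2D Gaussian parameter vectors on a side x side grid."""
    c = (side - 1) / 2
    return np.column_stack([
        rng.uniform(20, 1000, n),
        c + rng.uniform(-1, 1, n),
        c + rng.uniform(-1, 1, n),
        rng.uniform(0.6, 2.0, n),
        rng.uniform(1, 50, n),
    ])


@pytest.fixture
def gauss2d():
    return get_model("gauss2d")


@pytest.fixture
def grid5():
    return square_grid(5)
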