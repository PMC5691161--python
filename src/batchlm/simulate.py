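"""Synthetic fit batches with known ground truth.

Generates the kind of data used to characterize single-molecule spot
fitting: small square images of an isotropic 2D Gaussian peak on a constant
background, with either additive Gaussian noise at a chosen signal-to-noise
ratio or Poisson-distributed counts. The signal-to-noise ratio is defined
as SNR = A / (noise standard deviation), i.e. noise is scaled to the peak
amplitude above background.

Default conditions model a typical localization-microscopy spot: amplitude
500 counts, width sigma = 1 pixel, background 10 counts, on a 5 x 5 pixel
grid with the true center jittered uniformly within +-0.5 pixel of the grid
center. Initial guesses for the fits are drawn by perturbing the truth:
amplitude, width and background multiplied by Uniform(0.9, 1.1), the center
shifted by Uniform(-1, +1) pixel in each axis.

Everything is driven by one integer seed and is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .engine import FitBatch
from .models import get_model, square_grid

__all__ = [
    "SimSpec",
    "SimTruth",
    "PerturbRule",
    "make_gauss2d_batch",
    "add_gaussian_noise",
    "perturb_initials",
    "render_frame",
]

ParamRange = float | tuple[float, float]


@dataclass(frozen=True)
class PerturbRule:
    """How initial guesses are derived from the true parameters.

    Multiplicative parameters (amplitude, sigma, offset) are scaled by
    Uniform(1 - scale_frac, 1 + scale_frac); the center coordinates are
    shifted by Uniform(-shift, +shift) pixels.
    """

    scale_frac: float = 0.1
    shift: float = 1.0


@dataclass(frozen=True)
class SimSpec:
    """Conditions for one synthetic 2D-Gaussian batch.

    Scalar parameter entries are used as-is for every fit; a (lo, hi) tuple
    draws each fit's value uniformly from that range.
    """

    n_fits: int = 1000
    grid_side: int = 5
    amplitude: ParamRange = 500.0
    sigma: ParamRange = 1.0
    offset: ParamRange = 10.0
    center_jitter: float = 0.5
    noise: str = "gaussian"  # 'gaussian' | 'poisson' | 'none'
    snr: float = 10.0
    perturb: PerturbRule = field(default_factory=PerturbRule)
    seed: int = 0

    def __post_init__(self):
        if self.noise not in ("gaussian", "poisson", "none"):
            raise ValueError("noise must be 'gaussian', 'poisson' or 'none'")
        if self.noise == "gaussian" and not self.snr > 0:
            raise ValueError("snr must be > 0")
        if self.n_fits < 1 or self.grid_side < 2:
            raise ValueError("need n_fits >= 1 and grid_side >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class SimTruth:
    """Ground truth paired with a simulated batch."""

    true_params: np.ndarray
    noise_model: str
    seed: int
    grid_side: int
    snr: float | None = None


def _sample(rng: np.random.Generator, spec_val: ParamRange, n: int) -> np.ndarray:
    if np.isscalar(spec_val):
        return np.full(n, float(spec_val))
    lo, hi = spec_val
    return rng.uniform(lo, hi, n)


def add_gaussian_noise(
    values: np.ndarray,
    snr: float,
    amplitude: np.ndarray | float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise with std = amplitude / snr.

    ``amplitude`` may be per-fit; an infinite SNR leaves the data untouched.
    """
    if not snr > 0:
        raise ValueError("snr must be > 0")
    values = np.asarray(values, dtype=float)
    amp = np.broadcast_to(np.asarray(amplitude, dtype=float), values.shape[:1])
    std = amp / snr
    if np.all(std == 0):
        return values.copy()
    return values + rng.standard_normal(values.shape) * std[:, None]


def perturb_initials(
    truth: np.ndarray, rule: PerturbRule, rng: np.random.Generator
) -> np.ndarray:
    """Randomized starting parameters for each fit, derived from the truth.

    Parameter order is (amplitude, x0, y0, sigma, offset); see
    :class:`PerturbRule` for the perturbation model.
    """
    truth = np.asarray(truth, dtype=float)
    n = truth.shape[0]
    initials = truth.copy()
    lo, hi = 1.0 - rule.scale_frac, 1.0 + rule.scale_frac
    for col in (0, 3, 4):
        initials[:, col] *= rng.uniform(lo, hi, n)
    for col in (1, 2):
        initials[:, col] += rng.uniform(-rule.shift, rule.shift, n)
    return initials


def make_gauss2d_batch(spec: SimSpec) -> tuple[FitBatch, SimTruth]:
    """Generate a synthetic 2D-Gaussian batch plus its ground truth.

    Noise-free model values are rendered from sampled true parameters, noise
    is applied per the spec's noise model, and randomized initial guesses
    are attached. Raises if the sampled centers can leave the grid.
    """
    rng = np.random.default_rng(spec.seed)
    n, s = spec.n_fits, spec.grid_side
    center = (s - 1) / 2.0
    if spec.center_jitter < 0 or center - spec.center_jitter < 0:
        raise ValueError(
            f"center_jitter={spec.center_jitter} pushes peaks off the "
            f"{s}x{s} grid"
        )
    truth = np.column_stack([
        _sample(rng, spec.amplitude, n),
        center + rng.uniform(-spec.center_jitter, spec.center_jitter, n),
        center + rng.uniform(-spec.center_jitter, spec.center_jitter, n),
        _sample(rng, spec.sigma, n),
        _sample(rng, spec.offset, n),
    ])
    model = get_model("gauss2d")
    coords = square_grid(s)
    clean, _ = model.eval(truth, coords)

    if spec.noise == "gaussian":
        data = add_gaussian_noise(clean, spec.snr, truth[:, 0], rng)
    elif spec.noise == "poisson":
        if np.any(clean < 0):
            raise ValueError("Poisson noise requires non-negative model values")
        data = rng.poisson(clean).astype(float)
    else:
        data = clean.copy()

    initials = perturb_initials(truth, spec.perturb, rng)
    batch = FitBatch(data=data, initial_params=initials, coords=coords)
    sim_truth = SimTruth(
        true_params=truth,
        noise_model=spec.noise,
        seed=spec.seed,
        grid_side=s,
        snr=spec.snr if spec.noise == "gaussian" else None,
    )
    return batch, sim_truth


def render_frame(
    shape: tuple[int, int],
    spots: np.ndarray,
    noise_snr: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render 2D Gaussian spots into a single image frame.

    ``spots`` is (n_spots, 5) with rows (amplitude, x0, y0, sigma, offset);
    offsets are summed into a common background. Mainly a test utility for
    the ROI-extraction pipeline.
    """
    spots = np.atleast_2d(np.asarray(spots, dtype=float))
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(float)
    frame = np.zeros(shape, dtype=float)
    for amp, x0, y0, sig, off in spots:
        frame += amp * np.exp(
            -((x - x0) ** 2 + (y - y0) ** 2) / (2 * sig**2)
        )
    frame += spots[:, 4].sum()
    if noise_snr is not None:
        rng = rng or np.random.default_rng()
        frame = frame + rng.standard_normal(frame.shape) * (
            spots[:, 0].max() / noise_snr
        )
    return frame
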