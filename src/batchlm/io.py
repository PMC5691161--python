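"""Batch containers on disk, results tables, and ROI extraction from images.

A fit batch travels as a single HDF5 container holding the data matrix, the
initial-parameter matrix, the optional per-point sigma matrix and, for
simulated batches, the ground-truth table — plus a metadata block (model id,
grid side, seed, creation parameters). Round trips are bitwise exact.
Small hand-made batches can also be read from delimited text.

Image conventions: 0-based (row, column) indexing; an ROI of odd side s is
centered on the named pixel and spans center +- (s-1)/2 in each axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .engine import FitBatch, FitResult, FitState
from .models import get_model
from .simulate import SimTruth

__all__ = [
    "write_batch",
    "read_batch",
    "read_batch_tables",
    "write_results",
    "read_results",
    "write_truth_csv",
    "read_truth_csv",
    "extract_rois",
]


def write_batch(
    path: str | Path,
    batch: FitBatch,
    truth: SimTruth | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a batch (and optional ground truth) to an HDF5 container."""
    meta = dict(metadata or {})
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=batch.data)
        f.create_dataset("initial_params", data=batch.initial_params)
        if batch.sigma is not None:
            f.create_dataset("sigma", data=batch.sigma)
        if batch.coords is not None:
            for k, c in enumerate(batch.coords):
                f.create_dataset(f"coords/axis{k}", data=c)
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("true_params", data=truth.true_params)
            g.attrs["noise_model"] = truth.noise_model
            g.attrs["seed"] = truth.seed
            g.attrs["grid_side"] = truth.grid_side
            if truth.snr is not None:
                g.attrs["snr"] = truth.snr
        f.attrs["format"] = "batchlm-batch-v1"
        f.attrs["metadata"] = json.dumps(meta, default=str)


def read_batch(path: str | Path) -> tuple[FitBatch, SimTruth | None, dict]:
    """Read a batch container; returns (batch, truth-or-None, metadata).

    Schema violations raise with the name of the missing field.
    """
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise ValueError(f"{path}: required field 'data' missing")
        if "initial_params" not in f:
            raise ValueError(f"{path}: required field 'initial_params' missing")
        data = f["data"][...]
        initials = f["initial_params"][...]
        sigma = f["sigma"][...] if "sigma" in f else None
        coords = None
        if "coords" in f:
            axes = sorted(f["coords"], key=lambda k: int(k.removeprefix("axis")))
            coords = tuple(f["coords"][a][...] for a in axes)
        truth = None
        if "truth" in f:
            g = f["truth"]
            truth = SimTruth(
                true_params=g["true_params"][...],
                noise_model=str(g.attrs["noise_model"]),
                seed=int(g.attrs["seed"]),
                grid_side=int(g.attrs["grid_side"]),
                snr=float(g.attrs["snr"]) if "snr" in g.attrs else None,
            )
        meta = json.loads(f.attrs.get("metadata", "{}"))
    batch = FitBatch(data=data, initial_params=initials, coords=coords, sigma=sigma)
    return batch, truth, meta


def read_batch_tables(
    data_path: str | Path,
    initials_path: str | Path,
    sigma_path: str | Path | None = None,
) -> FitBatch:
    """Assemble a batch from delimited-text matrices (one fit per row)."""
    data = np.loadtxt(data_path, delimiter=",", ndmin=2)
    initials = np.loadtxt(initials_path, delimiter=",", ndmin=2)
    sigma = None
    if sigma_path is not None:
        sigma = np.loadtxt(sigma_path, delimiter=",", ndmin=2)
    return FitBatch(data=data, initial_params=initials, sigma=sigma)


def results_frame(results: FitResult, param_names=None) -> pd.DataFrame:
    p = results.params.shape[1]
    if param_names is None:
        param_names = [f"p{k}" for k in range(p)]
    frame = pd.DataFrame({"fit_index": np.arange(results.n_fits)})
    for k, name in enumerate(param_names):
        frame[name] = results.params[:, k]
    frame["state"] = FitState.to_names(results.states)
    frame["chi2"] = results.chi2
    frame["n_iterations"] = results.n_iterations
    return frame


def write_results(
    results: FitResult, path: str | Path, model_id: str | None = None
) -> None:
    """Write per-fit results to CSV, ordered by fit index.

    Parameter values are printed with 17 significant digits so the table
    reproduces them to full double precision on re-reading.
    """
    names = get_model(model_id).param_names if model_id else None
    frame = results_frame(results, names)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_truth_csv(truth: SimTruth, path: str | Path) -> None:
    names = get_model("gauss2d").param_names \
        if truth.true_params.shape[1] == 5 \
        else [f"p{k}" for k in range(truth.true_params.shape[1])]
    frame = pd.DataFrame(truth.true_params, columns=list(names))
    frame.insert(0, "fit_index", np.arange(len(frame)))
    frame.to_csv(path, index=False, float_format="%.17g")


def read_truth_csv(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path, float_precision="round_trip")
    return frame.drop(columns=["fit_index"]).to_numpy()


def _load_stack(stack) -> np.ndarray:
    if isinstance(stack, (str, Path)):
        arr = tifffile.imread(stack)
    else:
        arr = np.asarray(stack)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D frame or 3D stack, got shape {arr.shape}")
    return arr


def extract_rois(
    stack,
    centers: np.ndarray | pd.DataFrame,
    size: int,
) -> FitBatch:
    """Cut square patches around spot centers into a fit batch.

    Parameters
    ----------
    stack : array or path
        Image stack ``(n_frames, height, width)`` or a TIFF file path.
    centers : (n, 3) array or DataFrame with columns frame, row, col
        One ROI center per row, 0-based integer pixel coordinates.
    size : odd int
        Patch side length; the patch spans center +- (size-1)/2.

    Each patch becomes one fit dataset of ``size**2`` points (row-major).
    Initial parameters are auto-estimated per patch: offset = min, amplitude
    = max - min, center = intensity centroid of (value - min), sigma = s/4.
    """
    if size % 2 != 1:
        raise ValueError(f"ROI size must be odd, got {size}")
    arr = _load_stack(stack)
    if isinstance(centers, pd.DataFrame):
        centers = centers[["frame", "row", "col"]].to_numpy()
    centers = np.atleast_2d(np.asarray(centers, dtype=int))
    half = size // 2
    n_frames, h, w = arr.shape
    bad = np.flatnonzero(
        (centers[:, 0] < 0) | (centers[:, 0] >= n_frames)
        | (centers[:, 1] - half < 0) | (centers[:, 1] + half >= h)
        | (centers[:, 2] - half < 0) | (centers[:, 2] + half >= w)
    )
    if bad.size:
        raise ValueError(
            f"ROIs out of bounds for {size}x{size} patches at indices "
            f"{bad.tolist()}"
        )
    n = centers.shape[0]
    data = np.empty((n, size * size), dtype=float)
    initials = np.empty((n, 5), dtype=float)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    for i, (fr, row, col) in enumerate(centers):
        patch = arr[fr, row - half : row + half + 1, col - half : col + half + 1]
        patch = patch.astype(float)
        data[i] = patch.ravel()
        lo = patch.min()
        amp = patch.max() - lo
        weights = patch - lo
        total = weights.sum()
        if total > 0:
            cx = float((weights * xx).sum() / total)
            cy = float((weights * yy).sum() / total)
        else:
            cx = cy = half
        initials[i] = (amp, cx, cy, size / 4.0, lo)
    return FitBatch(data=data, initial_params=initials)
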