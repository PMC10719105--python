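"""Covariance-weighted Poisson loss for sequence-to-accessibility models.

Training signals are a cell-type-by-genomic-bin matrix.  To keep rare
cell types from being drowned out, each cell type i receives a weight
w_i = (sum_j C_ij) / n, where C is the between-type covariance matrix of
the true signals and n the number of cell types; the per-type Poisson
losses  mean_j (y_pred - y_true * log y_pred)  are then combined with
these weights.  The prose description (per-type row sums of the pairwise
covariance) is the default; the alternative reading -- a single scalar
weight equal to the mean of the diagonal variances -- is available via
``mode="scalar"``.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["covariance_weights", "weighted_poisson_loss", "poisson_loss_grad"]


def covariance_weights(y_true: np.ndarray, mode: str = "vector"):
    """Per-cell-type weights from the between-type covariance of true signals.

    ``y_true`` is cell-types x bins (>= 2 bins).  mode="vector" returns
    w_i = (sum_j C_ij)/n; mode="scalar" returns the single value
    (sum_i C_ii)/n.  Negative weights can arise from anticorrelated types
    and are passed through with a warning.
    """
    y = np.asarray(y_true, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 bins")
    n = y.shape[0]
    C = np.cov(y)
    C = np.atleast_2d(C)
    if mode == "vector":
        w = C.sum(axis=1) / n
    elif mode == "scalar":
        w = float(np.trace(C) / n)
    else:
        raise ValueError("mode must be 'vector' or 'scalar'")
    if np.any(np.atleast_1d(w) < 0):
        warnings.warn("negative covariance weights (anticorrelated cell types)")
    return w


def weighted_poisson_loss(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    w,
    reduction: str = "mean",
) -> float:
    """Weighted Poisson loss L = sum_i w_i * reduce_j (yp_ij - yt_ij * ln yp_ij).

    ``reduction`` over bins is the mean by default (scale-stable in the
    number of bins) or the sum.  Predictions must be strictly positive.
    A scalar ``w`` applies one weight to every cell type.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError("shape mismatch")
    if np.any(yp <= 0):
        raise ValueError("predictions must be strictly positive")
    per_entry = yp - yt * np.log(yp)
    if reduction == "mean":
        per_type = per_entry.mean(axis=1)
    elif reduction == "sum":
        per_type = per_entry.sum(axis=1)
    else:
        raise ValueError("reduction must be 'mean' or 'sum'")
    w = np.asarray(w, dtype=float)
    return float(np.sum(w * per_type))


def poisson_loss_grad(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Per-entry derivative of the (unweighted) Poisson term: 1 - y/yhat."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if np.any(yp <= 0):
        raise ValueError("predictions must be strictly positive")
    return 1.0 - yt / yp
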