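"""Cis-regulatory module discovery by non-negative matrix factorization.

The peaks-by-subclass accessibility matrix V (N x M, nonnegative) is
decomposed as V ~ W H with W (N x R) the basis ("which peaks belong to
each module") and H (R x M) the coefficients ("which subclasses each
module is active in").  The factorization uses Lee-Seung multiplicative
updates on the Frobenius objective from a seeded nonnegative random
initialization; the objective trajectory is recorded so monotonicity can
be asserted.  Rank selection is guided by the Hoyer sparseness of H rows
and the normalized Shannon entropy of column-normalized H, averaged over
several seeded runs.  Modules are associated with subclasses by min-max
scaling H within each subclass column and thresholding, and
module-specific peaks are selected by the Kim-Park feature score on W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ModuleDecomposition",
    "nmf",
    "cpm_normalize",
    "select_rank",
    "hoyer_sparseness",
    "coefficient_entropy",
    "associate_modules",
    "feature_scores",
    "module_of_peak",
]

_EPS = 1e-10


@dataclass
class ModuleDecomposition:
    W: np.ndarray  # N x R basis
    H: np.ndarray  # R x M coefficients
    rank: int
    seed: int
    errors: np.ndarray  # Frobenius reconstruction error per iteration
    converged: bool

    @property
    def error(self) -> float:
        return float(self.errors[-1])


def cpm_normalize(V: np.ndarray) -> np.ndarray:
    """Column-wise counts-per-million of the aggregated accessibility."""
    V = np.asarray(V, dtype=float)
    totals = V.sum(axis=0, keepdims=True)
    totals = np.where(totals == 0, 1.0, totals)
    return V / totals * 1e6


def nmf(
    V: np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ModuleDecomposition:
    """Multiplicative-update NMF of a nonnegative matrix (Frobenius loss).

    Converged when the relative change of the reconstruction error drops
    below ``tol`` or after ``max_iter`` iterations.  The error sequence is
    non-increasing by construction of the updates.
    """
    V = np.asarray(V, dtype=float)
    if V.min() < 0:
        raise ValueError("V must be nonnegative")
    n, m = V.shape
    if not 1 <= rank <= min(n, m):
        raise ValueError("rank must satisfy 1 <= R <= min(N, M)")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / rank) if V.mean() > 0 else 1.0
    W = scale * rng.random((n, rank)) + _EPS
    H = scale * rng.random((rank, m)) + _EPS

    errors = [np.linalg.norm(V - W @ H)]
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ V) / np.maximum(W.T @ W @ H, _EPS)
        W *= (V @ H.T) / np.maximum(W @ H @ H.T, _EPS)
        err = np.linalg.norm(V - W @ H)
        prev = errors[-1]
        errors.append(err)
        if prev > 0 and (prev - err) / prev < tol:
            converged = True
            break
    return ModuleDecomposition(
        W=W, H=H, rank=rank, seed=seed, errors=np.asarray(errors), converged=converged
    )


def hoyer_sparseness(x: np.ndarray) -> float:
    """Hoyer sparseness (sqrt(n) - |x|_1/|x|_2) / (sqrt(n) - 1), in [0, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n <= 1:
        return 1.0
    l2 = np.linalg.norm(x)
    if l2 == 0:
        return 0.0
    return float((np.sqrt(n) - np.abs(x).sum() / l2) / (np.sqrt(n) - 1))


def coefficient_entropy(H: np.ndarray) -> float:
    """Normalized Shannon entropy of column-normalized coefficients.

    Each subclass column of H is normalized to a distribution over
    modules; its entropy is divided by log2 R and the result averaged
    over columns.  0 means every subclass loads on a single module; 1
    means uniform loading.
    """
    H = np.asarray(H, dtype=float)
    r = H.shape[0]
    if r == 1:
        return 0.0
    totals = H.sum(axis=0, keepdims=True)
    totals = np.where(totals == 0, 1.0, totals)
    P = H / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log2(P), 0.0)
    ent = -terms.sum(axis=0) / np.log2(r)
    return float(ent.mean())


def select_rank(
    V: np.ndarray,
    ranks,
    n_runs: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
) -> pd.DataFrame:
    """Rank-selection metrics averaged over ``n_runs`` seeded NMF runs.

    Returns a table with per-rank mean sparseness (Hoyer, over rows of H)
    and mean entropy (normalized, over columns of H); higher sparseness
    and lower entropy indicate a crisper decomposition.
    """
    ranks = list(ranks)
    if not ranks:
        raise ValueError("rank grid is empty")
    rows = []
    for r in ranks:
        sp, en, err = [], [], []
        for run in range(n_runs):
            dec = nmf(V, r, seed=seed * 1000 + r * 10 + run, max_iter=max_iter, tol=tol)
            sp.append(np.mean([hoyer_sparseness(row) for row in dec.H]))
            en.append(coefficient_entropy(dec.H))
            err.append(dec.error)
        rows.append((r, float(np.mean(sp)), float(np.mean(en)), float(np.mean(err)), n_runs))
    return pd.DataFrame(
        rows, columns=["rank", "sparseness", "entropy", "error", "n_runs"]
    )


def associate_modules(H: np.ndarray, threshold: float = 0.1):
    """Associate modules with subclasses by min-max-scaled coefficients.

    Each subclass column of H is scaled to [0, 1]; (module, subclass) is
    associated iff the scaled value exceeds ``threshold``.  Constant
    columns scale to all-zero and are flagged.

    Returns (scaled H, association boolean matrix, flagged column indices).
    """
    H = np.asarray(H, dtype=float)
    if H.min() < 0:
        raise ValueError("H must be nonnegative")
    lo = H.min(axis=0, keepdims=True)
    hi = H.max(axis=0, keepdims=True)
    span = hi - lo
    flagged = np.nonzero(span.ravel() == 0)[0]
    scaled = np.where(span > 0, (H - lo) / np.where(span == 0, 1.0, span), 0.0)
    assoc = scaled > threshold
    return scaled, assoc, flagged


def feature_scores(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kim-Park feature score per peak and module-specific peak selection.

    With p(i, r) = W_ir / sum_r W_ir, the score is
    1 + (1/log2 R) * sum_r p log2 p, i.e. one minus the normalized row
    entropy: 1 for a peak loading on a single module, 0 for uniform
    loading.  A peak is module-specific iff its score exceeds
    median + 3 s.d. of the scores AND its largest basis entry exceeds the
    median of all entries of W.  All-zero rows get NaN scores and are
    never selected.
    """
    W = np.asarray(W, dtype=float)
    if W.min() < 0:
        raise ValueError("W must be nonnegative")
    n, r = W.shape
    rowsum = W.sum(axis=1, keepdims=True)
    zero_rows = rowsum.ravel() == 0
    P = W / np.where(rowsum == 0, 1.0, rowsum)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log2(P), 0.0)
    if r == 1:
        scores = np.ones(n)
    else:
        scores = 1.0 + terms.sum(axis=1) / np.log2(r)
    scores[zero_rows] = np.nan
    valid = scores[~zero_rows]
    med, sd = np.median(valid), np.std(valid)
    selected = (
        ~zero_rows
        & (scores > med + 3 * sd)
        & (W.max(axis=1) > np.median(W))
    )
    return scores, selected


def module_of_peak(W: np.ndarray) -> np.ndarray:
    """Hard module assignment: the basis component with the largest loading."""
    return np.argmax(np.asarray(W), axis=1)
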