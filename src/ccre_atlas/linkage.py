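"""Co-accessibility and enhancer-gene linking with shuffled-null calibration.

Candidate cCRE pairs are enumerated within a 500-kb genomic window and
classified proximal/distal by a +/-1-kb TSS margin.  Pairwise
co-accessibility is scored as the Pearson correlation of seeded random
metacell aggregates within subclasses; significance is calibrated against
scores recomputed after shuffling the peak columns of the cell-by-peak
matrix, with a normal fit to the shuffled scores, one-sided upper-tail
p-values and Benjamini-Hochberg control at FDR < 0.001.  Enhancer-gene
links are Pearson correlations across subclasses between distal-peak
accessibility and expression of the gene whose promoter hosts the
proximal member, thresholded at an empirical FDR computed from randomly
re-paired peak-gene correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NullFit",
    "enumerate_pairs",
    "make_metacells",
    "score_coaccessibility",
    "shuffle_peak_columns",
    "calibrate_coaccess_null",
    "normalize_log1p_cpm",
    "link_enhancer_gene",
    "empirical_fdr",
]

WINDOW = 500_000
PROXIMAL_MARGIN = 1000


def _distance_to_nearest(pos: np.ndarray, ref_sorted: np.ndarray) -> np.ndarray:
    """Distance from each position to the nearest reference position."""
    if len(ref_sorted) == 0:
        return np.full(len(pos), np.inf)
    idx = np.searchsorted(ref_sorted, pos)
    left = np.abs(pos - ref_sorted[np.clip(idx - 1, 0, len(ref_sorted) - 1)])
    right = np.abs(ref_sorted[np.clip(idx, 0, len(ref_sorted) - 1)] - pos)
    return np.minimum(left, right)


def enumerate_pairs(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = WINDOW,
    proximal_margin: int = PROXIMAL_MARGIN,
) -> pd.DataFrame:
    """All same-contig peak pairs with summit distance <= ``window``.

    Each member is labelled proximal iff its summit lies within
    ``proximal_margin`` of any TSS; the pair class is derived
    (proximal-proximal / distal-distal / distal-proximal).  Peaks are
    referenced by their positional index in ``peaks``.
    """
    peaks = peaks.reset_index(drop=True)
    tss_by_chrom = {
        c: np.sort(g["tss" if "tss" in g.columns else "pos"].to_numpy())
        for c, g in tss.groupby("chrom", sort=False)
    }
    summit = peaks["summit"].to_numpy()
    proximal = np.zeros(len(peaks), dtype=bool)
    for chrom, g in peaks.groupby("chrom", sort=False):
        ref = tss_by_chrom.get(chrom, np.array([]))
        d = _distance_to_nearest(g["summit"].to_numpy(), ref)
        proximal[g.index.to_numpy()] = d <= proximal_margin

    rows_a, rows_b = [], []
    for chrom, g in peaks.groupby("chrom", sort=False):
        idx = g.index.to_numpy()
        pos = summit[idx]
        order = np.argsort(pos, kind="mergesort")
        idx, pos = idx[order], pos[order]
        hi = np.searchsorted(pos, pos + window, side="right")
        for k in range(len(idx)):
            if hi[k] > k + 1:
                rows_a.append(np.full(hi[k] - k - 1, idx[k]))
                rows_b.append(idx[k + 1 : hi[k]])
    if not rows_a:
        return pd.DataFrame(columns=["a", "b", "distance", "class"])
    a = np.concatenate(rows_a)
    b = np.concatenate(rows_b)
    dist = np.abs(summit[a] - summit[b])
    pa, pb = proximal[a], proximal[b]
    cls = np.where(
        pa & pb, "proximal-proximal", np.where(~pa & ~pb, "distal-distal", "distal-proximal")
    )
    return pd.DataFrame({"a": a, "b": b, "distance": dist, "class": cls})


def make_metacells(
    X,
    subclass_of_cell: np.ndarray,
    metacell_size: int = 10,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Aggregate cells into seeded random metacells within each subclass.

    Cells are shuffled within their subclass and summed in groups of
    exactly ``metacell_size``; a remainder smaller than the group size is
    dropped.  Returns a dense metacell-by-peak matrix.
    """
    rng = rng or np.random.default_rng(0)
    subclass_of_cell = np.asarray(subclass_of_cell)
    groups = []
    for s in np.unique(subclass_of_cell):
        cells = np.nonzero(subclass_of_cell == s)[0]
        cells = rng.permutation(cells)
        n_full = len(cells) // metacell_size
        for k in range(n_full):
            groups.append(cells[k * metacell_size : (k + 1) * metacell_size])
    if not groups:
        raise ValueError("no complete metacell; reduce metacell_size")
    out = np.zeros((len(groups), X.shape[1]))
    dense = X.toarray() if sp.issparse(X) else np.asarray(X)
    for i, g in enumerate(groups):
        out[i] = dense[g].sum(axis=0)
    return out


def score_coaccessibility(
    meta: np.ndarray, pairs: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of metacell-aggregated signals per pair.

    Returns (scores, valid); pairs touching a zero-variance aggregated
    peak get NaN and valid=False.
    """
    meta = np.asarray(meta, dtype=float)
    mu = meta.mean(axis=0)
    sd = meta.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (meta - mu) / sd
    a = pairs["a"].to_numpy()
    b = pairs["b"].to_numpy()
    valid = (sd[a] > 0) & (sd[b] > 0)
    scores = np.full(len(pairs), np.nan)
    scores[valid] = np.nanmean(Z[:, a[valid]] * Z[:, b[valid]], axis=0)
    return scores, valid


def shuffle_peak_columns(X, rng: np.random.Generator):
    """Random permutation of the peak columns (shuffled-matrix background)."""
    perm = rng.permutation(X.shape[1])
    return X[:, perm]


@dataclass
class NullFit:
    """Normal null fitted to shuffled-background co-accessibility scores."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def pvalue(self, scores) -> np.ndarray:
        """One-sided upper-tail p-value under the fitted normal."""
        return stats.norm.sf(np.asarray(scores, dtype=float), self.mu, self.sigma)


def calibrate_coaccess_null(
    real_scores: np.ndarray,
    shuffled_scores: np.ndarray,
    fdr: float = 0.001,
) -> tuple[np.ndarray, np.ndarray, NullFit]:
    """Retain pairs whose score significantly exceeds the shuffled null.

    A normal distribution is fitted (MLE: mean and s.d.) to the shuffled
    scores; real scores get one-sided upper-tail p-values which are
    Benjamini-Hochberg adjusted; retained iff adjusted < ``fdr``.
    Returns (retained boolean mask, adjusted p-values, fitted null).
    """
    shuffled = np.asarray(shuffled_scores, dtype=float)
    shuffled = shuffled[np.isfinite(shuffled)]
    if len(shuffled) < 100:
        raise ValueError("need at least 100 shuffled scores to fit the null")
    null = NullFit(mu=float(shuffled.mean()), sigma=float(shuffled.std()))
    real = np.asarray(real_scores, dtype=float)
    finite = np.isfinite(real)
    pvals = np.full(len(real), np.nan)
    pvals[finite] = null.pvalue(real[finite])
    qvals = np.full(len(real), np.nan)
    qvals[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    retained = finite & (qvals < fdr)
    return retained, qvals, null


def normalize_log1p_cpm(M: pd.DataFrame) -> pd.DataFrame:
    """log1p of counts-per-million within each subclass row."""
    vals = M.to_numpy(dtype=float)
    totals = vals.sum(axis=1, keepdims=True)
    totals = np.where(totals == 0, 1.0, totals)
    return pd.DataFrame(
        np.log1p(vals / totals * 1e6), index=M.index, columns=M.columns
    )


def link_enhancer_gene(
    accessibility: pd.DataFrame,
    expression: pd.DataFrame,
    links: pd.DataFrame,
    normalize: bool = True,
) -> pd.DataFrame:
    """Pearson correlation across subclasses for candidate peak-gene links.

    ``accessibility`` is subclass x peak, ``expression`` subclass x gene
    (matched subclass rows), ``links`` has columns ``peak`` and ``gene``
    naming columns of the respective matrices.  Both matrices are log1p
    CPM-normalized per subclass unless ``normalize=False``.  Zero-variance
    members yield NaN and are flagged excluded.
    """
    if not accessibility.index.equals(expression.index):
        raise ValueError("subclass rows of accessibility and expression must match")
    if len(accessibility) < 3:
        raise ValueError("need at least 3 subclasses")
    A = normalize_log1p_cpm(accessibility) if normalize else accessibility
    E = normalize_log1p_cpm(expression) if normalize else expression

    def zscore(df):
        v = df.to_numpy(dtype=float)
        sd = v.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (v - v.mean(axis=0)) / sd
        return z, sd

    Za, sda = zscore(A)
    Ze, sde = zscore(E)
    ai = A.columns.get_indexer(links["peak"])
    gi = E.columns.get_indexer(links["gene"])
    if (ai < 0).any() or (gi < 0).any():
        raise KeyError("link references a peak or gene absent from the matrices")
    valid = (sda[ai] > 0) & (sde[gi] > 0)
    pcc = np.full(len(links), np.nan)
    pcc[valid] = np.mean(Za[:, ai[valid]] * Ze[:, gi[valid]], axis=0)
    out = links.copy()
    out["pcc"] = pcc
    out["excluded"] = ~valid
    return out


def empirical_fdr(
    real_pccs: np.ndarray,
    shuffled_pccs: np.ndarray,
    fdr: float = 0.01,
) -> tuple[float | None, float | None, np.ndarray]:
    """Empirical-FDR thresholds from shuffled-pair correlations.

    For a threshold t, FDR+(t) = #{shuffled >= t} / #{real >= t}
    (the shuffled count scaled by len(real)/len(shuffled) when the sets
    differ in size); the positive threshold is the smallest real score t
    with FDR+(t) < ``fdr``.  The negative tail is handled symmetrically.
    Returns (pos_threshold, neg_threshold, classification) with
    classification in {+1, -1, 0} per real score; a threshold is None
    when no score satisfies the bound.
    """
    real = np.asarray(real_pccs, dtype=float)
    real = real[np.isfinite(real)] if np.isnan(real).any() else real
    if len(real) == 0:
        raise ValueError("empty real score set")
    shuffled = np.sort(np.asarray(shuffled_pccs, dtype=float))
    shuffled = shuffled[np.isfinite(shuffled)]
    scale = len(real) / max(len(shuffled), 1)
    real_sorted = np.sort(real)

    def fdr_pos(t):
        n_real = len(real_sorted) - np.searchsorted(real_sorted, t, side="left")
        if n_real == 0:
            return np.inf
        n_shuf = len(shuffled) - np.searchsorted(shuffled, t, side="left")
        return n_shuf * scale / n_real

    def fdr_neg(t):
        n_real = np.searchsorted(real_sorted, t, side="right")
        if n_real == 0:
            return np.inf
        n_shuf = np.searchsorted(shuffled, t, side="right")
        return n_shuf * scale / n_real

    pos_candidates = [t for t in np.unique(real_sorted) if fdr_pos(t) < fdr]
    neg_candidates = [t for t in np.unique(real_sorted) if fdr_neg(t) < fdr]
    pos_t = min(pos_candidates) if pos_candidates else None
    neg_t = max(neg_candidates) if neg_candidates else None

    orig = np.asarray(real_pccs, dtype=float)
    cls = np.zeros(len(orig), dtype=int)
    if pos_t is not None:
        cls[np.isfinite(orig) & (orig >= pos_t)] = 1
    if neg_t is not None:
        cls[np.isfinite(orig) & (orig <= neg_t)] = -1
    return pos_t, neg_t, cls
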