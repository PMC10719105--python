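"""Reproducible-peak filtering and the zero-inflated beta cell-fraction filter.

Per-cluster summit calls are extended to fixed 501-bp elements, scores are
normalized to score-per-million (SPM) so a single cut-off applies across
clusters of very different depth, and a pooled peak survives only when it
overlaps >= 50% of its length with a call in both biological replicates or
both pseudoreplicates.  Cluster catalogues are merged by iteratively
keeping the highest-SPM element and removing everything it overlaps, which
preserves the fixed width.  Finally, elements must be accessible in a
significant fraction of cells in at least one cluster, judged against a
zero-inflated beta null fitted to background-region cell fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ZibParams",
    "extend_summits",
    "spm_transform",
    "spm_filter",
    "reproducible_peaks",
    "merge_union",
    "blacklist_filter",
    "fit_zib",
    "zib_filter",
]


def extend_summits(
    summits: pd.DataFrame,
    flank: int = 250,
    contig_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Extend summits by ``flank`` bp on either side to fixed-width peaks.

    A summit at position p becomes [p - flank, p + flank + 1), width
    2*flank + 1 (501 bp at the default).  Intervals are clipped at contig
    bounds and flagged; a summit outside its contig raises.
    """
    out = summits.copy()
    pos = out["summit"].to_numpy()
    if (pos < 0).any():
        raise ValueError("summit before contig start")
    start = pos - flank
    end = pos + flank + 1
    clipped = start < 0
    start = np.maximum(start, 0)
    if contig_sizes is not None:
        sizes = out["chrom"].map(contig_sizes).to_numpy()
        if np.any(pos >= sizes):
            raise ValueError("summit beyond contig end")
        over = end > sizes
        end = np.minimum(end, sizes)
        clipped = clipped | over
    out["start"], out["end"], out["clipped"] = start, end, clipped
    return out


def spm_transform(peaks: pd.DataFrame, score_col: str = "score") -> pd.DataFrame:
    """Convert caller scores (-log10 q) to score-per-million within a cluster.

    spm_i = score_i / (sum_j score_j / 1e6), so SPM sums to one million
    per cluster and depth-driven score inflation cancels.
    """
    total = peaks[score_col].sum()
    if len(peaks) == 0 or total <= 0:
        raise ValueError("total score must be positive")
    out = peaks.copy()
    out["spm"] = out[score_col] / (total / 1e6)
    return out


def spm_filter(peaks: pd.DataFrame, min_spm: float = 5.0) -> pd.DataFrame:
    """Retain peaks with SPM >= min_spm (inclusive)."""
    return peaks[peaks["spm"] >= min_spm].reset_index(drop=True)


def _max_overlap_fraction(pooled: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
    """For each pooled peak, max single-peak overlap / pooled length."""
    frac = np.zeros(len(pooled))
    others = {c: g for c, g in other.groupby("chrom", sort=False)}
    for chrom, group in pooled.groupby("chrom", sort=False):
        o = others.get(chrom)
        if o is None or len(o) == 0:
            continue
        ps = group["start"].to_numpy()[:, None]
        pe = group["end"].to_numpy()[:, None]
        os_, oe = o["start"].to_numpy()[None, :], o["end"].to_numpy()[None, :]
        ov = np.clip(np.minimum(pe, oe) - np.maximum(ps, os_), 0, None)
        frac[group.index.to_numpy()] = ov.max(axis=1) / (pe - ps)[:, 0]
    return frac


def reproducible_peaks(
    pooled: pd.DataFrame,
    rep1: pd.DataFrame | None,
    rep2: pd.DataFrame | None,
    pseudo1: pd.DataFrame | None,
    pseudo2: pd.DataFrame | None,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Replicate/pseudoreplicate reproducibility rule on pooled calls.

    A pooled peak is retained iff it overlaps at least ``min_overlap`` of
    its own length with some peak in both replicates, or with some peak in
    both pseudoreplicates.  Overlap fraction is measured against the
    pooled peak's length.  A call set that is absent (``None``, e.g. the
    caller was skipped for a depth-limited replicate) automatically passes
    its branch, and the decision is flagged in the ``auto_pass`` column.
    """
    pooled = pooled.reset_index(drop=True)

    def branch(a, b):
        ok = np.ones(len(pooled), dtype=bool)
        auto = (a is None) or (b is None)
        for other in (a, b):
            if other is not None:
                ok &= _max_overlap_fraction(pooled, other) >= min_overlap
        return ok, auto

    rep_ok, rep_auto = branch(rep1, rep2)
    pseudo_ok, pseudo_auto = branch(pseudo1, pseudo2)
    keep = rep_ok | pseudo_ok
    out = pooled[keep].reset_index(drop=True)
    out["auto_pass"] = bool(rep_auto or pseudo_auto)
    return out


def merge_union(per_cluster: dict[object, pd.DataFrame]) -> pd.DataFrame:
    """Merge cluster catalogues into a non-overlapping fixed-width union.

    Peaks across clusters are ranked by SPM (ties broken by coordinate for
    determinism); the top peak is kept and every peak overlapping it is
    removed, iterating until none remain.  Each catalogue entry records the
    clusters whose removed or identical peaks it absorbed
    (``source_clusters``).
    """
    frames = []
    for cluster, df in per_cluster.items():
        f = df.copy()
        f["cluster"] = cluster
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "summit", "spm", "source_clusters"])
    allp = pd.concat(frames, ignore_index=True)
    allp = allp.sort_values(
        ["spm", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)

    kept_trees: dict[str, IntervalTree] = {}
    kept_rows: list[int] = []
    kept_id = np.full(len(allp), -1, dtype=int)  # which kept entry absorbed each peak
    for i in range(len(allp)):
        chrom = allp.at[i, "chrom"]
        s, e = int(allp.at[i, "start"]), int(allp.at[i, "end"])
        tree = kept_trees.setdefault(chrom, IntervalTree())
        hits = tree[s:e]
        if hits:
            best = max(hits, key=lambda iv: min(iv.end, e) - max(iv.begin, s))
            kept_id[i] = best.data
        else:
            tree[s:e] = len(kept_rows)
            kept_id[i] = len(kept_rows)
            kept_rows.append(i)

    catalogue = allp.loc[kept_rows].reset_index(drop=True)
    members = pd.DataFrame({"kept": kept_id, "cluster": allp["cluster"]})
    prov = members.groupby("kept")["cluster"].apply(
        lambda c: ",".join(str(x) for x in sorted(set(c)))
    )
    catalogue["source_clusters"] = prov.to_numpy()
    catalogue = catalogue.sort_values(["chrom", "start"]).reset_index(drop=True)
    return catalogue.drop(columns=["cluster"])


def blacklist_filter(peaks: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Remove peaks overlapping any blacklist interval by >= 1 bp."""
    if len(blacklist) == 0:
        return peaks.reset_index(drop=True)
    trees: dict[str, IntervalTree] = {}
    for chrom, g in blacklist.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(g["start"].astype(int), g["end"].astype(int))
        )
    keep = []
    for chrom, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"]):
        tree = trees.get(chrom)
        keep.append(tree is None or not tree.overlaps(int(s), int(e)))
    return peaks[np.asarray(keep)].reset_index(drop=True)


@dataclass
class ZibParams:
    """Zero-inflated beta null for fraction-of-cells-accessible.

    A point mass ``pi0`` at zero mixed with Beta(alpha, beta) on (0, 1).
    """

    pi0: float
    alpha: float
    beta: float
    degenerate: bool = False  # all-zero input: Beta part undefined

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must be in [0, 1]")
        if not self.degenerate and (self.alpha <= 0 or self.beta <= 0):
            raise ValueError("beta shapes must be positive")

    def sf(self, x):
        """Upper-tail P(X >= x): 1 for x <= 0, (1 - pi0) * (1 - F_beta(x)) else."""
        x = np.asarray(x, dtype=float)
        if self.degenerate:
            return np.where(x <= 0, 1.0, 0.0)
        tail = (1.0 - self.pi0) * stats.beta.sf(x, self.alpha, self.beta)
        return np.where(x <= 0, 1.0, tail)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        zero = rng.random(size) < self.pi0
        out = stats.beta.rvs(self.alpha, self.beta, size=size, random_state=rng)
        out[zero] = 0.0
        return out


def fit_zib(fractions: np.ndarray, min_obs: int = 100, min_nonzero: int = 10) -> ZibParams:
    """Fit the zero-inflated beta null to background cell fractions.

    pi0 is the zero proportion; (alpha, beta) are the maximum-likelihood
    Beta shapes on the nonzero part (via scipy's numerical MLE with the
    support fixed to (0, 1)).  Values exactly 1 are shrunk by
    (x*(n-1) + 0.5)/n to keep the likelihood finite.
    """
    x = np.asarray(fractions, dtype=float)
    if x.min() < 0 or x.max() > 1:
        raise ValueError("fractions must lie in [0, 1]")
    pi0 = float(np.mean(x == 0))
    nz = x[x > 0]
    if len(nz) == 0:
        return ZibParams(pi0=1.0, alpha=np.nan, beta=np.nan, degenerate=True)
    if len(x) < min_obs or len(nz) < min_nonzero:
        raise ValueError(
            f"need >= {min_obs} observations with >= {min_nonzero} nonzero to fit"
        )
    n = len(nz)
    nz = np.where(nz == 1.0, (nz * (n - 1) + 0.5) / n, nz)
    alpha, beta, _, _ = stats.beta.fit(nz, floc=0.0, fscale=1.0)
    return ZibParams(pi0=pi0, alpha=float(alpha), beta=float(beta))


def zib_filter(
    fractions: pd.DataFrame, null: ZibParams, fdr: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-fraction significance filter against the zero-inflated beta null.

    ``fractions`` is peaks x clusters.  Upper-tail p-values are adjusted
    by Benjamini-Hochberg within each cluster; a peak is retained when the
    adjusted value is below ``fdr`` in at least one cluster.  Returns
    (retained fractions, per-(peak, cluster) q-values).
    """
    vals = fractions.to_numpy(dtype=float)
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("fractions must lie in [0, 1]")
    pvals = null.sf(vals)
    qvals = np.empty_like(pvals)
    for j in range(pvals.shape[1]):
        qvals[:, j] = multipletests(pvals[:, j], method="fdr_bh")[1]
    q = pd.DataFrame(qvals, index=fractions.index, columns=fractions.columns)
    keep = (q < fdr).any(axis=1)
    return fractions[keep], q
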