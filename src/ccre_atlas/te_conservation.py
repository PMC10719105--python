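"""Transposable-element overlap, highTE classification and conservation.

Per-subclass TE-cCRE fractions (the fraction of a subclass's peaks
overlapping any TE by >= 1 bp) are bimodal across brain subclasses; a
two-component Gaussian mixture fitted by EM separates a high-TE component
from the bulk, with per-subclass p-values from the upper tail of the
lower (null) component.  Differential chromatin accessibility between
subclass groups uses the Wilcoxon rank-sum test with BH correction; TE
family enrichment uses two-sided Fisher exact tests; interval enrichment
against a reference set uses a genome-shuffle permutation test; and
orthology classes follow the >50%-of-bases-mappable rule combined with
cross-species accessibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Gmm2Fit",
    "te_fraction",
    "overlaps_any",
    "fit_highte_mixture",
    "dca_wilcoxon",
    "family_enrichment",
    "interval_permutation_test",
    "classify_orthology",
    "te_signal_correlation",
]


def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, g in intervals.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(g["start"].astype(int), g["end"].astype(int))
        )
    return trees


def overlaps_any(peaks: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """Boolean per peak: overlaps any reference interval by >= 1 bp."""
    trees = _trees(reference)
    out = np.zeros(len(peaks), dtype=bool)
    for k, (chrom, s, e) in enumerate(zip(peaks["chrom"], peaks["start"], peaks["end"])):
        tree = trees.get(chrom)
        out[k] = tree is not None and tree.overlaps(int(s), int(e))
    return out


def te_fraction(
    subclass_peaks: dict[object, pd.DataFrame], te: pd.DataFrame
) -> pd.Series:
    """Fraction of each subclass's peaks overlapping any TE.

    A peak hit by several TEs counts once (peak-level indicator).  Empty
    peak sets yield NaN (undefined) rather than zero.
    """
    out = {}
    for subclass, peaks in subclass_peaks.items():
        if len(peaks) == 0:
            out[subclass] = np.nan
            continue
        out[subclass] = float(overlaps_any(peaks, te).mean())
    return pd.Series(out, name="te_fraction")


@dataclass
class Gmm2Fit:
    """Two-component 1-D Gaussian mixture fit (mu1 < mu2)."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    posterior_upper: np.ndarray  # per observation
    is_high: np.ndarray  # posterior_upper > 0.5
    pvalues: np.ndarray  # upper tail under the lower (null) component
    loglik: np.ndarray  # EM trajectory, non-decreasing
    collapsed: bool  # components indistinguishable


def fit_highte_mixture(
    fractions: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-10,
    var_floor: float = 1e-8,
    seed: int = 0,
) -> Gmm2Fit:
    """EM fit of a two-component Gaussian mixture to TE fractions.

    Initialized from a seeded two-means split; components are ordered by
    mean.  A subclass is highTE when its posterior for the upper component
    exceeds 0.5; p-values are upper tails under the lower component,
    reported for transparency.  Components whose means collapse within a
    few floor-widths are flagged.
    """
    x = np.asarray(fractions, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    rng = np.random.default_rng(seed)

    # two-means init: centroids at the lower/upper terciles, refined
    mu = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
    if mu[0] == mu[1]:
        mu = mu + np.array([-1e-6, 1e-6])
    for _ in range(20):
        assign = np.abs(x[:, None] - mu[None, :]).argmin(axis=1)
        for k in range(2):
            if np.any(assign == k):
                mu[k] = x[assign == k].mean()
    var = np.array(
        [
            max(x[assign == k].var(), var_floor) if np.any(assign == k) else x.var() + var_floor
            for k in range(2)
        ]
    )
    w = np.array([max((assign == k).mean(), 1e-3) for k in range(2)])
    w = w / w.sum()

    logliks = []
    resp = None
    for _ in range(max_iter):
        comp = np.stack(
            [w[k] * stats.norm.pdf(x, mu[k], np.sqrt(var[k])) for k in range(2)], axis=1
        )
        total = comp.sum(axis=1)
        total = np.where(total <= 0, np.finfo(float).tiny, total)
        ll = float(np.log(total).sum())
        resp = comp / total[:, None]
        if logliks and ll - logliks[-1] < tol:
            logliks.append(ll)
            break
        logliks.append(ll)
        nk = resp.sum(axis=0)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)

    order = np.argsort(mu)
    mu, var, w = mu[order], var[order], w[order]
    resp = resp[:, order]
    sds = np.sqrt(var)
    collapsed = bool(abs(mu[1] - mu[0]) < 5 * np.sqrt(var_floor))
    posterior_upper = resp[:, 1]
    pvalues = stats.norm.sf(x, mu[0], sds[0])
    return Gmm2Fit(
        weights=w,
        means=mu,
        sds=sds,
        posterior_upper=posterior_upper,
        is_high=posterior_upper > 0.5,
        pvalues=pvalues,
        loglik=np.asarray(logliks),
        collapsed=collapsed,
    )


def dca_wilcoxon(
    accessibility: pd.DataFrame, group_a: list, group_b: list
) -> pd.DataFrame:
    """Differential chromatin accessibility by Wilcoxon rank-sum test.

    ``accessibility`` is peaks x subclasses; groups name subclass columns.
    Two-sided; exact for small untied samples, normal approximation with
    tie correction otherwise (scipy's automatic policy).  Peaks constant
    across both groups get p = 1.  BH adjustment across peaks.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    A = accessibility[group_a].to_numpy(dtype=float)
    B = accessibility[group_b].to_numpy(dtype=float)
    stats_, pvals = np.empty(len(A)), np.ones(len(A))
    for i in range(len(A)):
        a, b = A[i], B[i]
        if np.all(a == a[0]) and np.all(b == a[0]):
            stats_[i] = np.nan
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        stats_[i], pvals[i] = res.statistic, res.pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"statistic": stats_, "pvalue": pvals, "qvalue": qvals},
        index=accessibility.index,
    )


def family_enrichment(
    foreground: pd.Series, background: pd.Series
) -> pd.DataFrame:
    """Per-family Fisher exact enrichment of foreground vs background counts.

    Inputs are counts per family.  For each family, the 2x2 table
    [[fg_family, fg_other], [bg_family, bg_other]] is tested two-sided;
    zero-margin tables give p = 1 and an undefined odds ratio.
    BH adjustment across families.
    """
    families = sorted(set(foreground.index) | set(background.index))
    fg = foreground.reindex(families, fill_value=0).astype(int)
    bg = background.reindex(families, fill_value=0).astype(int)
    fg_total, bg_total = int(fg.sum()), int(bg.sum())
    rows = []
    for fam in families:
        table = [[fg[fam], fg_total - fg[fam]], [bg[fam], bg_total - bg[fam]]]
        if min(sum(table[0]), sum(table[1]), table[0][0] + table[1][0], table[0][1] + table[1][1]) == 0:
            rows.append((fam, np.nan, 1.0))
            continue
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append((fam, odds, p))
    out = pd.DataFrame(rows, columns=["family", "odds_ratio", "pvalue"])
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def interval_permutation_test(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    genome_sizes: dict[str, int],
    n: int = 1000,
    seed: int = 0,
) -> tuple[int, np.ndarray, float]:
    """Genome-shuffle enrichment of query intervals at a reference set.

    Each shuffle re-places every query uniformly at random on its own
    contig (lengths and contig assignment preserved); the statistic is the
    number of query intervals overlapping any reference interval.  The
    empirical p-value uses the plus-one correction
    p = (1 + #{null >= observed}) / (n + 1), so it is never zero.
    Returns (observed, null distribution, p).
    """
    rng = np.random.default_rng(seed)
    lengths = (query["end"] - query["start"]).to_numpy()
    chroms = query["chrom"].to_numpy()
    for chrom, length in zip(chroms, lengths):
        if chrom not in genome_sizes:
            raise KeyError(f"no genome size for {chrom}")
        if length > genome_sizes[chrom]:
            raise ValueError(f"query longer than contig {chrom}")
    observed = int(overlaps_any(query, reference).sum())
    trees = _trees(reference)
    null = np.empty(n, dtype=int)
    max_start = np.array([genome_sizes[c] for c in chroms]) - lengths
    for it in range(n):
        starts = (rng.random(len(query)) * (max_start + 1)).astype(np.int64)
        hits = 0
        for chrom, s, L in zip(chroms, starts, lengths):
            tree = trees.get(chrom)
            if tree is not None and tree.overlaps(int(s), int(s + L)):
                hits += 1
        null[it] = hits
    p = (1 + int(np.sum(null >= observed))) / (n + 1)
    return observed, null, p


def classify_orthology(records: pd.DataFrame, min_fraction: float = 0.5) -> pd.DataFrame:
    """Assign conservation classes from mappability and target accessibility.

    mapped_fraction > min_fraction and accessible in the target species ->
    CA-conserved; mappable but not accessible -> CA-divergent; otherwise
    mouse-specific.  Fractions outside [0, 1] are rejected.
    """
    frac = records["mapped_fraction"].to_numpy(dtype=float)
    if (frac < 0).any() or (frac > 1).any():
        raise ValueError("mapped_fraction must lie in [0, 1]")
    accessible = records["accessible_in_target"].to_numpy(dtype=bool)
    mapped = frac > min_fraction
    cls = np.where(
        mapped & accessible,
        "CA-conserved",
        np.where(mapped, "CA-divergent", "mouse-specific"),
    )
    out = records.copy()
    out["class"] = cls
    return out


def te_signal_correlation(
    accessibility: pd.DataFrame, mcg: pd.DataFrame, rna: pd.DataFrame
) -> pd.DataFrame:
    """Per-TE Pearson correlations of accessibility with mCG and RNA.

    All inputs are TE x subclass with matched columns; rows with zero
    variance in accessibility are excluded (NaN).
    """
    if accessibility.shape[1] < 3:
        raise ValueError("need at least 3 matched subclasses")
    if not (accessibility.columns.equals(mcg.columns) and accessibility.columns.equals(rna.columns)):
        raise ValueError("subclass columns must match")

    def rowcorr(X, Y):
        x = X.to_numpy(dtype=float)
        y = Y.to_numpy(dtype=float)
        xs, ys = x.std(axis=1), y.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            xz = (x - x.mean(axis=1, keepdims=True)) / xs[:, None]
            yz = (y - y.mean(axis=1, keepdims=True)) / ys[:, None]
            r = np.mean(xz * yz, axis=1)
        r[(xs == 0) | (ys == 0)] = np.nan
        return r

    return pd.DataFrame(
        {
            "pcc_mcg": rowcorr(accessibility, mcg),
            "pcc_rna": rowcorr(accessibility, rna),
        },
        index=accessibility.index,
    )
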