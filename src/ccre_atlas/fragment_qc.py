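"""Fragment-level QC: Tn5 correction, filters, TSS enrichment, nucleus gating.

The Tn5 transposase duplicates 9 bp at its target site, so aligned
fragment ends are corrected by +4 bp on the plus-strand end and -5 bp on
the minus-strand end before any downstream counting.  Per-nucleus quality
is summarized by the deduplicated fragment count and the TSS enrichment
(TSSe): single-base insertion counts aggregated in a +/-2,000-bp
strand-corrected window around each TSS, normalized to the mean signal in
the 1,900-2,000-bp flanks, smoothed with a centred 11-bp window; TSSe is
the maximum of the smoothed profile.  Nuclei with >= 1,000 fragments and
TSSe >= 10 pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TssProfile",
    "tn5_shift",
    "tn5_shift_fragments",
    "filter_read_pairs",
    "insertion_sites",
    "tss_profile",
    "tss_enrichment",
    "filter_nuclei",
]

WINDOW = 2000
FLANK_LO = 1900
SMOOTH = 11


def tn5_shift(start, end):
    """Apply the +4/-5 Tn5 correction to fragment coordinates.

    The plus-strand (left) end is shifted +4 and the minus-strand (right)
    end -5; coordinates are 0-based half-open.  Negative results are
    clipped to 0 and flagged.  Returns (start, end, clipped) arrays (or
    scalars for scalar input).
    """
    scalar = np.isscalar(start)
    s = np.atleast_1d(np.asarray(start, dtype=np.int64)) + 4
    e = np.atleast_1d(np.asarray(end, dtype=np.int64)) - 5
    clipped = (s < 0) | (e < 0)
    s = np.maximum(s, 0)
    e = np.maximum(e, 0)
    # a fragment shorter than the 9-bp correction degenerates; keep a
    # 1-bp stub and flag it rather than emitting an inverted interval
    bad = e <= s
    e = np.where(bad, s + 1, e)
    clipped |= bad
    if scalar:
        return int(s[0]), int(e[0]), bool(clipped[0])
    return s, e, clipped


def tn5_shift_fragments(fragments: pd.DataFrame) -> pd.DataFrame:
    """Tn5-correct a BED-style fragments table (chrom, start, end, ...)."""
    out = fragments.copy()
    s, e, clipped = tn5_shift(out["start"].to_numpy(), out["end"].to_numpy())
    out["start"], out["end"], out["clipped"] = s, e, clipped
    return out


def filter_read_pairs(pairs: pd.DataFrame, mapq_min: int = 30) -> pd.DataFrame:
    """MAPQ and PCR-duplicate filtering of aligned read pairs.

    Fragments with quality strictly greater than ``mapq_min`` are
    retained; duplicates (identical barcode, chrom, start, end) collapse
    to a single record.  Malformed rows (start >= end, mapq out of
    [0, 60]) raise with their positional row number.
    """
    required = {"chrom", "start", "end", "barcode", "mapq"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = (pairs["start"] >= pairs["end"]) | ~pairs["mapq"].between(0, 60)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(f"malformed read pair at row {row}")
    kept = pairs[pairs["mapq"] > mapq_min]
    return kept.drop_duplicates(subset=["barcode", "chrom", "start", "end"]).reset_index(
        drop=True
    )


def insertion_sites(fragments: pd.DataFrame) -> pd.DataFrame:
    """Explode fragments into single-base cut sites (both ends).

    The left cut site is ``start`` and the right cut site ``end - 1``
    (the end coordinate being exclusive).
    """
    left = fragments[["chrom", "barcode", "start"]].rename(columns={"start": "pos"})
    right = fragments[["chrom", "barcode"]].copy()
    right["pos"] = fragments["end"].to_numpy() - 1
    return pd.concat([left, right], ignore_index=True)


@dataclass
class TssProfile:
    """Aggregate insertion profile around TSSs for one unit (barcode/sample)."""

    offsets: np.ndarray  # -2000 .. +2000
    aggregate: np.ndarray  # raw per-offset insertion counts
    flank_mean: float
    smoothed: np.ndarray  # 11-bp moving average of aggregate/flank_mean
    tsse: float
    low_coverage: bool  # flank had zero signal; pseudocount applied


def _smooth(x: np.ndarray, width: int = SMOOTH) -> np.ndarray:
    """Centred moving average, truncated (not padded) at the edges."""
    half = width // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def tss_profile(
    positions: dict[str, np.ndarray], tss: pd.DataFrame, window: int = WINDOW
) -> TssProfile:
    """Build the strand-corrected TSS insertion profile for one barcode.

    ``positions`` maps chrom -> sorted insertion positions; ``tss`` needs
    columns chrom, pos, strand.  Minus-strand TSSs are mirrored so the
    profile is in TSS-relative orientation.
    """
    if len(tss) == 0:
        raise ValueError("need at least one TSS")
    size = 2 * window + 1
    aggregate = np.zeros(size)
    for chrom, group in tss.groupby("chrom", sort=False):
        pos = positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        pos = np.asarray(pos)
        for t, strand in zip(group["pos"].to_numpy(), group["strand"].to_numpy()):
            lo = np.searchsorted(pos, t - window, side="left")
            hi = np.searchsorted(pos, t + window, side="right")
            if hi <= lo:
                continue
            off = pos[lo:hi] - t
            if strand == "-":
                off = -off
            aggregate += np.bincount(off + window, minlength=size)

    flank = (np.abs(np.arange(-window, window + 1)) >= FLANK_LO)
    flank_total = aggregate[flank].sum()
    low_coverage = flank_total == 0
    if low_coverage:
        # one pseudocount insertion spread over the flank keeps sparse
        # nuclei finite instead of dividing by zero
        flank_mean = 1.0 / flank.sum()
    else:
        flank_mean = flank_total / flank.sum()
    smoothed = _smooth(aggregate / flank_mean)
    return TssProfile(
        offsets=np.arange(-window, window + 1),
        aggregate=aggregate,
        flank_mean=float(flank_mean),
        smoothed=smoothed,
        tsse=float(smoothed.max()),
        low_coverage=bool(low_coverage),
    )


def tss_enrichment(insertions: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """Per-barcode TSSe from a cut-site table (chrom, pos, barcode).

    Returns a DataFrame with columns barcode, tsse, low_coverage.
    """
    rows = []
    for barcode, group in insertions.groupby("barcode", sort=True):
        positions = {
            chrom: np.sort(sub["pos"].to_numpy())
            for chrom, sub in group.groupby("chrom", sort=False)
        }
        prof = tss_profile(positions, tss)
        rows.append((barcode, prof.tsse, prof.low_coverage))
    return pd.DataFrame(rows, columns=["barcode", "tsse", "low_coverage"])


def filter_nuclei(
    qc: pd.DataFrame, min_fragments: int = 1000, min_tsse: float = 10.0
) -> pd.DataFrame:
    """Nucleus QC gate: n_fragments >= min_fragments AND tsse >= min_tsse.

    Both thresholds are inclusive.  Input order is preserved.
    """
    missing = {"barcode", "n_fragments", "tsse"} - set(qc.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    keep = (qc["n_fragments"] >= min_fragments) & (qc["tsse"] >= min_tsse)
    return qc[keep].reset_index(drop=True)


def qc_table(
    fragments: pd.DataFrame,
    tss: pd.DataFrame,
    min_fragments: int = 1000,
    min_tsse: float = 10.0,
) -> pd.DataFrame:
    """Full per-barcode QC: fragment counts, TSSe and the pass flag."""
    counts = (
        fragments.groupby("barcode", sort=True).size().rename("n_fragments").reset_index()
    )
    tsse = tss_enrichment(insertion_sites(fragments), tss)
    qc = counts.merge(tsse, on="barcode", how="left")
    qc["pass"] = (qc["n_fragments"] >= min_fragments) & (qc["tsse"] >= min_tsse)
    return qc
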