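"""Readers and writers for the pipeline's standard text formats.

Everything is plain text: BED-style fragments TSV (0-based half-open),
narrowPeak summit calls, BED intervals, MatrixMarket sparse matrices with
barcode/peak sidecar files, and JSON manifests.  All tables round-trip
bit-exactly through these functions.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "read_fragments",
    "write_fragments",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "read_tss_bed",
    "read_matrix",
    "write_matrix",
    "sha256_file",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragments(path) -> pd.DataFrame:
    """Read a 10x-style fragments TSV (chrom, start, end, barcode, count)."""
    with _open(path) as fh:
        df = pd.read_csv(
            fh,
            sep="\t",
            comment="#",
            header=None,
            names=FRAGMENT_COLUMNS,
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "barcode": str, "count": np.int64},
        )
    if (df["start"] >= df["end"]).any():
        bad = int(np.nonzero((df["start"] >= df["end"]).to_numpy())[0][0]) + 1
        raise ValueError(f"{path}: invalid interval at line {bad}")
    return df


def write_fragments(fragments: pd.DataFrame, path) -> None:
    with _open(path, "wt") as fh:
        fragments[FRAGMENT_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    with _open(path) as fh:
        first = pd.read_csv(fh, sep="\t", comment="#", header=None)
    first = first.iloc[:, : len(first.columns)]
    cols = list(names) + [f"col{i}" for i in range(len(names), first.shape[1])]
    first.columns = cols[: first.shape[1]]
    return first


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in ("chrom", "start", "end") if c in df.columns]
    extra = [c for c in df.columns if c not in cols] if columns is None else []
    with _open(path, "wt") as fh:
        df[cols + extra].to_csv(fh, sep="\t", header=False, index=False)


def read_narrowpeak(path) -> pd.DataFrame:
    """Read narrowPeak; the summit is start + the 10th-column offset."""
    names = [
        "chrom", "start", "end", "name", "score",
        "strand", "signal", "pvalue", "qvalue", "summit_offset",
    ]
    with _open(path) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", header=None, names=names)
    df["summit"] = df["start"] + df["summit_offset"]
    return df


def read_tss_bed(path) -> pd.DataFrame:
    """TSS BED: chrom, start, end, name, score, strand; TSS = start (+) / end-1 (-)."""
    df = read_bed(path, names=("chrom", "start", "end", "name", "score", "strand"))
    if "strand" not in df.columns:
        raise ValueError("TSS BED requires a strand column")
    df["pos"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df[["chrom", "pos", "strand", "name"]] if "name" in df.columns else df


def write_matrix(X, row_names, col_names, prefix) -> None:
    """Write a matrix as MTX plus row/column sidecar TSVs (<prefix>.mtx, .rows.tsv, .cols.tsv)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(X) if not sp.issparse(X) else X.tocoo()
    mmwrite(str(prefix) + ".mtx", mat)
    pd.Series(list(row_names)).to_csv(str(prefix) + ".rows.tsv", sep="\t", header=False, index=False)
    pd.Series(list(col_names)).to_csv(str(prefix) + ".cols.tsv", sep="\t", header=False, index=False)


def read_matrix(prefix):
    """Read an MTX + sidecars written by :func:`write_matrix`."""
    prefix = str(prefix)
    try:
        mat = mmread(prefix + ".mtx").tocsr()
    except Exception as exc:  # surface the offending file for corrupt headers
        raise ValueError(f"cannot parse MatrixMarket file {prefix}.mtx: {exc}") from exc
    rows = pd.read_csv(prefix + ".rows.tsv", sep="\t", header=None)[0].tolist()
    cols = pd.read_csv(prefix + ".cols.tsv", sep="\t", header=None)[0].tolist()
    return mat, rows, cols


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
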