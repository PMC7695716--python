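"""Thin genomic-interval helpers over pandas/pyranges.

Intervals travel as pandas DataFrames with ``chrom``, ``start``, ``end``
columns (0-based, half-open), the same convention the synthetic generator
exports, so truth-vs-call comparisons need no coordinate shims.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = ["to_pyranges", "from_pyranges", "merge_intervals", "subtract_intervals",
           "overlaps_any", "read_bed", "write_bed"]


def to_pyranges(df: pd.DataFrame) -> pr.PyRanges:
    d = df.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"})
    return pr.PyRanges(d)


def from_pyranges(g: pr.PyRanges) -> pd.DataFrame:
    d = g.df if len(g) else pd.DataFrame(columns=["Chromosome", "Start", "End"])
    d = d.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    d["chrom"] = d["chrom"].astype(str)
    return d.reset_index(drop=True)


def merge_intervals(df: pd.DataFrame, max_gap: int = 0) -> pd.DataFrame:
    """Merge intervals whose gap is strictly less than ``max_gap`` (bp).

    ``max_gap=0`` merges only overlapping/bookended intervals.
    """
    if df.empty:
        return df.copy()
    slack = max(max_gap - 1, 0)
    return from_pyranges(to_pyranges(df[["chrom", "start", "end"]]).merge(slack=slack))


def subtract_intervals(df: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    if df.empty or other.empty:
        return df.copy()
    extra = [c for c in df.columns if c not in ("chrom", "start", "end")]
    res = from_pyranges(to_pyranges(df).subtract(to_pyranges(other[["chrom", "start", "end"]])))
    return res[["chrom", "start", "end"] + [c for c in extra if c in res.columns]]


def overlaps_any(df: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
    """Boolean per row of ``df``: overlaps at least one interval in ``other``."""
    if df.empty:
        return np.zeros(0, dtype=bool)
    if other.empty:
        return np.zeros(len(df), dtype=bool)
    flags = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        o = other[other["chrom"] == chrom]
        if o.empty:
            continue
        s = o["start"].to_numpy()
        e = o["end"].to_numpy()
        order = np.argsort(s)
        s, e = s[order], e[order]
        e_cummax = np.maximum.accumulate(e)
        for idx, (a, b) in zip(sub.index, zip(sub["start"], sub["end"])):
            k = np.searchsorted(s, b, side="left")
            flags[df.index.get_loc(idx)] = k > 0 and e_cummax[k - 1] > a
    return flags


def read_bed(path, names=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    base = ["chrom", "start", "end"]
    extra = list(names or [])
    cols = base + extra
    df = df.iloc[:, : len(cols)]
    df.columns = cols[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + [c for c in (extra_cols or []) if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
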