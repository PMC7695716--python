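"""Aggregate interaction-neighbourhood analysis (an APA variant).

Around each anchor pair a square window of the observed-over-expected
contact matrix is extracted (200 kb around each bin at 20 kb resolution
gives 11 x 11 pixels); sub-matrices are summed and each pixel divided by the
number of contributing (non-missing) sub-matrices.  Differential aggregates
subtract one condition's aggregate from the other's on pixels defined in
both.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, MatrixKind

__all__ = [
    "AggregateNeighborhood",
    "extract_neighborhood",
    "aggregate_neighborhoods",
    "differential_aggregate",
    "island_peak_pairs",
]


@dataclasses.dataclass
class AggregateNeighborhood:
    """k x k accumulated values with a matching contributing-count matrix."""

    values: np.ndarray
    counts: np.ndarray
    window: int
    resolution: int

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def center(self) -> float:
        return float(self.values[self.k // 2, self.k // 2])


def neighborhood_size(window: int, resolution: int) -> int:
    half = (window // 2) // resolution
    return 2 * half + 1


def extract_neighborhood(
    matrix: ContactMatrix,
    anchor_pair: tuple[int, int],
    window: int = 200_000,
    resolution: int | None = None,
) -> np.ndarray:
    """k x k sub-matrix around an anchor pair, NaN on missing pixels.

    Rows span the window centred on the bin containing anchor 1, columns the
    window centred on anchor 2's bin; pixels beyond the matrix edge or on
    masked bins are NaN.  Anchors are bp positions on the matrix chromosome.
    """
    if matrix.kind != MatrixKind.OBS_OVER_EXP:
        raise ValueError("extract_neighborhood expects an obs/exp matrix")
    res = resolution or matrix.resolution
    if res != matrix.resolution:
        raise ValueError("resolution does not match the matrix")
    half = (window // 2) // res
    k = 2 * half + 1
    b1, b2 = matrix.bin_of(anchor_pair[0]), matrix.bin_of(anchor_pair[1])
    n = matrix.n_bins
    out = np.full((k, k), np.nan)
    live = matrix.unmasked()
    for r in range(k):
        i = b1 - half + r
        if not (0 <= i < n) or not live[i]:
            continue
        for c in range(k):
            j = b2 - half + c
            if not (0 <= j < n) or not live[j]:
                continue
            out[r, c] = matrix.values[i, j]
    return out


def aggregate_neighborhoods(
    submatrices: list[np.ndarray], window: int = 200_000, resolution: int = 20_000
) -> AggregateNeighborhood:
    """Missing-value-aware mean of equally shaped sub-matrices.

    Each pixel is the sum of non-missing contributions divided by their
    count; pixels with zero contributions stay NaN.
    """
    if not submatrices:
        raise ValueError("no sub-matrices to aggregate")
    shape = submatrices[0].shape
    for s in submatrices:
        if s.shape != shape:
            raise ValueError("sub-matrices differ in shape")
    stack = np.stack(submatrices)
    counts = (~np.isnan(stack)).sum(axis=0)
    sums = np.nansum(stack, axis=0)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AggregateNeighborhood(values=values, counts=counts,
                                 window=window, resolution=resolution)


def differential_aggregate(
    agg_a: AggregateNeighborhood, agg_b: AggregateNeighborhood
) -> np.ndarray:
    """Per-pixel B minus A on pixels defined in both aggregates."""
    if agg_a.values.shape != agg_b.values.shape:
        raise ValueError("aggregate shapes differ")
    if (agg_a.window, agg_a.resolution) != (agg_b.window, agg_b.resolution):
        raise ValueError("aggregates have different window/resolution")
    both = (agg_a.counts > 0) & (agg_b.counts > 0)
    return np.where(both, agg_b.values - agg_a.values, np.nan)


def island_peak_pairs(
    islands: pd.DataFrame,
    cohesin_peaks: pd.DataFrame,
    max_dist: int = 150_000,
    resolution: int = 20_000,
) -> pd.DataFrame:
    """All (island centre, peak centre) anchor pairs within ``max_dist``.

    Pairs closer than two bins are excluded so the neighbourhood never sits
    on the diagonal.  Output columns: chrom, pos1 < pos2.
    """
    rows = []
    for chrom, isl in islands.groupby("chrom", sort=False):
        pk = cohesin_peaks[cohesin_peaks["chrom"] == chrom]
        if pk.empty:
            continue
        ic = ((isl["start"] + isl["end"]) // 2).to_numpy()
        pc = ((pk["start"] + pk["end"]) // 2).to_numpy()
        for a in ic:
            for b in pc:
                d = abs(int(a) - int(b))
                if 2 * resolution <= d <= max_dist:
                    rows.append((chrom, min(int(a), int(b)), max(int(a), int(b))))
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2"])
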