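"""Contact-matrix data model, normalization and I/O.

A :class:`ContactMatrix` is a per-chromosome symmetric binned intra-chromosomal
matrix.  The normalization workflow mirrors standard Hi-C practice: mask
low-coverage bins, balance with iterative correction (ICE) so every bin has
equal visibility, then divide by the per-diagonal expected value
("distance correction") to obtain observed-over-expected ratios that expose
compartments, domains and loops independently of genomic distance.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MatrixKind",
    "ContactMatrix",
    "load_matrix",
    "write_matrix",
    "load_bin_table",
    "write_bin_table",
    "filter_low_coverage_bins",
    "ice_balance",
    "distance_correct",
    "aggregate_replicates",
]


class MatrixKind(str, enum.Enum):
    RAW = "raw"
    BALANCED = "balanced"
    OBS_OVER_EXP = "obs_over_exp"
    LOGRATIO = "logratio"


@dataclasses.dataclass
class ContactMatrix:
    """Symmetric binned contact matrix for one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    resolution : int
        Bin width in bp.  Bin ``i`` covers ``[i*resolution, (i+1)*resolution)``
        (0-based, half-open).
    values : ndarray of shape (n_bins, n_bins)
        Symmetric, non-negative except for ``logratio`` kind.
    mask : ndarray of bool, shape (n_bins,)
        ``True`` marks an excluded bin; its whole row/column is treated as
        missing by every downstream operation.
    kind : MatrixKind
    bias : ndarray or None
        Multiplicative per-bin bias from balancing (NaN on masked bins).
    """

    chrom: str
    resolution: int
    values: np.ndarray
    mask: np.ndarray = None
    kind: MatrixKind = MatrixKind.RAW
    bias: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_bins,):
                raise ValueError("mask length must equal n_bins")
        self.kind = MatrixKind(self.kind)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_of(self, position: int) -> int:
        """Bin index containing a bp position (floor division)."""
        return int(position) // int(self.resolution)

    def unmasked(self) -> np.ndarray:
        return ~self.mask

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            chrom=self.chrom,
            resolution=self.resolution,
            values=self.values.copy(),
            mask=self.mask.copy(),
            kind=self.kind,
            bias=None if self.bias is None else self.bias.copy(),
        )


def load_bin_table(path) -> pd.DataFrame:
    """Read a BED bin table (chrom, start, end[, index])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_bin_table(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def make_bin_table(chrom: str, chrom_length: int, resolution: int) -> pd.DataFrame:
    n = -(-chrom_length // resolution)
    starts = np.arange(n) * resolution
    ends = np.minimum(starts + resolution, chrom_length)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})


def load_matrix(path, bin_table: pd.DataFrame) -> ContactMatrix:
    """Load a sparse triplet text matrix (bin_i, bin_j, count).

    Duplicate triplets are summed; (i, j) and (j, i) refer to the same pixel.
    Raises a parse error naming the first offending line when an index falls
    outside the bin table.
    """
    chroms = bin_table["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("bin table must cover a single chromosome")
    n = len(bin_table)
    resolution = int(bin_table["end"].iloc[0] - bin_table["start"].iloc[0])
    values = np.zeros((n, n))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(
                    f"{path}: line {lineno}: bin index ({i},{j}) outside 0..{n - 1}"
                )
            values[i, j] += c
            if i != j:
                values[j, i] += c
    return ContactMatrix(chrom=str(chroms[0]), resolution=resolution, values=values)


def write_matrix(matrix: ContactMatrix, path) -> None:
    """Write the upper triangle (incl. diagonal) as sparse triplet text."""
    iu, ju = np.triu_indices(matrix.n_bins)
    v = matrix.values[iu, ju]
    keep = v != 0
    with open(path, "w") as fh:
        for i, j, c in zip(iu[keep], ju[keep], v[keep]):
            if float(c).is_integer():
                fh.write(f"{i}\t{j}\t{int(c)}\n")
            else:
                fh.write(f"{i}\t{j}\t{c!r}\n")


def filter_low_coverage_bins(
    matrix: ContactMatrix, min_marginal_quantile: float = 0.05
) -> ContactMatrix:
    """Mask bins whose marginal contact sum falls below the given quantile.

    Zero-marginal bins are always masked.  Returns a copy with the updated
    mask; quantile 0 masks only zero-marginal bins.
    """
    out = matrix.copy()
    marg = out.values.sum(axis=1)
    active = ~out.mask
    out.mask |= marg == 0
    if min_marginal_quantile > 0:
        pool = marg[active & (marg > 0)]
        if pool.size:
            cut = np.quantile(pool, min_marginal_quantile)
            out.mask |= marg < cut
    if out.mask.all():
        raise ValueError("all bins masked by low-coverage filter")
    return out


def ice_balance(
    matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-5
) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative correction: find per-bin biases equalizing bin visibility.

    Solves for positive ``bias`` such that ``raw[i,j]/(bias[i]*bias[j])`` has
    equal row sums over unmasked bins, iterating until the coefficient of
    variation of those row sums drops below ``tol``.  Biases are normalized to
    mean 1 on unmasked bins so the overall scale of the matrix is preserved.

    Returns the balanced matrix and the bias vector (NaN on masked bins).
    Raises if the CV has not converged within ``max_iter`` sweeps.
    """
    if matrix.kind not in (MatrixKind.RAW, MatrixKind.BALANCED):
        raise ValueError("ice_balance expects a raw or balanced matrix")
    live = matrix.unmasked()
    if live.sum() == 0:
        raise ValueError("no unmasked bins to balance")
    w = matrix.values[np.ix_(live, live)].astype(float)
    bias = np.ones(w.shape[0])
    cv = np.inf
    for _ in range(max_iter):
        s = w.sum(axis=1)
        mean_s = s.mean()
        cv = s.std() / mean_s if mean_s > 0 else 0.0
        if cv < tol:
            break
        delta = s / mean_s
        delta[delta == 0] = 1.0
        w /= np.outer(delta, delta)
        bias *= delta
    else:
        raise RuntimeError(f"ICE did not converge in {max_iter} iterations (CV={cv:.3g})")
    # renormalize to mean bias 1
    scale = bias.mean()
    bias /= scale
    w *= scale**2

    full_bias = np.full(matrix.n_bins, np.nan)
    full_bias[live] = bias
    values = np.array(matrix.values, dtype=float)
    values[np.ix_(live, live)] = w
    out = ContactMatrix(
        chrom=matrix.chrom,
        resolution=matrix.resolution,
        values=values,
        mask=matrix.mask.copy(),
        kind=MatrixKind.BALANCED,
        bias=full_bias,
    )
    return out, full_bias


def distance_correct(matrix: ContactMatrix) -> ContactMatrix:
    """Observed-over-expected transform.

    The expected value for offset ``d = |i - j|`` is the mean of unmasked
    entries on that diagonal; each entry is divided by its diagonal's
    expectation.  Diagonals whose unmasked entries are all zero stay NaN; a
    positive observation on a zero-expected diagonal is an error.
    """
    if matrix.kind != MatrixKind.BALANCED:
        raise ValueError("distance_correct expects a balanced matrix")
    n = matrix.n_bins
    live = matrix.unmasked()
    out = np.full((n, n), np.nan)
    v = matrix.values
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = live[i] & live[j]
        if not ok.any():
            continue
        exp = v[i[ok], j[ok]].mean()
        if exp == 0:
            if (v[i[ok], j[ok]] > 0).any():
                raise ValueError(f"zero expected value with observations on diagonal {d}")
            continue
        out[i[ok], j[ok]] = v[i[ok], j[ok]] / exp
        out[j[ok], i[ok]] = out[i[ok], j[ok]]
    return ContactMatrix(
        chrom=matrix.chrom,
        resolution=matrix.resolution,
        values=np.where(np.isnan(out), np.nan, out),
        mask=matrix.mask.copy(),
        kind=MatrixKind.OBS_OVER_EXP,
    )


def aggregate_replicates(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Combine replicate raw matrices into one representative matrix.

    Each replicate is scaled to the mean library size (total contact count)
    and the per-pixel arithmetic mean is taken.  This library-size-normalized
    mean serves as the combined matrix for visualization and aggregate
    neighbourhood analysis.
    """
    if not matrices:
        raise ValueError("no matrices to aggregate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.resolution != first.resolution or m.n_bins != first.n_bins:
            raise ValueError("replicate matrices must share bin table and resolution")
    totals = np.array([m.values.sum() for m in matrices], dtype=float)
    if (totals == 0).any():
        raise ValueError("replicate with zero total contacts")
    target = totals.mean()
    acc = np.zeros_like(first.values, dtype=float)
    for m, t in zip(matrices, totals):
        acc += m.values * (target / t)
    acc /= len(matrices)
    mask = np.zeros(first.n_bins, dtype=bool)
    for m in matrices:
        mask |= m.mask
    return ContactMatrix(
        chrom=first.chrom,
        resolution=first.resolution,
        values=acc,
        mask=mask,
        kind=MatrixKind.RAW,
    )
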