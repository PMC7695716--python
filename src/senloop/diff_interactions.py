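"""Differential bin-pair interaction testing between two conditions.

The workflow follows the count-based differential-interaction framework:
bin pairs are filtered for low counts and diagonal entries, trended
(abundance-dependent) biases between libraries are removed with a
local-regression (loess) offset, and each pair is tested for a condition
effect under a negative-binomial model with empirically shrunk dispersions
and a quasi-likelihood-style F-test, followed by Benjamini-Hochberg
correction across all tested pairs.

All heavy steps are vectorized across pairs, so tables with 10^5-10^6 pairs
are testable in seconds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .contacts import ContactMatrix

__all__ = [
    "build_binpair_table",
    "normalize_trended",
    "test_differential",
    "run_differential",
]

_PRIOR_COUNT = 0.5


def build_binpair_table(
    cond1: list[ContactMatrix],
    cond2: list[ContactMatrix],
    min_total_count: int = 10,
) -> pd.DataFrame:
    """Assemble the per-pair count table from replicate matrices.

    Keeps intra-chromosomal upper-triangle pairs (i < j; the diagonal is
    excluded from testing) with total count across all replicates at least
    ``min_total_count``.  Columns ``c1_r0, c1_r1, ..., c2_r0, ...`` hold raw
    replicate counts.  Requires >= 2 replicates per condition so dispersion
    is estimable.
    """
    if len(cond1) < 2 or len(cond2) < 2:
        raise ValueError("need >= 2 replicates per condition to estimate dispersion")
    first = cond1[0]
    for m in cond1 + cond2:
        if m.n_bins != first.n_bins or m.resolution != first.resolution:
            raise ValueError("all replicate matrices must share the bin table")
    iu, ju = np.triu_indices(first.n_bins, k=1)
    live = first.unmasked()
    for m in cond1 + cond2:
        live &= m.unmasked()
    ok = live[iu] & live[ju]
    iu, ju = iu[ok], ju[ok]
    data = {"chrom": first.chrom, "bin_i": iu, "bin_j": ju}
    cols = []
    for c, reps in (("c1", cond1), ("c2", cond2)):
        for r, m in enumerate(reps):
            name = f"{c}_r{r}"
            data[name] = m.values[iu, ju]
            cols.append(name)
    df = pd.DataFrame(data)
    total = df[cols].sum(axis=1)
    df = df[total >= min_total_count].reset_index(drop=True)
    df.attrs["count_cols"] = cols
    df.attrs["n_rep"] = (len(cond1), len(cond2))
    df.attrs["resolution"] = first.resolution
    return df


def _count_columns(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    c1 = sorted(c for c in table.columns if c.startswith("c1_r"))
    c2 = sorted(c for c in table.columns if c.startswith("c2_r"))
    return c1, c2


def normalize_trended(
    table: pd.DataFrame, span: float = 0.3, min_pairs: int = 50
) -> pd.DataFrame:
    """Loess offsets removing trended biases between libraries.

    For each library, the log2 ratio of its counts to the per-pair geometric
    mean across libraries is smoothed against average log2 abundance with
    local regression; the smooth becomes a per-pair, per-library offset (log2
    units).  With fewer than ``min_pairs`` pairs a global median offset is
    used instead (with a warning).  Adds ``ave_logabundance`` and one
    ``offset_*`` column per count column.
    """
    out = table.copy()
    c1, c2 = _count_columns(out)
    cols = c1 + c2
    counts = out[cols].to_numpy(dtype=float)
    logs = np.log2(counts + _PRIOR_COUNT)
    ref = logs.mean(axis=1)  # log2 geometric mean across libraries
    out["ave_logabundance"] = ref
    small = len(out) < min_pairs
    if small:
        warnings.warn(
            f"only {len(out)} pairs; falling back to global median offsets",
            stacklevel=2,
        )
    for k, col in enumerate(cols):
        m = logs[:, k] - ref
        if small:
            off = np.full(len(out), np.median(m))
        else:
            order = np.argsort(ref, kind="stable")
            sm = lowess(
                m[order], ref[order], frac=span, it=2,
                delta=0.01 * (ref.max() - ref.min()), return_sorted=False
            )
            off = np.empty_like(sm)
            off[order] = sm
        out[f"offset_{col}"] = off
    out.attrs.update(table.attrs)
    return out


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Negative-binomial unit deviance, elementwise; Poisson limit at phi=0."""
    mu = np.maximum(mu, 1e-10)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), y.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        pois = term1 - (y - mu)
        size = 1.0 / np.maximum(phi, 1e-12)
        nb = term1 - (y + size) * np.log((y + size) / (mu + size))
        dev = np.where(phi > 0, nb, pois)
    return 2.0 * dev


def _trended_dispersion(
    counts: np.ndarray,
    sizes: np.ndarray,
    groups: np.ndarray,
    abundance: np.ndarray,
    n_bins: int = 20,
    prior_df: float = 10.0,
) -> np.ndarray:
    """Method-of-moments dispersion per pair, shrunk toward an abundance trend.

    Per pair, the within-group residual variance gives a raw quasi-dispersion
    estimate phi = max(0, (s^2 - mu)/mu^2) pooled over groups; the trend is
    the mean raw estimate per abundance bin, and each pair's estimate is
    squeezed toward the trend with weight ``prior_df`` against the residual
    degrees of freedom.
    """
    norm = counts / sizes  # normalized counts
    n_pairs = counts.shape[0]
    num = np.zeros(n_pairs)
    df = 0.0
    mu_bar = np.zeros(n_pairs)
    ng = 0
    for g in np.unique(groups):
        sel = groups == g
        x = norm[:, sel]
        mu = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        num += np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-10) ** 2, 0.0)
        df += sel.sum() - 1
        mu_bar += mu
        ng += 1
    raw = np.maximum(num / ng, 0.0)
    # abundance trend
    order = np.argsort(abundance, kind="stable")
    edges = np.linspace(0, n_pairs, n_bins + 1).astype(int)
    trend = np.empty(n_pairs)
    centers, means = [], []
    for b in range(n_bins):
        idx = order[edges[b] : edges[b + 1]]
        if idx.size == 0:
            continue
        centers.append(abundance[idx].mean())
        means.append(raw[idx].mean())
    centers = np.asarray(centers)
    means = np.asarray(means)
    trend = np.interp(abundance, centers, means)
    shrunk = (prior_df * trend + df * raw) / (prior_df + df)
    return np.maximum(shrunk, 1e-8)


def test_differential(
    table: pd.DataFrame, fdr: float = 0.05, prior_df: float = 10.0
) -> pd.DataFrame:
    """Quasi-likelihood-style NB test of the condition effect per bin pair.

    Group means are estimated with offset-normalized counts; the
    likelihood-ratio statistic between the common-mean and two-mean NB models
    (at the shrunk trended dispersion) is divided by an empirically shrunk
    quasi-dispersion factor and referred to an F distribution.  Adds
    ``logFC`` (condition2 over condition1, log2), ``pvalue``, ``fdr`` and
    ``significant`` columns; BH correction runs across all tested pairs.
    """
    c1, c2 = _count_columns(table)
    cols = c1 + c2
    counts = table[cols].to_numpy(dtype=float)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("pair with all-zero counts survived filtering")
    off_cols = [f"offset_{c}" for c in cols]
    if not all(c in table.columns for c in off_cols):
        raise ValueError("offsets missing: run normalize_trended first")
    offsets = table[off_cols].to_numpy(dtype=float)
    sizes = 2.0**offsets  # per-pair, per-library relative size factors
    groups = np.array([0] * len(c1) + [1] * len(c2))
    abundance = table["ave_logabundance"].to_numpy()

    phi = _trended_dispersion(counts, sizes, groups, abundance, prior_df=prior_df)

    # group means on the normalized scale (Poisson-consistent estimator)
    g1 = groups == 0
    g2 = groups == 1
    m1 = counts[:, g1].sum(axis=1) / sizes[:, g1].sum(axis=1)
    m2 = counts[:, g2].sum(axis=1) / sizes[:, g2].sum(axis=1)
    m0 = counts.sum(axis=1) / sizes.sum(axis=1)

    mu_alt = np.where(groups[None, :] == 0, m1[:, None], m2[:, None]) * sizes
    mu_null = m0[:, None] * sizes
    phi_mat = phi[:, None]
    dev_alt = _nb_deviance(counts, mu_alt, phi_mat).sum(axis=1)
    dev_null = _nb_deviance(counts, mu_null, phi_mat).sum(axis=1)
    lr = np.maximum(dev_null - dev_alt, 0.0)

    # quasi-dispersion: residual deviance over residual df, shrunk to its trend
    n_lib = counts.shape[1]
    df_resid = n_lib - 2
    s2_raw = dev_alt / df_resid
    order = np.argsort(abundance, kind="stable")
    nb_bins = 20
    edges = np.linspace(0, len(s2_raw), nb_bins + 1).astype(int)
    centers, meds = [], []
    for b in range(nb_bins):
        idx = order[edges[b] : edges[b + 1]]
        if idx.size:
            centers.append(abundance[idx].mean())
            meds.append(np.median(s2_raw[idx]))
    # median-based trend needs a chi-square consistency factor: the median of
    # deviance/df under the null sits below its mean
    consistency = stats.chi2.median(df_resid) / df_resid
    s2_trend = np.interp(abundance, np.asarray(centers), np.asarray(meds)) / consistency
    s2_trend = np.maximum(s2_trend, 1e-8)
    d0 = 2.0 * prior_df
    s2_post = (d0 * s2_trend + df_resid * s2_raw) / (d0 + df_resid)
    s2_post = np.maximum(s2_post, 1e-8)

    fstat = lr / s2_post
    df2 = df_resid + d0
    pvals = stats.f.sf(fstat, 1, df2)

    # symmetric fold change with prior counts so label swap negates exactly
    a1 = (counts[:, g1] / sizes[:, g1]).mean(axis=1)
    a2 = (counts[:, g2] / sizes[:, g2]).mean(axis=1)
    logfc = np.log2(a2 + _PRIOR_COUNT) - np.log2(a1 + _PRIOR_COUNT)

    out = table.copy()
    out["logFC"] = logfc
    out["pvalue"] = pvals
    out["fdr"] = _bh(pvals)
    out["significant"] = out["fdr"] < fdr
    out.attrs.update(table.attrs)
    return out


def _bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_differential(
    cond1: list[ContactMatrix],
    cond2: list[ContactMatrix],
    min_total_count: int = 10,
    fdr: float = 0.05,
    span: float = 0.3,
) -> pd.DataFrame:
    """Filter, normalize and test in one call; see the individual steps."""
    table = build_binpair_table(cond1, cond2, min_total_count=min_total_count)
    if len(table) == 0:
        return table
    table = normalize_trended(table, span=span)
    return test_differential(table, fdr=fdr)


def binpairs_to_bedpe(table: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Significant-pair table to BEDPE-style coordinates."""
    return pd.DataFrame(
        {
            "chrom1": table["chrom"],
            "start1": table["bin_i"] * resolution,
            "end1": (table["bin_i"] + 1) * resolution,
            "chrom2": table["chrom"],
            "start2": table["bin_j"] * resolution,
            "end2": (table["bin_j"] + 1) * resolution,
            "logFC": table.get("logFC"),
            "pvalue": table.get("pvalue"),
            "fdr": table.get("fdr"),
        }
    )
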