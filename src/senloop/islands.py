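"""Transcription-dependent cohesin islands.

Cohesin islands are wide (multi-kb), CTCF-independent cohesin accumulations
at the 3' ends of highly transcribed genes.  They are defined operationally
through an elongation-inhibition contrast: regions significantly losing
cohesin when transcription elongation is blocked (+DRB), wider than 2 kb.
Gene association goes through a 10 kb window downstream of the TES combined
with a high-expression filter; gene topology (isolated vs convergent)
controls how expression-stratified meta-profiles are centred.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .regions import overlaps_any
from .tracks import CoverageTrack

__all__ = [
    "call_islands",
    "associate_islands_to_genes",
    "classify_gene_topology",
    "metagene_tes_profile",
    "scaled_island_profile",
]


def call_islands(
    diffregions_vs_drb: pd.DataFrame,
    ctcf_peaks: pd.DataFrame,
    min_width: int = 2_000,
) -> pd.DataFrame:
    """Select islands from the +/-DRB differential-binding contrast.

    ``diffregions_vs_drb`` must come from comparing untreated (condition A)
    with elongation-inhibited (condition B) cohesin tracks, so an island is a
    ``loss``-direction region (signal vanishes under DRB) strictly wider than
    ``min_width``.  Each island records whether it touches a CTCF peak
    (expected false: islands are CTCF-independent) and its width.
    """
    if diffregions_vs_drb.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "width", "ctcf_overlap", "fdr"])
    lost = diffregions_vs_drb[diffregions_vs_drb["direction"] == "loss"].copy()
    lost["width"] = lost["end"] - lost["start"]
    lost = lost[lost["width"] > min_width].reset_index(drop=True)
    lost["ctcf_overlap"] = (
        overlaps_any(lost, ctcf_peaks) if not ctcf_peaks.empty
        else np.zeros(len(lost), dtype=bool)
    )
    return lost[["chrom", "start", "end", "width", "ctcf_overlap", "fdr"]]


def _tes_window(gene, window: int) -> tuple[int, int]:
    """Strand-directed [TES, TES + window) interval."""
    tes = int(gene["tes"]) if isinstance(gene, (pd.Series, dict)) else int(gene.tes)
    strand = gene["strand"] if isinstance(gene, (pd.Series, dict)) else gene.strand
    if strand == "+":
        return tes, tes + window
    return max(tes - window, 0), tes


def associate_islands_to_genes(
    islands: pd.DataFrame,
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    tes_window: int = 10_000,
    high_expr_threshold: float | None = None,
    expr_col: str = "mean_log_tpm",
) -> pd.DataFrame:
    """Map islands to host genes via downstream TES windows.

    A gene is associated when its strand-directed ``[TES, TES + 10 kb)``
    window overlaps an island and the gene clears the high-expression filter
    (default: top quartile of ``expr_col``).  Returns the island table with
    ``gene_id`` (None marks intergenic/enhancer-only islands).
    """
    expr = expression.set_index("gene_id")[expr_col]
    if high_expr_threshold is None:
        high_expr_threshold = float(np.quantile(expr.to_numpy(), 0.75))
    hosts: list[list[str]] = [[] for _ in range(len(islands))]
    for g in genes.itertuples():
        if expr.get(g.gene_id, -np.inf) < high_expr_threshold:
            continue
        ws, we = _tes_window(g, tes_window)
        sub = islands[(islands["chrom"] == g.chrom)
                      & (islands["start"] < we) & (islands["end"] > ws)]
        for i in sub.index:
            hosts[islands.index.get_loc(i)].append(g.gene_id)
    out = islands.copy()
    out["gene_id"] = [h[0] if h else None for h in hosts]
    out["all_hosts"] = [",".join(h) if h else "" for h in hosts]
    return out


def classify_gene_topology(genes: pd.DataFrame, extension: int = 10_000) -> pd.DataFrame:
    """Label genes isolated / convergent / other.

    Convergent: an opposite-strand pair whose strand-directed
    ``[TES, TES + extension)`` windows overlap (3' ends approaching each
    other).  Isolated: the gene body extended by ``extension`` on both sides
    overlaps no other gene.  Everything else is ``other``.
    """
    labels = pd.Series("other", index=genes.index, dtype=object)
    partner = pd.Series(None, index=genes.index, dtype=object)
    by_chrom = dict(tuple(genes.groupby("chrom", sort=False)))
    for chrom, sub in by_chrom.items():
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for i, gi in enumerate(sub.index):
            g = sub.loc[gi]
            ws, we = _tes_window(g, extension)
            conv = None
            for j, gj in enumerate(sub.index):
                if gi == gj or sub.loc[gj, "strand"] == g["strand"]:
                    continue
                os_, oe = _tes_window(sub.loc[gj], extension)
                if ws < oe and os_ < we:
                    conv = sub.loc[gj, "gene_id"]
                    break
            if conv is not None:
                labels[gi] = "convergent"
                partner[gi] = conv
                continue
            lo, hi = g["start"] - extension, g["end"] + extension
            touch = (starts < hi) & (ends > lo)
            touch[i] = False
            labels[gi] = "other" if touch.any() else "isolated"
    return pd.DataFrame({
        "gene_id": genes["gene_id"],
        "label": labels,
        "partner": partner,
    })


def _oriented_values(track: CoverageTrack, chrom: str, center: int, flank: int,
                     flip: bool) -> np.ndarray:
    step = track.step
    n_pts = 2 * (flank // step)
    v = track.data[chrom]
    i0 = center // step - n_pts // 2
    out = np.full(n_pts, np.nan)
    lo = max(i0, 0)
    hi = min(i0 + n_pts, len(v))
    out[lo - i0: hi - i0] = v[lo:hi]
    return out[::-1] if flip else out


def metagene_tes_profile(
    coverage: CoverageTrack,
    genes: pd.DataFrame,
    topology: pd.DataFrame,
    expression: pd.DataFrame,
    n_groups: int = 4,
    flank: int = 50_000,
    expr_col: str = "mean_log_tpm",
) -> tuple[np.ndarray, list[str]]:
    """Expression-stratified coverage profiles around gene 3' ends.

    Genes are grouped into ``n_groups`` expression quantiles (log-TPM);
    profiles are centred at the TES for isolated genes and at the midpoint
    between the two TESs for convergent pairs, with minus-strand genes
    flipped so downstream of the 3' end is always to the right.  Returns a
    (group x position) matrix of group means and the group names (low to
    high expression); empty groups are dropped with a warning.
    """
    topo = topology.set_index("gene_id")
    expr = expression.set_index("gene_id")[expr_col]
    gidx = genes.set_index("gene_id")
    chroms, centers, flips, levels = [], [], [], []
    seen_pairs = set()
    for g in genes.itertuples():
        lab = topo.loc[g.gene_id, "label"]
        if lab == "isolated":
            center, flip = int(g.tes), g.strand == "-"
        elif lab == "convergent":
            p = topo.loc[g.gene_id, "partner"]
            key = tuple(sorted((g.gene_id, p)))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            center, flip = int((g.tes + gidx.loc[p, "tes"]) // 2), False
        else:
            continue
        chroms.append(g.chrom)
        centers.append(center)
        flips.append(flip)
        levels.append(float(expr[g.gene_id]))
    levels = np.asarray(levels)
    qs = np.quantile(levels, np.linspace(0, 1, n_groups + 1))
    group_of = np.clip(np.searchsorted(qs, levels, side="right") - 1, 0, n_groups - 1)
    n_pts = 2 * (flank // coverage.step)
    profiles, names = [], []
    for gnum in range(n_groups):
        members = np.flatnonzero(group_of == gnum)
        if members.size == 0:
            warnings.warn(f"expression group {gnum} empty; dropped", stacklevel=2)
            continue
        acc = np.zeros(n_pts)
        cnt = np.zeros(n_pts)
        for m in members:
            vals = _oriented_values(coverage, chroms[m], centers[m], flank, flips[m])
            ok = ~np.isnan(vals)
            acc[ok] += vals[ok]
            cnt[ok] += 1
        profiles.append(np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan))
        names.append(f"q{gnum + 1}")
    return np.vstack(profiles), names


def scaled_island_profile(
    coverage: CoverageTrack,
    islands: pd.DataFrame,
    flank: int = 5_000,
    n_scaled_points: int = 50,
) -> np.ndarray:
    """Meta-profile over islands with bodies rescaled to a common length.

    Each island body is linearly interpolated onto ``n_scaled_points``; the
    flanks stay at native track resolution.  Returns the across-island mean
    profile (left flank, scaled body, right flank).
    """
    if islands.empty:
        raise ValueError("no islands to profile")
    step = coverage.step
    n_flank = flank // step
    profs = []
    for isl in islands.itertuples():
        v = coverage.data[isl.chrom]
        body = coverage.values_in(isl.chrom, isl.start, isl.end)
        x_old = np.linspace(0, 1, len(body))
        x_new = np.linspace(0, 1, n_scaled_points)
        body_scaled = np.interp(x_new, x_old, body)
        left = _flank_values(v, isl.start // step - n_flank, n_flank)
        right = _flank_values(v, -(-isl.end // step), n_flank)
        profs.append(np.concatenate([left, body_scaled, right]))
    return np.nanmean(np.vstack(profs), axis=0)


def _flank_values(v: np.ndarray, i0: int, n: int) -> np.ndarray:
    out = np.full(n, np.nan)
    lo = max(i0, 0)
    hi = min(i0 + n, len(v))
    if hi > lo:
        out[lo - i0: hi - i0] = v[lo:hi]
    return out
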