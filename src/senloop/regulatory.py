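"""Enhancer-promoter (EP) change annotation and cross-technology calibration.

Enhancers are active-mark peaks supported by chromatin accessibility, merged
when closer than 12.5 kb and cleared of promoter windows; promoters are 5 kb
windows around TSSs of differentially expressed genes.  Significant
differential bin pairs become EP interactions when one bin overlaps an
enhancer and the other a promoter.  Because binned genome-wide maps call EP
contacts less precisely than fragment-resolution capture maps, a calibration
step scans enhancer-size cutoffs and resolution subsets for the filter that
maximizes capture-supported calls minus capture-unsupported ones.
"""

from __future__ import annotations

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .regions import merge_intervals, overlaps_any, subtract_intervals

__all__ = [
    "define_enhancers",
    "define_promoters",
    "annotate_ep_changes",
    "calibrate_hic_filter",
    "ep_network_components",
    "directionality_correlation",
    "genes_dissociating_from_repressive_domains",
]

MAX_EP_SEPARATION = 2_000_000


def define_enhancers(
    active_mark_peaks: pd.DataFrame,
    accessibility_peaks: pd.DataFrame,
    promoter_windows: pd.DataFrame,
    merge_dist: int = 12_500,
) -> pd.DataFrame:
    """Enhancer set for one condition.

    Active-mark peaks overlapping at least one accessibility peak are merged
    when their gap is under ``merge_dist`` and promoter windows are
    subtracted.  Returns chrom/start/end/size with fresh enhancer ids.
    """
    if active_mark_peaks.empty:
        return pd.DataFrame(columns=["enhancer_id", "chrom", "start", "end", "size"])
    keep = active_mark_peaks[overlaps_any(active_mark_peaks, accessibility_peaks)]
    if keep.empty:
        return pd.DataFrame(columns=["enhancer_id", "chrom", "start", "end", "size"])
    merged = merge_intervals(keep, max_gap=merge_dist)
    if not promoter_windows.empty:
        merged = subtract_intervals(merged, promoter_windows)
    merged = merged.reset_index(drop=True)
    merged["size"] = merged["end"] - merged["start"]
    merged.insert(0, "enhancer_id", [f"enh_{i}" for i in range(len(merged))])
    return merged


def define_promoters(genes: pd.DataFrame, de_labels: pd.Series | dict) -> pd.DataFrame:
    """5 kb promoter windows (TSS +/- 2.5 kb) for DE genes only.

    ``genes`` needs gene_id/chrom/strand and either a ``tss`` column or
    start/end (strand-aware TSS).  Windows running past the chromosome start
    are truncated at 0.
    """
    g = genes.copy()
    if "tss" not in g.columns:
        g["tss"] = np.where(g["strand"] == "+", g["start"], g["end"])
    labels = pd.Series(de_labels)
    de = g[g["gene_id"].map(labels).isin(["up", "down"])]
    n_trunc = int((de["tss"] < 2_500).sum())
    if n_trunc:
        warnings.warn(f"{n_trunc} promoter window(s) truncated at chromosome start",
                      stacklevel=2)
    return pd.DataFrame({
        "gene_id": de["gene_id"],
        "chrom": de["chrom"],
        "start": np.maximum(de["tss"] - 2_500, 0),
        "end": de["tss"] + 2_500,
    }).reset_index(drop=True)


def _bin_interval(row, resolution):
    return row["bin_i"] * resolution, (row["bin_i"] + 1) * resolution, \
        row["bin_j"] * resolution, (row["bin_j"] + 1) * resolution


def annotate_ep_changes(
    diff_binpairs: pd.DataFrame,
    enhancers: pd.DataFrame,
    promoters: pd.DataFrame,
    resolution: int,
    source: str | None = None,
    max_separation: int = MAX_EP_SEPARATION,
) -> pd.DataFrame:
    """EP interactions among significant differential bin pairs.

    A pair is annotated when one bin overlaps >=1 enhancer and the other
    >=1 promoter; every enhancer x promoter combination is emitted.  Pairs
    separated by ``max_separation`` or more are dropped.
    """
    src = source or f"HiC_{resolution}"
    cols = ["enhancer_id", "gene_id", "chrom", "enh_start", "enh_end",
            "enhancer_size", "logFC", "fdr", "separation", "source"]
    sig = diff_binpairs
    if "significant" in sig.columns:
        sig = sig[sig["significant"]]
    rows = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        enh = enhancers[enhancers["chrom"] == chrom]
        prom = promoters[promoters["chrom"] == chrom]
        if enh.empty or prom.empty:
            continue
        es, ee = enh["start"].to_numpy(), enh["end"].to_numpy()
        ps, pe = prom["start"].to_numpy(), prom["end"].to_numpy()
        for r in sub.itertuples():
            sep = (r.bin_j - r.bin_i) * resolution
            if sep >= max_separation:
                continue
            b = [(r.bin_i * resolution, (r.bin_i + 1) * resolution),
                 (r.bin_j * resolution, (r.bin_j + 1) * resolution)]
            for (s1, e1), (s2, e2) in (b, b[::-1]):
                e_hit = np.flatnonzero((es < e1) & (ee > s1))
                p_hit = np.flatnonzero((ps < e2) & (pe > s2))
                for ei, pi in itertools.product(e_hit, p_hit):
                    erow = enh.iloc[ei]
                    rows.append((
                        erow["enhancer_id"], prom.iloc[pi]["gene_id"], chrom,
                        erow["start"], erow["end"],
                        erow.get("size", erow["end"] - erow["start"]),
                        getattr(r, "logFC", np.nan), getattr(r, "fdr", np.nan),
                        sep, src,
                    ))
    out = pd.DataFrame(rows, columns=cols)
    return out.drop_duplicates(subset=["enhancer_id", "gene_id", "source"]).reset_index(drop=True)


def _ep_keys(df: pd.DataFrame) -> set[tuple]:
    return set(zip(df["enhancer_id"], df["gene_id"]))


def calibrate_hic_filter(
    hic_ep_by_resolution: dict[int, pd.DataFrame],
    chic_ep: pd.DataFrame,
    candidate_size_cutoffs: list[float],
    candidate_resolution_sets: list[tuple[int, ...]] | None = None,
    captured_regions: pd.DataFrame | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Choose the enhancer-size cutoff and resolution subset for EP calls.

    For every candidate (cutoff, resolution subset) the binned-map EP calls
    restricted to enhancers strictly larger than the cutoff are compared with
    the capture baseline: ``score = |shared| - |binned-only|``, computed
    within the captured regions when given.  The highest score wins; ties go
    to the stricter filter (larger cutoff, then fewer/finer resolutions).
    Returns the chosen filter and the full score table.
    """
    if chic_ep.empty:
        raise ValueError("empty capture EP baseline")
    resolutions = sorted(hic_ep_by_resolution)
    if candidate_resolution_sets is None:
        candidate_resolution_sets = [
            tuple(resolutions[: k + 1]) for k in range(len(resolutions))
        ]

    def restrict(df):
        if captured_regions is None or df.empty or "enh_start" not in df.columns:
            return df
        iv = df.rename(columns={"enh_start": "start", "enh_end": "end"})
        return df[overlaps_any(iv[["chrom", "start", "end"]], captured_regions)]

    chic_keys = _ep_keys(restrict(chic_ep))
    rows = []
    for cutoff in candidate_size_cutoffs:
        for subset in candidate_resolution_sets:
            frames = [restrict(hic_ep_by_resolution[r]) for r in subset]
            merged = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
                columns=["enhancer_id", "gene_id", "enhancer_size"])
            merged = merged[merged["enhancer_size"] > cutoff]
            keys = _ep_keys(merged)
            shared = len(keys & chic_keys)
            hic_only = len(keys - chic_keys)
            rows.append({
                "size_cutoff": cutoff,
                "resolutions": subset,
                "shared": shared,
                "hic_only": hic_only,
                "score": shared - hic_only,
            })
    table = pd.DataFrame(rows)
    ranked = sorted(
        rows,
        key=lambda r: (-r["score"], -r["size_cutoff"], len(r["resolutions"]),
                       max(r["resolutions"])),
    )
    chosen = ranked[0]
    return chosen, table


def apply_ep_filter(
    hic_ep_by_resolution: dict[int, pd.DataFrame], chosen: dict
) -> pd.DataFrame:
    """Union of binned-map EP calls passing the calibrated filter."""
    frames = [hic_ep_by_resolution[r] for r in chosen["resolutions"]]
    merged = pd.concat(frames, ignore_index=True)
    merged = merged[merged["enhancer_size"] > chosen["size_cutoff"]]
    return merged.drop_duplicates(subset=["enhancer_id", "gene_id"]).reset_index(drop=True)


def combine_ep_sources(chic_ep: pd.DataFrame, hic_ep: pd.DataFrame) -> pd.DataFrame:
    """Merge capture and binned-map EP calls, keeping the capture record
    (finer resolution) when a pair is found by both."""
    both = pd.concat([chic_ep, hic_ep], ignore_index=True)
    return both.drop_duplicates(subset=["enhancer_id", "gene_id"], keep="first").reset_index(drop=True)


def ep_network_components(ep: pd.DataFrame) -> pd.DataFrame:
    """Connected components of the bipartite enhancer-promoter graph.

    Returns one row per component with node, enhancer, promoter and edge
    counts, largest first.
    """
    g = nx.Graph()
    for r in ep.itertuples():
        g.add_edge(("E", r.enhancer_id), ("P", r.gene_id))
    rows = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        n_e = sum(1 for n in comp if n[0] == "E")
        rows.append({
            "n_nodes": len(comp),
            "n_enhancers": n_e,
            "n_promoters": len(comp) - n_e,
            "n_edges": sub.number_of_edges(),
        })
    return pd.DataFrame(rows).sort_values("n_nodes", ascending=False).reset_index(drop=True)


def directionality_correlation(
    ep: pd.DataFrame,
    enhancer_activity_logfc: pd.Series | dict,
    gene_expression_logfc: pd.Series | dict,
) -> dict[str, tuple[float, float]]:
    """Pearson correlation of interaction change with activity and expression.

    Returns ``{"activity": (r, p), "expression": (r, p)}`` where the
    interaction log fold change is correlated against the enhancer's
    activity change and the target gene's expression change.
    """
    if len(ep) < 3:
        raise ValueError("need >= 3 EP pairs")
    act = pd.Series(enhancer_activity_logfc)
    expr = pd.Series(gene_expression_logfc)
    x = ep["logFC"].to_numpy(dtype=float)
    a = ep["enhancer_id"].map(act).to_numpy(dtype=float)
    e = ep["gene_id"].map(expr).to_numpy(dtype=float)
    out = {}
    for name, v in (("activity", a), ("expression", e)):
        if np.std(x) == 0 or np.std(v) == 0:
            raise ValueError(f"zero-variance input for {name} correlation")
        r, p = stats.pearsonr(v, x)
        out[name] = (float(r), float(p))
    return out


def genes_dissociating_from_repressive_domains(
    diff_binpairs: pd.DataFrame,
    genes: pd.DataFrame,
    repressive_regions: pd.DataFrame,
    de_labels: pd.Series | dict,
    resolution: int,
) -> list[str]:
    """Upregulated genes losing contact with repressive chromatin.

    A gene is listed when it is upregulated and at least one significantly
    *decreased* bin pair has one bin overlapping the gene body and the other
    overlapping a repressive (e.g. H3K27me3) region.
    """
    labels = pd.Series(de_labels)
    up = genes[genes["gene_id"].map(labels) == "up"]
    sig = diff_binpairs
    if "significant" in sig.columns:
        sig = sig[sig["significant"]]
    sig = sig[sig["logFC"] < 0]
    found = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        g = up[up["chrom"] == chrom]
        rep = repressive_regions[repressive_regions["chrom"] == chrom]
        if g.empty or rep.empty:
            continue
        gs, ge = g["start"].to_numpy(), g["end"].to_numpy()
        rs, re = rep["start"].to_numpy(), rep["end"].to_numpy()
        for r in sub.itertuples():
            b = [(r.bin_i * resolution, (r.bin_i + 1) * resolution),
                 (r.bin_j * resolution, (r.bin_j + 1) * resolution)]
            for (s1, e1), (s2, e2) in (b, b[::-1]):
                if not ((rs < e2) & (re > s2)).any():
                    continue
                for gi in np.flatnonzero((gs < e1) & (ge > s1)):
                    found.append(g.iloc[gi]["gene_id"])
    return sorted(set(found))
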