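"""ChIP-seq-style binding analysis: peaks, differential binding, loop context.

A simplified enrichment caller finds peaks as maximal runs of
signal-over-input enrichment; consensus keeps peaks supported by at least two
replicates.  Differential binding compares input-subtracted,
library-normalized signal between conditions in sliding windows with a
variance-moderated test, merges adjacent same-direction significant windows,
applies Benjamini-Hochberg correction and a minimum read floor.  Binding
changes are then classified against chromatin-loop geometry (at an anchor,
inside the span, or outside) and loop anchors are scored for co-binding by
two factors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diff_interactions import _bh
from .tracks import CoverageTrack

__all__ = [
    "call_peaks",
    "consensus_peaks",
    "diff_binding",
    "classify_changes_vs_loops",
    "anchor_binding_fraction",
]


def _smooth(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return x
    kernel = np.ones(k) / k
    return np.convolve(x, kernel, mode="same")


def call_peaks(
    signal: CoverageTrack,
    input_track: CoverageTrack,
    min_fold: float = 4.0,
    min_len: int = 400,
    smooth_steps: int = 3,
    prior: float = 1.0,
) -> pd.DataFrame:
    """Maximal runs of smoothed signal/input enrichment above ``min_fold``.

    The input is scaled to the signal's library size before the ratio; a
    small prior count regularizes empty input windows.  Runs shorter than
    ``min_len`` bp are dropped; the summit is the position of the run's
    maximum smoothed signal.
    """
    if not signal.same_grid(input_track):
        raise ValueError("signal and input tracks are on different grids")
    scale = signal.total() / max(input_track.total(), 1.0)
    rows = []
    step = signal.step
    for chrom, sig in signal.data.items():
        inp = input_track.data[chrom] * scale
        s = _smooth(sig, smooth_steps)
        i = _smooth(inp, smooth_steps)
        ratio = (s + prior) / (i + prior)
        above = ratio >= min_fold
        if not above.any():
            continue
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            starts = [0] + starts
        if above[-1]:
            ends = ends + [len(above)]
        for a, b in zip(starts, ends):
            if (b - a) * step < min_len:
                continue
            summit = a + int(np.argmax(s[a:b]))
            rows.append((chrom, a * step, b * step,
                         summit * step + step // 2, float(ratio[a:b].max())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "enrichment"])


def consensus_peaks(replicate_peak_sets: list[pd.DataFrame], min_support: int = 2) -> pd.DataFrame:
    """Merged union peaks supported by >= ``min_support`` replicates."""
    if len(replicate_peak_sets) < 2:
        raise ValueError("consensus requires >= 2 replicate peak sets")
    from .regions import merge_intervals

    union = pd.concat(
        [df[["chrom", "start", "end"]] for df in replicate_peak_sets], ignore_index=True
    )
    if union.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "support"])
    merged = merge_intervals(union)
    support = np.zeros(len(merged), dtype=int)
    for df in replicate_peak_sets:
        from .regions import overlaps_any

        support += overlaps_any(merged, df).astype(int)
    merged = merged.assign(support=support)
    return merged[merged["support"] >= min_support].reset_index(drop=True)


def _window_counts(track: CoverageTrack, window_bp: int) -> dict[str, np.ndarray]:
    steps_per_win = window_bp // track.step
    out = {}
    for chrom, v in track.data.items():
        n = len(v) // steps_per_win
        out[chrom] = v[: n * steps_per_win].reshape(n, steps_per_win).sum(axis=1)
    return out


def diff_binding(
    cond_a: list[CoverageTrack],
    input_a: CoverageTrack,
    cond_b: list[CoverageTrack],
    input_b: CoverageTrack,
    fdr: float = 0.05,
    min_reads: int = 100,
    window_bp: int = 200,
    smooth_windows: int = 3,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """Windowed differential-binding regions between two conditions.

    Per window, each replicate's signal is library-normalized and the scaled
    input subtracted; the square-root transform stabilizes the count variance
    and a variance-moderated two-sample t-test (pooled variance squeezed
    toward an abundance trend with ``prior_df`` prior degrees of freedom)
    tests the condition effect.  BH-significant adjacent windows of the same
    direction merge into regions; a region survives only if its maximum
    per-window read count (summed over replicates) reaches ``min_reads`` in
    at least one condition.  Direction ``gain`` means higher in ``cond_b``.
    """
    tracks = cond_a + cond_b
    for t in tracks[1:]:
        if not tracks[0].same_grid(t):
            raise ValueError("replicate tracks are on different grids")
    n_a, n_b = len(cond_a), len(cond_b)
    if n_a < 1 or n_b < 1:
        raise ValueError("need >= 1 replicate per condition")
    totals = np.array([t.total() for t in tracks])
    if (totals <= 0).any():
        raise ValueError("non-positive library size")

    win = {t_i: _window_counts(t, window_bp) for t_i, t in enumerate(tracks)}
    inw_a = _window_counts(input_a, window_bp)
    inw_b = _window_counts(input_b, window_bp)

    def _depth(wins_by_chrom, fallback_total):
        # robust depth estimate: median window count is insensitive to
        # localized condition-specific signal, unlike the total
        allw = np.concatenate(list(wins_by_chrom.values()))
        med = np.median(allw)
        return med if med > 0 else max(allw.mean(), fallback_total / max(len(allw), 1))

    depths = np.array([_depth(win[k], totals[k]) for k in range(len(tracks))])
    target = depths.mean()
    tot_in_a = _depth(inw_a, max(input_a.total(), 1.0))
    tot_in_b = _depth(inw_b, max(input_b.total(), 1.0))

    step = window_bp
    all_rows = []
    for chrom in cond_a[0].chroms:
        nw = len(win[0][chrom])
        y = np.empty((nw, n_a + n_b))
        raw = np.empty((nw, n_a + n_b))
        for k in range(n_a + n_b):
            sig = win[k][chrom]
            raw[:, k] = sig
            inw = inw_a[chrom] if k < n_a else inw_b[chrom]
            tot_in = tot_in_a if k < n_a else tot_in_b
            net = sig * (target / depths[k]) - inw * (target / tot_in)
            y[:, k] = _smooth(np.sqrt(np.maximum(net, 0.0)), smooth_windows)
        m_a = y[:, :n_a].mean(axis=1)
        m_b = y[:, n_a:].mean(axis=1)
        df_resid = n_a + n_b - 2
        if df_resid > 0:
            s2 = (y[:, :n_a].var(axis=1, ddof=1) * (n_a - 1)
                  + y[:, n_a:].var(axis=1, ddof=1) * (n_b - 1)) / df_resid
        else:
            s2 = np.zeros(nw)
        abundance = y.mean(axis=1)
        order = np.argsort(abundance, kind="stable")
        nb = 20
        edges = np.linspace(0, nw, nb + 1).astype(int)
        centers, meds = [], []
        for b in range(nb):
            idx = order[edges[b]: edges[b + 1]]
            if idx.size:
                centers.append(abundance[idx].mean())
                meds.append(np.median(s2[idx]) if df_resid > 0 else 0.25)
        s2_trend = np.interp(abundance, np.asarray(centers), np.asarray(meds))
        s2_trend = np.maximum(s2_trend, 1e-3)
        s2_post = (prior_df * s2_trend + df_resid * s2) / (prior_df + df_resid)
        se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
        tstat = (m_b - m_a) / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df_resid + prior_df)
        all_rows.append(pd.DataFrame({
            "chrom": chrom,
            "window": np.arange(nw),
            "p": pvals,
            "delta": m_b - m_a,
            "raw_a": raw[:, :n_a].sum(axis=1),
            "raw_b": raw[:, n_a:].sum(axis=1),
        }))
    table = pd.concat(all_rows, ignore_index=True)
    table["fdr"] = _bh(table["p"].to_numpy())
    table["sig"] = table["fdr"] < fdr

    regions = []
    for chrom, sub in table.groupby("chrom", sort=False):
        sub = sub.sort_values("window")
        cur = None
        for r in sub.itertuples():
            if not r.sig:
                if cur:
                    regions.append(cur)
                    cur = None
                continue
            direction = "gain" if r.delta > 0 else "loss"
            if cur and r.window == cur["wend"] and direction == cur["direction"]:
                cur["wend"] = r.window + 1
                cur["fdr"] = min(cur["fdr"], r.fdr)
                cur["max_a"] = max(cur["max_a"], r.raw_a)
                cur["max_b"] = max(cur["max_b"], r.raw_b)
            else:
                if cur:
                    regions.append(cur)
                cur = {"chrom": chrom, "wstart": r.window, "wend": r.window + 1,
                       "direction": direction, "fdr": r.fdr,
                       "max_a": r.raw_a, "max_b": r.raw_b}
        if cur:
            regions.append(cur)
    rows = []
    for reg in regions:
        max_reads = max(reg["max_a"], reg["max_b"])
        if max_reads < min_reads:
            continue
        rows.append((reg["chrom"], reg["wstart"] * step, reg["wend"] * step,
                     reg["direction"], reg["fdr"], max_reads))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "fdr", "max_reads"])


def classify_changes_vs_loops(
    diff_regions: pd.DataFrame, loops: pd.DataFrame, end_pad: int = 20_000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each binding change a category per loop: at_anchor/inside/outside.

    Loops carry BEDPE-style anchors (chrom, start1, end1, start2, end2); the
    change's midpoint falls ``at_anchor`` when within either anchor extended
    by ``end_pad`` on both sides, ``inside`` when within the loop span but
    not at an anchor, else ``outside``.  Also returns a per-loop summary
    counting gains/losses at anchors and inside.
    """
    cat_rows = []
    for li, loop in loops.iterrows():
        sub = diff_regions[diff_regions["chrom"] == loop["chrom"]]
        for ci, ch in sub.iterrows():
            mid = (ch["start"] + ch["end"]) // 2
            at1 = loop["start1"] - end_pad <= mid < loop["end1"] + end_pad
            at2 = loop["start2"] - end_pad <= mid < loop["end2"] + end_pad
            if at1 or at2:
                cat = "at_anchor"
            elif loop["start1"] <= mid < loop["end2"]:
                cat = "inside"
            else:
                cat = "outside"
            cat_rows.append((li, ci, ch.get("direction", ""), cat))
    cats = pd.DataFrame(cat_rows, columns=["loop", "change", "direction", "category"])
    summaries = []
    for li in loops.index:
        sub = cats[cats["loop"] == li]
        summaries.append({
            "loop": li,
            "loss_at_anchor": int(((sub["category"] == "at_anchor")
                                   & (sub["direction"] == "loss")).sum()),
            "gain_at_anchor": int(((sub["category"] == "at_anchor")
                                   & (sub["direction"] == "gain")).sum()),
            "loss_inside": int(((sub["category"] == "inside")
                                & (sub["direction"] == "loss")).sum()),
            "gain_inside": int(((sub["category"] == "inside")
                                & (sub["direction"] == "gain")).sum()),
        })
    return cats, pd.DataFrame(summaries)


def anchor_binding_fraction(
    loops: pd.DataFrame,
    peak_set_1: pd.DataFrame,
    peak_set_2: pd.DataFrame,
    tol: int = 10_000,
) -> float:
    """Fraction of loops with both anchors bound by both peak sets.

    An anchor counts as bound by a set when the nearest peak centre lies
    within ``tol`` bp of the anchor interval (distance 0 inside the anchor).
    """
    if loops.empty:
        return float("nan")

    def centers(df):
        return {c: ((g["start"] + g["end"]) // 2).to_numpy()
                for c, g in df.groupby("chrom")}

    c1, c2 = centers(peak_set_1), centers(peak_set_2)
    n_ok = 0
    for loop in loops.itertuples():
        ok = True
        for s, e in ((loop.start1, loop.end1), (loop.start2, loop.end2)):
            for cen in (c1, c2):
                pts = cen.get(loop.chrom, np.array([]))
                if pts.size == 0:
                    ok = False
                    break
                dist = np.where(pts < s, s - pts, np.where(pts >= e, pts - e + 1, 0))
                if dist.min() > tol:
                    ok = False
                    break
            if not ok:
                break
        n_ok += ok
    return n_ok / len(loops)
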