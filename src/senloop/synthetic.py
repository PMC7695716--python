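"""Synthetic two-condition chromatin dataset with planted ground truth.

Generates everything the analysis pipeline consumes — replicate contact
matrices, ChIP-seq-style coverage tracks with matched inputs, gene annotation
and expression tables — for a "growing" and a "senescent" condition, with
known (planted) compartments, TAD borders, loops, differential interactions,
enhancer-promoter changes, differentially expressed genes and
transcription-dependent cohesin islands.  Every stage draws from a child
seed spawned from one global seed, so stages can be regenerated
independently and identical config+seed yields identical output.

The contact model is a multiplicative expected-count surface — power-law
distance decay (exponent -1, flat beyond 2 Mb) x compartment checkerboard x
within-TAD enrichment x loop-pixel enrichment — sampled as negative binomial
counts.  Coverage tracks carry sharp (<=1 kb) CTCF-co-located peaks in every
condition and wide cohesin domains downstream of highly expressed genes that
appear only in the senescent condition and vanish under transcription
elongation inhibition (the +DRB tracks).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .tracks import CoverageTrack, DEFAULT_STEP

__all__ = [
    "SyntheticConfig",
    "TruthTables",
    "CONDITIONS",
    "simulate_annotation",
    "simulate_expression",
    "simulate_contacts",
    "simulate_coverage",
    "simulate_all",
    "simulate_count_table",
    "simulate_ep_calibration",
]

CONDITIONS = ("growing", "senescent")

_STAGES = ("annotation", "expression", "contacts", "coverage")


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions of the synthetic dataset (all coordinates in bp)."""

    n_chromosomes: int = 2
    chrom_length: int = 20_000_000
    resolutions: tuple[int, ...] = (100_000, 40_000, 20_000)
    n_replicates_per_condition: int = 2
    seed: int = 0
    compartment_block_size: int = 2_000_000
    n_tads: int = 10  # borders per chromosome
    n_loops: int = 10
    loop_strength: float = 3.0
    n_diff_interactions: int = 20
    diff_logfc: float = 2.0
    n_genes: int = 80
    fraction_convergent: float = 0.2
    n_islands: int = 10
    island_width_range: tuple[int, int] = (3_000, 18_000)
    noise_dispersion: float = 0.01
    library_size: int = 20_000_000
    # secondary knobs
    n_enhancers: int = 40
    n_de_genes: int = 20
    de_logfc: float = 2.0
    n_ep_changes: int = 8
    compartment_strength: float = 0.4
    tad_strength: float = 2.0
    coverage_step: int = DEFAULT_STEP
    background_rate: float = 2.0

    def __post_init__(self):
        lo, hi = self.island_width_range
        if not (2_000 < lo <= hi < 20_000 + 1):
            raise ValueError("island_width_range must lie within (2 kb, 20 kb)")
        for name in ("n_chromosomes", "n_genes", "n_loops", "n_islands",
                     "n_diff_interactions", "n_replicates_per_condition"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def rng(self, stage: str) -> np.random.Generator:
        """Child generator for a named stage, spawned from the global seed."""
        idx = _STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(_STAGES))[idx]
        return np.random.default_rng(child)


@dataclasses.dataclass
class TruthTables:
    """Planted ground truth, exported in 0-based half-open coordinates."""

    genes: pd.DataFrame | None = None
    enhancers: pd.DataFrame | None = None
    promoters: pd.DataFrame | None = None
    compartments: dict[str, np.ndarray] | None = None  # labels at 100 kb
    reference_activity: dict[str, np.ndarray] | None = None  # at 100 kb
    borders: dict[str, np.ndarray] | None = None  # bin indices at 40 kb
    loops: pd.DataFrame | None = None
    diff_pairs: pd.DataFrame | None = None
    ep_changes: pd.DataFrame | None = None
    islands: pd.DataFrame | None = None
    ctcf_sites: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None


class SizingError(ValueError):
    """The simulated genome cannot host a requested feature."""


# ---------------------------------------------------------------------------
# annotation


def _place_genes(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = config.chroms()
    n_conv = int(round(config.fraction_convergent * config.n_genes))
    n_conv -= n_conv % 2
    n_pairs = n_conv // 2
    n_single = config.n_genes - n_conv

    units: list[str] = ["pair"] * n_pairs + ["single"] * n_single
    rng.shuffle(units)
    per_chrom = np.array_split(np.arange(len(units)), config.n_chromosomes)

    rows = []
    gid = 0
    margin = 200_000
    for ci, chrom in enumerate(chroms):
        cursor = margin
        for ui in per_chrom[ci]:
            unit = units[ui]
            cursor += int(rng.integers(30_000, 100_000))
            if unit == "pair":
                l1 = int(rng.integers(10_000, 60_000))
                l2 = int(rng.integers(10_000, 60_000))
                tes_gap = int(rng.integers(1_000, 5_000))
                end = cursor + l1 + tes_gap + l2
                if end > config.chrom_length - margin:
                    raise SizingError(
                        f"convergent pair gene_{gid} does not fit on {chrom}: "
                        f"needs up to {end} bp of {config.chrom_length}"
                    )
                a, b = gid, gid + 1
                rows.append((f"gene_{a}", chrom, cursor, cursor + l1, "+",
                             "convergent", f"gene_{b}"))
                rows.append((f"gene_{b}", chrom, cursor + l1 + tes_gap, end, "-",
                             "convergent", f"gene_{a}"))
                gid += 2
                cursor = end
            else:
                l1 = int(rng.integers(10_000, 60_000))
                if cursor + l1 > config.chrom_length - margin:
                    raise SizingError(
                        f"gene_{gid} does not fit on {chrom}: needs up to "
                        f"{cursor + l1} bp of {config.chrom_length}"
                    )
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((f"gene_{gid}", chrom, cursor, cursor + l1, strand,
                             "isolated", None))
                gid += 1
                cursor += l1
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand",
                       "topology", "partner"]
    )
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    genes["tes"] = np.where(genes["strand"] == "+", genes["end"], genes["start"])
    return genes


def _tes_zone(gene) -> tuple[int, int]:
    """Downstream-of-TES zone where an island may live (+2 kb slop)."""
    if gene.strand == "+":
        return int(gene.tes) - 2_000, int(gene.tes) + 22_000
    return int(gene.tes) - 22_000, int(gene.tes) + 2_000


def _place_enhancers(
    config: SyntheticConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    per_chrom = -(-config.n_enhancers // config.n_chromosomes)
    eid = 0
    for chrom in config.chroms():
        sub = genes[genes["chrom"] == chrom].sort_values("start")
        starts = [200_000] + list(sub["end"])
        ends = list(sub["start"]) + [config.chrom_length - 200_000]
        gaps = [(s, e) for s, e in zip(starts, ends) if e - s >= 40_000]
        rng.shuffle(gaps)
        placed = 0
        for s, e in gaps:
            if placed >= per_chrom:
                break
            size = int(rng.integers(3_000, 12_000))
            if e - s < size + 24_000:
                continue
            lo = s + 12_000
            hi = e - 12_000 - size
            start = int(rng.integers(lo, hi + 1))
            rows.append((f"enh_{eid}", chrom, start, start + size, size))
            eid += 1
            placed += 1
    return pd.DataFrame(rows, columns=["enhancer_id", "chrom", "start", "end", "size"])


def _avoid(zones: list[tuple[int, int]], pos: int, pad: int = 0) -> bool:
    return any(lo - pad <= pos < hi + pad for lo, hi in zones)


def simulate_annotation(config: SyntheticConfig) -> TruthTables:
    """Genes, enhancers, compartments, borders, loops, CTCF sites.

    Genes are non-overlapping except designated convergent pairs (opposite
    strands, 3' ends within a <5 kb gap); enhancers sit in intergenic gaps
    with >=12 kb clearance so they never touch a promoter window.  Raises
    :class:`SizingError` naming the first feature the genome cannot host.
    """
    rng = config.rng("annotation")
    genes = _place_genes(config, rng)
    enhancers = _place_enhancers(config, genes, rng)

    # compartments: alternating A/B blocks on the 100 kb grid
    comp, ref = {}, {}
    n100 = -(-config.chrom_length // 100_000)
    bins_per_block = max(config.compartment_block_size // 100_000, 1)
    for chrom in config.chroms():
        phase = int(rng.integers(0, 2))
        block = (np.arange(n100) // bins_per_block + phase) % 2
        labels = np.where(block == 0, "A", "B")
        comp[chrom] = labels
        ref[chrom] = np.where(labels == "A", 2.0, 0.5) + rng.normal(0, 0.05, n100)

    # TAD borders on the 40 kb grid.  Compartment block edges insulate by
    # construction, so they are part of the planted border truth; additional
    # random borders keep >= 600 kb clearance from each other and the edges.
    borders = {}
    n40 = config.chrom_length // 40_000
    edge_step = max(config.compartment_block_size // 40_000, 1)
    for chrom in config.chroms():
        edges = list(range(edge_step, n40 - edge_step + 1, edge_step))
        pos = list(edges)
        extra, tries = 0, 0
        while extra < config.n_tads and tries < 10_000:
            cand = int(rng.integers(15, n40 - 15))
            if all(abs(cand - p) >= 15 for p in pos):
                pos.append(cand)
                extra += 1
            tries += 1
        if extra < config.n_tads:
            raise SizingError(f"cannot place {config.n_tads} TAD borders on {chrom}")
        borders[chrom] = np.array(sorted(pos), dtype=int)

    # forbidden zones for point features: downstream-of-TES island territory
    zones = {c: [] for c in config.chroms()}
    for g in genes.itertuples():
        zones[g.chrom].append(_tes_zone(g))

    # loops: anchor pairs snapped to 20 kb bin midpoints
    snap = 20_000
    loop_rows = []
    per_chrom = -(-config.n_loops // config.n_chromosomes)
    for chrom in config.chroms():
        placed, tries = 0, 0
        while placed < per_chrom and len(loop_rows) < config.n_loops and tries < 10_000:
            tries += 1
            sep = int(rng.integers(10, 61)) * snap  # 200 kb - 1.2 Mb
            a1 = (int(rng.integers(300_000, config.chrom_length - 300_000 - sep))
                  // snap) * snap + snap // 2
            a2 = a1 + sep
            if _avoid(zones[chrom], a1, 2_000) or _avoid(zones[chrom], a2, 2_000):
                continue
            # loops form within compartments: both anchors on the same label
            lab = comp[chrom]
            if lab[min(a1 // 100_000, len(lab) - 1)] != lab[min(a2 // 100_000, len(lab) - 1)]:
                continue
            if any(r[0] == chrom and abs(r[1] - a1) < 60_000 and abs(r[2] - a2) < 60_000
                   for r in loop_rows):
                continue
            loop_rows.append((chrom, a1, a2))
            placed += 1
    loops = pd.DataFrame(loop_rows, columns=["chrom", "anchor1", "anchor2"])
    loops["strength_growing"] = config.loop_strength
    loops["strength_senescent"] = config.loop_strength

    # CTCF sites: at loop anchors plus extras clear of TES zones
    ctcf_rows = [(r.chrom, int(r.anchor1)) for r in loops.itertuples()]
    ctcf_rows += [(r.chrom, int(r.anchor2)) for r in loops.itertuples()]
    for chrom in config.chroms():
        placed, tries = 0, 0
        while placed < 15 and tries < 10_000:
            tries += 1
            pos = int(rng.integers(250_000, config.chrom_length - 250_000))
            if _avoid(zones[chrom], pos, 2_000):
                continue
            ctcf_rows.append((chrom, pos))
            placed += 1
    ctcf = pd.DataFrame(ctcf_rows, columns=["chrom", "pos"]).sort_values(
        ["chrom", "pos"]).reset_index(drop=True)

    # generic differential interactions (EP-linked ones come with expression)
    n_generic = max(config.n_diff_interactions - config.n_ep_changes, 0)
    diff_rows = []
    tries = 0
    chrom_list = config.chroms()
    while len(diff_rows) < n_generic and tries < 20_000:
        tries += 1
        chrom = chrom_list[int(rng.integers(len(chrom_list)))]
        sep = int(rng.integers(5, 31)) * snap  # 100 kb - 600 kb
        p1 = (int(rng.integers(300_000, config.chrom_length - 300_000 - sep))
              // snap) * snap + snap // 2
        p2 = p1 + sep
        near_loop = any(
            r.chrom == chrom and abs(r.anchor1 - p1) < 50_000 and abs(r.anchor2 - p2) < 50_000
            for r in loops.itertuples()
        )
        clash = any(r[0] == chrom and abs(r[1] - p1) < 50_000 and abs(r[2] - p2) < 50_000
                    for r in diff_rows)
        if near_loop or clash:
            continue
        sign = 1.0 if len(diff_rows) % 2 == 0 else -1.0
        diff_rows.append((chrom, p1, p2, sign * config.diff_logfc, "generic"))
    diff_pairs = pd.DataFrame(
        diff_rows, columns=["chrom", "pos1", "pos2", "logfc", "kind"])

    return TruthTables(
        genes=genes,
        enhancers=enhancers,
        compartments=comp,
        reference_activity=ref,
        borders=borders,
        loops=loops,
        diff_pairs=diff_pairs,
        ctcf_sites=ctcf,
    )


# ---------------------------------------------------------------------------
# expression, islands, EP changes


def simulate_expression(config: SyntheticConfig, truth: TruthTables) -> TruthTables:
    """Per-gene TPM per condition, DE labels, islands, promoters, EP changes.

    Differentially expressed genes carry |planted log2 fold| >= 1 (default 2);
    island host genes are drawn overwhelmingly (9 of 10) from the top
    expression quartile, mirroring the observation that nearly all island
    hosts are highly expressed.
    """
    if truth.genes is None:
        raise ValueError("run simulate_annotation first")
    rng = config.rng("expression")
    genes = truth.genes
    n = len(genes)
    base = rng.lognormal(mean=3.0, sigma=1.2, size=n)
    labels = np.array(["ns"] * n, dtype=object)
    fold = np.zeros(n)
    n_de = min(config.n_de_genes, n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    for k, gi in enumerate(de_idx):
        sign = 1.0 if k % 2 == 0 else -1.0
        fold[gi] = sign * max(config.de_logfc, 1.0)
        labels[gi] = "up" if sign > 0 else "down"
    tpm1 = base
    tpm2 = base * 2.0 ** fold
    expression = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "tpm_growing": tpm1,
        "tpm_senescent": tpm2,
        "mean_log_tpm": np.log2(1 + (tpm1 + tpm2) / 2),
        "de_label": labels,
        "planted_log2fc": fold,
    })

    # islands: downstream of isolated genes' TES, hosts mostly top-quartile
    iso = genes.index[genes["topology"] == "isolated"].to_numpy()
    mlt = expression["mean_log_tpm"].to_numpy()
    thresh = np.quantile(mlt, 0.75)
    hi_pool = [i for i in iso if mlt[i] >= thresh]
    lo_pool = [i for i in iso if mlt[i] < thresh]
    rng.shuffle(hi_pool)
    rng.shuffle(lo_pool)
    k_high = min(int(np.ceil(0.9 * config.n_islands)), len(hi_pool))
    hosts = hi_pool[:k_high] + lo_pool[: config.n_islands - k_high]
    if len(hosts) < config.n_islands:
        raise SizingError("not enough isolated genes to host the requested islands")
    lo_w, hi_w = config.island_width_range
    rows = []
    for gi in hosts:
        g = genes.loc[gi]
        width = int(rng.integers(lo_w, hi_w + 1))
        if g["strand"] == "+":
            start = int(g["tes"]) + int(rng.integers(0, 2_000))
            rows.append((g["chrom"], start, start + width, g["gene_id"]))
        else:
            end = int(g["tes"]) - int(rng.integers(0, 2_000))
            rows.append((g["chrom"], end - width, end, g["gene_id"]))
    islands = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])

    # promoter windows for DE genes
    de = genes.loc[sorted(de_idx)].copy()
    promoters = pd.DataFrame({
        "gene_id": de["gene_id"],
        "chrom": de["chrom"],
        "start": np.maximum(de["tss"] - 2_500, 0),
        "end": de["tss"] + 2_500,
    }).reset_index(drop=True)

    # EP-linked differential interactions: enhancer center <-> DE gene TSS
    enh = truth.enhancers
    used_enh: set[str] = set()
    ep_rows, extra_diff = [], []
    order = list(np.array(sorted(de_idx))[rng.permutation(n_de)])
    for gi in order:
        if len(ep_rows) >= config.n_ep_changes:
            break
        g = genes.loc[gi]
        cands = enh[(enh["chrom"] == g["chrom"]) & (~enh["enhancer_id"].isin(used_enh))]
        if cands.empty:
            continue
        centers = (cands["start"] + cands["end"]) // 2
        dist = (centers - int(g["tss"])).abs()
        ok = cands[(dist >= 100_000) & (dist <= 600_000)]
        if ok.empty:
            continue
        e = ok.iloc[int(rng.integers(len(ok)))]
        used_enh.add(e["enhancer_id"])
        ec = int((e["start"] + e["end"]) // 2)
        p1, p2 = sorted((ec, int(g["tss"])))
        sign = 1.0 if labels[gi] == "up" else -1.0
        extra_diff.append((g["chrom"], p1, p2, sign * config.diff_logfc, "ep"))
        ep_rows.append((e["enhancer_id"], g["gene_id"], sign * config.diff_logfc))

    extra_df = pd.DataFrame(extra_diff,
                            columns=["chrom", "pos1", "pos2", "logfc", "kind"])
    if extra_df.empty:
        diff_pairs = truth.diff_pairs.copy()
    else:
        diff_pairs = pd.concat([truth.diff_pairs, extra_df], ignore_index=True)
    ep_changes = pd.DataFrame(ep_rows, columns=["enhancer_id", "gene_id", "logfc"])

    truth.expression = expression
    truth.islands = islands
    truth.promoters = promoters
    truth.diff_pairs = diff_pairs
    truth.ep_changes = ep_changes
    return truth


# ---------------------------------------------------------------------------
# contacts


def _expected_matrix(
    config: SyntheticConfig, truth: TruthTables, chrom: str, resolution: int,
    condition: str,
) -> np.ndarray:
    n = -(-config.chrom_length // resolution)
    idx = np.arange(n)
    mid = idx * resolution + resolution // 2
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    floor_bins = max(2_000_000 // resolution, 1)
    expected = 1.0 / np.maximum(np.minimum(d, floor_bins), 1.0)

    labels100 = truth.compartments[chrom]
    lab = labels100[np.minimum(mid // 100_000, len(labels100) - 1)]
    same = lab[:, None] == lab[None, :]
    cs = config.compartment_strength
    expected *= np.where(same, 1.0 + cs, 1.0 - cs)

    border_bp = truth.borders[chrom] * 40_000
    tad_id = np.searchsorted(border_bp, mid)
    expected *= np.where(tad_id[:, None] == tad_id[None, :], config.tad_strength, 1.0)

    scol = f"strength_{condition}"
    for r in truth.loops[truth.loops["chrom"] == chrom].itertuples():
        i, j = int(r.anchor1) // resolution, int(r.anchor2) // resolution
        if i != j:
            expected[i, j] *= getattr(r, scol)
            expected[j, i] = expected[i, j]
    if condition == CONDITIONS[1]:
        for r in truth.diff_pairs[truth.diff_pairs["chrom"] == chrom].itertuples():
            i, j = int(r.pos1) // resolution, int(r.pos2) // resolution
            if i != j:
                expected[i, j] *= 2.0 ** r.logfc
                expected[j, i] = expected[i, j]
    return expected


def simulate_contacts(
    config: SyntheticConfig, truth: TruthTables, resolution: int
) -> dict[str, list[dict[str, ContactMatrix]]]:
    """Replicate contact matrices per condition at one resolution.

    Expected counts are scaled so each replicate's unique-pixel total matches
    ``library_size``, then sampled as negative binomial with the configured
    dispersion (Poisson when the dispersion is 0).  Matrices are symmetric,
    integer and non-negative.
    """
    if truth.diff_pairs is None or truth.expression is None:
        raise ValueError("truth incomplete: run simulate_annotation and simulate_expression")
    rng = config.rng("contacts")
    out: dict[str, list[dict[str, ContactMatrix]]] = {}
    for condition in CONDITIONS:
        exp_by_chrom = {
            chrom: _expected_matrix(config, truth, chrom, resolution, condition)
            for chrom in config.chroms()
        }
        unique_total = sum(
            np.triu(e).sum() for e in exp_by_chrom.values()
        )
        scale = config.library_size / unique_total
        reps = []
        for _ in range(config.n_replicates_per_condition):
            mats = {}
            for chrom, e in exp_by_chrom.items():
                mu = e * scale
                if np.triu(mu).mean() < 0.01:
                    warnings.warn(
                        f"very sparse simulation on {chrom}: mean expected count "
                        f"{np.triu(mu).mean():.3g} per pixel", stacklevel=2)
                iu, ju = np.triu_indices(mu.shape[0])
                m = mu[iu, ju]
                phi = config.noise_dispersion
                if phi > 0:
                    size = 1.0 / phi
                    p = size / (size + m)
                    draws = rng.negative_binomial(size, np.clip(p, 1e-12, 1.0))
                else:
                    draws = rng.poisson(m)
                vals = np.zeros_like(mu)
                vals[iu, ju] = draws
                vals[ju, iu] = draws
                mats[chrom] = ContactMatrix(
                    chrom=chrom, resolution=resolution, values=vals)
            reps.append(mats)
        out[condition] = reps
    return out


# ---------------------------------------------------------------------------
# coverage


def _add_interval(rate: np.ndarray, start: int, end: int, step: int, value: float):
    i0 = max(int(start) // step, 0)
    i1 = min(-(-int(end) // step), len(rate))
    if i1 > i0:
        rate[i0:i1] += value


def island_height(mean_log_tpm: float) -> float:
    """Island plateau rate per step, monotone in host expression."""
    return 8.0 + 5.0 * mean_log_tpm


def _rate_tracks(
    config: SyntheticConfig, truth: TruthTables, condition: str, drb: bool
) -> dict[str, dict[str, np.ndarray]]:
    """Deterministic Poisson rate per track per chromosome."""
    step = config.coverage_step
    n_steps = -(-config.chrom_length // step)
    bg = config.background_rate
    rates = {
        name: {c: np.full(n_steps, bg) for c in config.chroms()}
        for name in ("cohesin", "ctcf", "active", "accessibility", "polymerase")
    }
    # sharp CTCF-co-located peaks, present in every condition and +/-DRB
    for r in truth.ctcf_sites.itertuples():
        for name, h in (("ctcf", 40.0), ("cohesin", 40.0)):
            _add_interval(rates[name][r.chrom], r.pos - 300, r.pos + 300, step, h)
    # cohesin islands: senescent, transcription-dependent (gone under DRB)
    if condition == CONDITIONS[1] and not drb:
        expr = truth.expression.set_index("gene_id")
        for r in truth.islands.itertuples():
            h = island_height(float(expr.loc[r.gene_id, "mean_log_tpm"]))
            _add_interval(rates["cohesin"][r.chrom], r.start, r.end, step, h)
    # enhancer activity and accessibility
    for r in truth.enhancers.itertuples():
        _add_interval(rates["active"][r.chrom], r.start, r.end, step, 15.0)
        c = (r.start + r.end) // 2
        _add_interval(rates["accessibility"][r.chrom], c - 500, c + 500, step, 25.0)
    # promoter-proximal marks and gene-body polymerase proxy
    tpm_col = f"tpm_{condition}"
    expr = truth.expression.set_index("gene_id")
    for g in truth.genes.itertuples():
        tpm = float(expr.loc[g.gene_id, tpm_col])
        _add_interval(rates["accessibility"][g.chrom], g.tss - 500, g.tss + 500,
                      step, 25.0)
        _add_interval(rates["active"][g.chrom], g.tss - 1_000, g.tss + 1_000,
                      step, 20.0)
        body_rate = 2.0 + 3.0 * np.log2(1 + tpm)
        if drb:  # elongation inhibited: polymerase stays promoter-proximal
            lo = g.tss if g.strand == "+" else g.tss - 1_000
            _add_interval(rates["polymerase"][g.chrom], lo, lo + 1_000, step, body_rate)
        else:
            _add_interval(rates["polymerase"][g.chrom], g.start, g.end, step, body_rate)
    return rates


def simulate_coverage(
    config: SyntheticConfig, truth: TruthTables, condition: str, drb: bool = False
) -> dict[str, object]:
    """Replicate coverage tracks (plus one flat-Poisson input) for a condition.

    Returns ``{track_name: [CoverageTrack per replicate], "input": CoverageTrack}``.
    Sharp CTCF-co-located peaks appear in every condition regardless of DRB;
    wide island domains appear only in the senescent condition without DRB,
    with plateau height monotone in host-gene expression.
    """
    if truth.expression is None:
        raise ValueError("truth incomplete: run simulate_expression first")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    # separate child stream per (condition, drb) so conditions are independent
    offset = CONDITIONS.index(condition) * 2 + int(drb)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(len(_STAGES))[
            _STAGES.index("coverage")].spawn(4)[offset]
    )
    rates = _rate_tracks(config, truth, condition, drb)
    step = config.coverage_step
    out: dict[str, object] = {}
    for name, per_chrom in rates.items():
        reps = []
        for _ in range(config.n_replicates_per_condition):
            data = {c: rng.poisson(r).astype(float) for c, r in per_chrom.items()}
            reps.append(CoverageTrack(step=step, data=data))
        out[name] = reps
    n_steps = -(-config.chrom_length // step)
    out["input"] = CoverageTrack(
        step=step,
        data={c: rng.poisson(config.background_rate, n_steps).astype(float)
              for c in config.chroms()},
    )
    return out


# ---------------------------------------------------------------------------
# convenience


@dataclasses.dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: TruthTables
    contacts: dict[int, dict[str, list[dict[str, ContactMatrix]]]]
    coverage: dict[tuple[str, bool], dict[str, object]]


def simulate_all(config: SyntheticConfig) -> SyntheticDataset:
    """Run every stage: annotation, expression, contacts, coverage."""
    truth = simulate_annotation(config)
    truth = simulate_expression(config, truth)
    contacts = {res: simulate_contacts(config, truth, res)
                for res in config.resolutions}
    coverage = {
        (CONDITIONS[0], False): simulate_coverage(config, truth, CONDITIONS[0], False),
        (CONDITIONS[1], False): simulate_coverage(config, truth, CONDITIONS[1], False),
        (CONDITIONS[1], True): simulate_coverage(config, truth, CONDITIONS[1], True),
    }
    return SyntheticDataset(config=config, truth=truth, contacts=contacts,
                            coverage=coverage)


# ---------------------------------------------------------------------------
# focused simulators for calibration studies


def simulate_count_table(
    n_pairs: int,
    n_rep: int = 2,
    mean_range: tuple[float, float] = (20.0, 400.0),
    dispersion: float = 0.05,
    n_changed: int = 0,
    change_log2fc: float = 2.0,
    changed_mean_range: tuple[float, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct NB bin-pair count table for testing calibration.

    Pairs share a common mean drawn log-uniformly from ``mean_range``; the
    first ``n_changed`` pairs (base means from ``changed_mean_range``, by
    default the bulk range) have condition 2 means multiplied by
    ``2**change_log2fc``.  Changed pairs should stay within the bulk
    abundance range after the fold, as trended normalization — like any
    between-library normalization — assumes changes are a minority at every
    abundance.  Returns a table shaped like
    :func:`~senloop.diff_interactions.build_binpair_table` output with a
    ``planted`` truth column.
    """
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_pairs))
    if n_changed and changed_mean_range is not None:
        mu[:n_changed] = np.exp(rng.uniform(
            np.log(changed_mean_range[0]), np.log(changed_mean_range[1]), n_changed))
    fc = np.ones(n_pairs)
    fc[:n_changed] = 2.0 ** change_log2fc
    data = {"chrom": "chr1",
            "bin_i": np.arange(n_pairs),
            "bin_j": np.arange(n_pairs) + 1}
    size = 1.0 / dispersion if dispersion > 0 else None

    def draw(m):
        if size is None:
            return rng.poisson(m)
        return rng.negative_binomial(size, size / (size + m))

    for r in range(n_rep):
        data[f"c1_r{r}"] = draw(mu)
    for r in range(n_rep):
        data[f"c2_r{r}"] = draw(mu * fc)
    df = pd.DataFrame(data)
    df["planted"] = np.arange(n_pairs) < n_changed
    return df


def simulate_ep_calibration(
    seed: int = 0,
    n_true_large: int = 20,
    n_true_small: int = 12,
    n_false_coarse: int = 15,
    size_cutoff: float = 7_500.0,
    resolutions: tuple[int, ...] = (10_000, 20_000, 30_000, 40_000, 60_000, 100_000),
) -> dict[str, object]:
    """Scenario for the cross-technology enhancer-promoter filter calibration.

    Plants a regime in which only enhancer-promoter calls involving enhancers
    larger than ``size_cutoff`` replicate between the fragment-resolution
    capture technology and binned genome-wide maps: the capture set contains
    exactly the large-enhancer truth, fine-resolution maps additionally call
    small-enhancer interactions absent from the capture baseline, and coarse
    resolutions add spurious large-enhancer calls.  Detection probabilities
    (0.95 capture / 0.9 fine-bin) model per-technology efficiency.
    """
    rng = np.random.default_rng(seed)
    records = []
    eid = 0
    for k in range(n_true_large + n_true_small):
        large = k < n_true_large
        size = float(rng.integers(8_000, 15_000)) if large else float(
            rng.integers(3_000, 7_000))
        records.append({
            "enhancer_id": f"enh_{eid}", "gene_id": f"gene_{k}",
            "enhancer_size": size, "true": True, "large": large,
        })
        eid += 1
    chic, hic = [], {r: [] for r in resolutions}
    fine = [r for r in resolutions if r <= 30_000]
    for rec in records:
        ep = (rec["enhancer_id"], rec["gene_id"], rec["enhancer_size"])
        if rec["large"] and rng.random() < 0.95:
            chic.append(ep)
        for r in fine:
            if rng.random() < 0.9:
                hic[r].append(ep)
    # coarse-resolution spurious calls: large enhancers, not in capture truth
    for k in range(n_false_coarse):
        size = float(rng.integers(8_000, 15_000))
        ep = (f"enh_{eid}", f"fp_gene_{k}", size)
        eid += 1
        for r in resolutions:
            if r > 30_000:
                hic[r].append(ep)
    truth_eps = {(r["enhancer_id"], r["gene_id"]) for r in records}
    return {
        "chic": chic,
        "hic_by_resolution": hic,
        "true_eps": truth_eps,
        "size_cutoff": size_cutoff,
        "resolutions": resolutions,
    }
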