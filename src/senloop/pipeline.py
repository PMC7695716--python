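"""End-to-end orchestration on synthetic (or pre-loaded) inputs.

``run_all`` executes the stages in dependency order — contact normalization,
compartments/TAD borders, differential interactions, binding analysis,
enhancer-promoter annotation, cohesin islands, aggregate neighbourhoods —
and returns a nested report of every count and table.  With planted truth
available, ``compare_to_truth`` adds precision/recall/F1 per feature class.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation as agg
from . import architecture as arch
from . import binding
from . import contacts as ct
from . import diff_interactions as di
from . import islands as isl
from . import regulatory as reg
from .synthetic import CONDITIONS, SyntheticConfig, SyntheticDataset, TruthTables, simulate_all

__all__ = ["run_all", "compare_to_truth", "write_report"]


def _combined_oe(reps: list[dict[str, ct.ContactMatrix]], quantile=0.05):
    chroms = reps[0].keys()
    out = {}
    for chrom in chroms:
        comb = ct.aggregate_replicates([r[chrom] for r in reps])
        f = ct.filter_low_coverage_bins(comb, quantile)
        b, _ = ct.ice_balance(f)
        out[chrom] = ct.distance_correct(b)
    return out


STAGES = ("architecture", "diff_interactions", "binding", "regulatory",
          "islands", "aggregation")
_STAGE_DEPS = {
    "regulatory": ("diff_interactions", "binding"),
    "islands": ("binding",),
    "aggregation": ("islands", "binding"),
}


def run_all(
    dataset: SyntheticDataset,
    diff_resolution: int = 20_000,
    border_window: int = 10,
    fdr: float = 0.05,
    stages: set[str] | None = None,
) -> dict:
    """Run the requested stages (default: all) in dependency order.

    Raises a named-stage error when a requested stage's upstream dependency
    is toggled off.
    """
    stages = set(STAGES) if stages is None else set(stages)
    unknown = stages - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in stages:
        for dep in _STAGE_DEPS.get(stage, ()):
            if dep not in stages:
                raise ValueError(f"stage '{stage}' requires stage '{dep}'")
    report: dict = {"seed": dataset.config.seed, "stages": {}, "_objects": {}}
    if "architecture" in stages:
        _run_architecture(dataset, report, border_window)
    if "diff_interactions" in stages:
        _run_diff(dataset, report, diff_resolution, fdr)
    if "binding" in stages:
        _run_binding(dataset, report, fdr)
    if "regulatory" in stages:
        _run_regulatory(dataset, report, diff_resolution)
    if "islands" in stages:
        _run_islands(dataset, report, fdr)
    if "aggregation" in stages:
        _run_aggregation(dataset, report)
    return report


def _run_architecture(dataset, report, border_window):
    cfg = dataset.config
    truth = dataset.truth
    g, s = CONDITIONS

    # --- architecture: compartments at 100 kb from combined obs/exp
    comp_scores = {}
    for cond in CONDITIONS:
        oe = _combined_oe(dataset.contacts[100_000][cond])
        comp_scores[cond] = {
            chrom: arch.compartment_scores(m, truth.reference_activity[chrom])
            for chrom, m in oe.items()
        }
    report["stages"]["compartments"] = {
        cond: {chrom: int(np.sum(track.scores > 0))
               for chrom, track in comp_scores[cond].items()}
        for cond in CONDITIONS
    }

    # --- TAD borders at 40 kb: per replicate, then per-condition consensus
    consensus = {}
    for cond in CONDITIONS:
        per_rep: dict[str, list[arch.BorderSet]] = {}
        for rep in dataset.contacts[40_000][cond]:
            for chrom, m in rep.items():
                f = ct.filter_low_coverage_bins(m, 0.05)
                b, _ = ct.ice_balance(f)
                per_rep.setdefault(chrom, []).append(
                    arch.call_borders(b, border_window))
        consensus[cond] = {
            chrom: arch.consensus_borders(sets, min_score=7, tolerance_bins=1)
            for chrom, sets in per_rep.items()
        }
    n40 = -(-cfg.chrom_length // 40_000)
    nmi = {
        chrom: arch.border_nmi(consensus[g][chrom], consensus[s][chrom], n40)
        for chrom in cfg.chroms()
    }
    report["stages"]["borders"] = {
        "n_consensus": {cond: {c: len(b) for c, b in consensus[cond].items()}
                        for cond in CONDITIONS},
        "nmi_growing_vs_senescent": nmi,
    }
    report["_objects"]["consensus_borders"] = consensus
    report["_objects"]["compartments"] = comp_scores


def _run_diff(dataset, report, diff_resolution, fdr):
    cfg = dataset.config
    g, s = CONDITIONS
    # --- differential interactions at diff_resolution
    tables = []
    for chrom in cfg.chroms():
        c1 = [rep[chrom] for rep in dataset.contacts[diff_resolution][g]]
        c2 = [rep[chrom] for rep in dataset.contacts[diff_resolution][s]]
        tables.append(di.build_binpair_table(c1, c2))
    table = pd.concat(tables, ignore_index=True)
    table = di.normalize_trended(table)
    table = di.test_differential(table, fdr=fdr)
    sig = table[table["significant"]]
    report["stages"]["diff_interactions"] = {
        "resolution": diff_resolution,
        "n_tested": int(len(table)),
        "n_significant": int(len(sig)),
        "n_up": int((sig["logFC"] > 0).sum()),
        "n_down": int((sig["logFC"] < 0).sum()),
    }
    report["_objects"]["diff_table"] = table
    report["_objects"]["significant_pairs"] = sig
    report["_objects"]["diff_resolution"] = diff_resolution


def _run_binding(dataset, report, fdr):
    truth = dataset.truth
    g, s = CONDITIONS
    # --- binding: consensus peaks and differential binding (cohesin)
    peaks = {}
    for cond in CONDITIONS:
        cov = dataset.coverage[(cond, False)]
        for name in ("cohesin", "ctcf", "active", "accessibility"):
            reps = [binding.call_peaks(tr, cov["input"]) for tr in cov[name]]
            peaks[(cond, name)] = binding.consensus_peaks(reps)
    diffbind = binding.diff_binding(
        dataset.coverage[(g, False)]["cohesin"], dataset.coverage[(g, False)]["input"],
        dataset.coverage[(s, False)]["cohesin"], dataset.coverage[(s, False)]["input"],
        fdr=fdr,
    )
    loops_bedpe = pd.DataFrame({
        "chrom": truth.loops["chrom"],
        "start1": truth.loops["anchor1"] - 10_000,
        "end1": truth.loops["anchor1"] + 10_000,
        "start2": truth.loops["anchor2"] - 10_000,
        "end2": truth.loops["anchor2"] + 10_000,
    })
    cats, loop_summary = binding.classify_changes_vs_loops(diffbind, loops_bedpe)
    bound_frac = binding.anchor_binding_fraction(
        loops_bedpe, peaks[(s, "cohesin")], peaks[(s, "ctcf")])
    report["stages"]["binding"] = {
        "n_consensus_peaks": {f"{c}_{n}": int(len(p))
                              for (c, n), p in peaks.items()},
        "n_diff_regions": int(len(diffbind)),
        "n_gain": int((diffbind["direction"] == "gain").sum()),
        "n_loss": int((diffbind["direction"] == "loss").sum()),
        "loop_category_counts": cats["category"].value_counts().to_dict(),
        "anchor_binding_fraction": float(bound_frac),
    }
    report["_objects"]["peaks"] = peaks
    report["_objects"]["diffbind"] = diffbind
    report["_objects"]["loop_summary"] = loop_summary


def _run_regulatory(dataset, report, diff_resolution):
    truth = dataset.truth
    peaks = report["_objects"]["peaks"]
    sig = report["_objects"]["significant_pairs"]
    # --- regulatory: enhancers, promoters, EP annotation
    prom = reg.define_promoters(
        truth.genes, truth.expression.set_index("gene_id")["de_label"])
    enh_sets = []
    for cond in CONDITIONS:
        enh_sets.append(reg.define_enhancers(
            peaks[(cond, "active")], peaks[(cond, "accessibility")], prom))
    enh = pd.concat(enh_sets, ignore_index=True)
    enh = enh.drop_duplicates(subset=["chrom", "start", "end"]).reset_index(drop=True)
    enh["enhancer_id"] = [f"enh_{i}" for i in range(len(enh))]
    ep = reg.annotate_ep_changes(sig, enh, prom, diff_resolution)
    comps = reg.ep_network_components(ep)
    report["stages"]["regulatory"] = {
        "n_enhancers": int(len(enh)),
        "n_promoters": int(len(prom)),
        "n_ep_interactions": int(len(ep)),
        "n_network_components": int(len(comps)),
        "largest_component_nodes": int(comps["n_nodes"].max()) if len(comps) else 0,
    }
    report["_objects"]["ep"] = ep
    report["_objects"]["enhancers"] = enh
    report["_objects"]["promoters"] = prom


def _run_islands(dataset, report, fdr):
    truth = dataset.truth
    peaks = report["_objects"]["peaks"]
    g, s = CONDITIONS
    # --- cohesin islands from the +/-DRB contrast in the senescent condition
    cov_ris = dataset.coverage[(s, False)]
    cov_drb = dataset.coverage[(s, True)]
    drb_diff = binding.diff_binding(
        cov_ris["cohesin"], cov_ris["input"],
        cov_drb["cohesin"], cov_drb["input"], fdr=fdr)
    called_islands = isl.call_islands(drb_diff, peaks[(s, "ctcf")])
    assoc = isl.associate_islands_to_genes(
        called_islands, truth.genes, truth.expression)
    topo = isl.classify_gene_topology(truth.genes)
    report["stages"]["islands"] = {
        "n_islands": int(len(called_islands)),
        "widths": [int(w) for w in called_islands["width"]],
        "n_ctcf_overlapping": int(called_islands["ctcf_overlap"].sum()),
        "n_gene_associated": int(assoc["gene_id"].notna().sum()),
        "topology_counts": topo["label"].value_counts().to_dict(),
    }
    report["_objects"]["islands"] = called_islands
    report["_objects"]["island_assoc"] = assoc


def _run_aggregation(dataset, report):
    g, s = CONDITIONS
    peaks = report["_objects"]["peaks"]
    called_islands = report["_objects"]["islands"]
    # --- aggregate neighbourhoods on combined obs/exp matrices at 20 kb
    oe = {cond: _combined_oe(dataset.contacts[20_000][cond]) for cond in CONDITIONS}
    pairs = agg.island_peak_pairs(called_islands, peaks[(s, "cohesin")])
    aggs = {}
    for cond in CONDITIONS:
        subs = [
            agg.extract_neighborhood(oe[cond][r.chrom], (r.pos1, r.pos2))
            for r in pairs.itertuples() if r.chrom in oe[cond]
        ]
        aggs[cond] = (agg.aggregate_neighborhoods(subs) if subs else None)
    diff_agg = (agg.differential_aggregate(aggs[g], aggs[s])
                if aggs[g] is not None and aggs[s] is not None else None)
    report["stages"]["aggregation"] = {
        "n_anchor_pairs": int(len(pairs)),
        "shape": list(aggs[s].values.shape) if aggs[s] is not None else None,
        "center_diff": (float(diff_agg[5, 5]) if diff_agg is not None else None),
    }
    report["_objects"]["aggregates"] = aggs
    report["_objects"]["diff_aggregate"] = diff_agg


def _interval_prf(called: pd.DataFrame, planted: pd.DataFrame) -> dict:
    """Precision/recall/F1 by interval overlap."""
    if len(called) == 0:
        return {"precision": None, "recall": 0.0, "f1": 0.0,
                "n_called": 0, "n_planted": int(len(planted))}
    from .regions import overlaps_any

    tp_called = overlaps_any(called[["chrom", "start", "end"]],
                             planted[["chrom", "start", "end"]]).sum()
    tp_planted = overlaps_any(planted[["chrom", "start", "end"]],
                              called[["chrom", "start", "end"]]).sum()
    precision = tp_called / len(called)
    recall = tp_planted / len(planted) if len(planted) else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"precision": float(precision), "recall": float(recall),
            "f1": float(f1), "n_called": int(len(called)),
            "n_planted": int(len(planted))}


def compare_to_truth(report: dict, truth: TruthTables, config: SyntheticConfig,
                     diff_resolution: int = 20_000) -> dict:
    """Precision/recall metrics of every called feature class vs planted truth."""
    objs = report["_objects"]
    metrics: dict = {}

    if "compartments" in objs:
        # compartments: sign agreement (senescent condition shown)
        agree, total = 0, 0
        for chrom, track in objs["compartments"][CONDITIONS[1]].items():
            labels = truth.compartments[chrom]
            ok = ~np.isnan(track.scores)
            called = np.where(track.scores > 0, "A", "B")
            agree += int((called[ok] == labels[ok]).sum())
            total += int(ok.sum())
        metrics["compartment_sign_agreement"] = agree / total if total else None

    if "consensus_borders" in objs:
        # borders: +/-1 bin matching on consensus of the senescent condition
        tp = fp = fn = 0
        for chrom, bset in objs["consensus_borders"][CONDITIONS[1]].items():
            planted = truth.borders[chrom]
            matched_planted = np.zeros(len(planted), dtype=bool)
            for c in bset.positions:
                d = np.abs(planted - c)
                if len(d) and d.min() <= 1:
                    matched_planted[np.argmin(d)] = True
                else:
                    fp += 1
            tp += int(matched_planted.sum())
            fn += int((~matched_planted).sum())
        prec = tp / (tp + fp) if tp + fp else None
        rec = tp / (tp + fn) if tp + fn else None
        metrics["border_precision"] = prec
        metrics["border_recall"] = rec
        metrics["border_f1"] = (2 * prec * rec / (prec + rec)
                                if prec and rec and prec + rec > 0 else 0.0)

    if "significant_pairs" in objs:
        # differential interactions: planted pixel recovery
        sig = objs["significant_pairs"]
        called_pix = set(zip(sig["chrom"], sig["bin_i"], sig["bin_j"]))
        planted_pix = set()
        for r in truth.diff_pairs.itertuples():
            i, j = int(r.pos1) // diff_resolution, int(r.pos2) // diff_resolution
            planted_pix.add((r.chrom, min(i, j), max(i, j)))
        tp = len(called_pix & planted_pix)
        metrics["diff_interaction_recall"] = (tp / len(planted_pix)
                                              if planted_pix else None)
        metrics["diff_interaction_precision"] = (tp / len(called_pix)
                                                 if called_pix else None)

    if "ep" in objs:
        # EP changes: planted target genes recovered
        called_genes = set(objs["ep"]["gene_id"])
        planted_genes = set(truth.ep_changes["gene_id"])
        metrics["ep_gene_recall"] = (len(called_genes & planted_genes)
                                     / len(planted_genes) if planted_genes else None)

    if "islands" in objs:
        metrics["islands"] = _interval_prf(objs["islands"], truth.islands)
    return metrics


def write_report(report: dict, metrics: dict | None, outdir) -> Path:
    """Serialize the report (without heavy objects) as JSON + markdown."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    slim = {k: v for k, v in report.items() if not k.startswith("_")}
    if metrics is not None:
        slim["truth_metrics"] = metrics
    p = out / "report.json"
    with open(p, "w") as fh:
        json.dump(slim, fh, indent=2, sort_keys=True, default=str)
    lines = ["# senloop run report", ""]
    for stage, content in slim.get("stages", {}).items():
        lines.append(f"## {stage}")
        lines.append("```json")
        lines.append(json.dumps(content, indent=2, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))
    return p
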