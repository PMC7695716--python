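import numpy as np
import pandas as pd
import pytest

from senloop.regulatory import (annotate_ep_changes, apply_ep_filter,
                                calibrate_hic_filter, combine_ep_sources,
                                define_enhancers, define_promoters,
                                directionality_correlation,
                                ep_network_components,
                                genes_dissociating_from_repressive_domains)
from senloop.synthetic import simulate_ep_calibration


def iv(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestDefineEnhancers:
    def test_no_accessibility_overlap_excluded(self):
        active = iv(("chr1", 0, 1000))
        acc = iv(("chr1", 5000, 6000))
        out = define_enhancers(active, acc, iv())
        assert len(out) == 0

    def test_gap_below_merge_distance_merged(self):
        active = iv(("chr1", 0, 1000), ("chr1", 13000, 14000))
        acc = active.copy()
        out = define_enhancers(active, acc, iv(), merge_dist=12_500)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 0 and out.iloc[0]["end"] == 14000
        assert out.iloc[0]["size"] == 14000

    def test_gap_above_merge_distance_not_merged(self):
        active = iv(("chr1", 0, 1000), ("chr1", 14000, 15000))
        acc = active.copy()
        out = define_enhancers(active, acc, iv(), merge_dist=12_500)
        assert len(out) == 2

    def test_promoter_windows_subtracted(self):
        active = iv(("chr1", 0, 10_000))
        prom = iv(("chr1", 4000, 6000))
        out = define_enhancers(active, active.copy(), prom)
        assert len(out) == 2
        assert not ((out["start"] < 6000) & (out["end"] > 4000)).any()


GENES = pd.DataFrame({
    "gene_id": ["g1", "g2", "g3"],
    "chrom": ["chr1"] * 3,
    "start": [10_000, 50_000, 90_000],
    "end": [20_000, 60_000, 100_000],
    "strand": ["+", "-", "+"],
})


class TestDefinePromoters:
    def test_only_de_genes_get_windows(self):
        out = define_promoters(GENES, {"g1": "up", "g2": "ns", "g3": "down"})
        assert set(out["gene_id"]) == {"g1", "g3"}

    def test_minus_strand_window_centred_on_interval_end(self):
        out = define_promoters(GENES, {"g2": "down"})
        assert out.iloc[0]["start"] == 57_500 and out.iloc[0]["end"] == 62_500

    def test_window_truncated_at_chromosome_start(self):
        g = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "start": [1000],
                          "end": [9000], "strand": ["+"]})
        out = define_promoters(g, {"g": "up"})
        assert out.iloc[0]["start"] == 0


def sig_pairs(rows, cols=("chrom", "bin_i", "bin_j", "logFC", "fdr")):
    df = pd.DataFrame(rows, columns=list(cols))
    df["significant"] = True
    return df


ENH = pd.DataFrame({
    "enhancer_id": ["e1", "e2"],
    "chrom": ["chr1", "chr1"],
    "start": [100_000, 105_000],
    "end": [103_000, 109_000],
    "size": [3000, 4000],
})
PROM = pd.DataFrame({
    "gene_id": ["g1"],
    "chrom": ["chr1"],
    "start": [502_500],
    "end": [507_500],
})


class TestAnnotateEP:
    def test_enhancer_enhancer_pair_not_emitted(self):
        # both bins cover only enhancers; the promoter sits elsewhere
        pairs = sig_pairs([("chr1", 10, 10, 1.0, 0.01)])
        out = annotate_ep_changes(
            pairs, ENH, PROM.assign(start=900_000, end=905_000),
            resolution=10_000)
        assert len(out) == 0

    def test_two_enhancers_one_promoter_two_records(self):
        pairs = sig_pairs([("chr1", 10, 50, 1.5, 0.01)])
        out = annotate_ep_changes(pairs, ENH, PROM, resolution=10_000)
        assert len(out) == 2
        assert set(out["enhancer_id"]) == {"e1", "e2"}
        assert (out["gene_id"] == "g1").all()

    def test_separation_cap_applied(self):
        pairs = sig_pairs([("chr1", 10, 250, 1.5, 0.01)])
        prom_far = PROM.assign(start=2_502_500, end=2_507_500)
        out = annotate_ep_changes(pairs, ENH, prom_far, resolution=10_000)
        assert len(out) == 0

    def test_planted_truth_recovered_at_fragment_resolution(self, small_dataset):
        truth = small_dataset.truth
        res = 5_000
        rows = []
        for r in truth.diff_pairs[truth.diff_pairs["kind"] == "ep"].itertuples():
            rows.append((r.chrom, r.pos1 // res, r.pos2 // res, r.logfc, 1e-6))
        pairs = sig_pairs(rows)
        out = annotate_ep_changes(pairs, truth.enhancers, truth.promoters, res,
                                  source="cHiC_fragment")
        planted = set(zip(truth.ep_changes["enhancer_id"],
                          truth.ep_changes["gene_id"]))
        called = set(zip(out["enhancer_id"], out["gene_id"]))
        assert planted <= called


def _ep_df(entries):
    return pd.DataFrame(
        [{"enhancer_id": e, "gene_id": g, "enhancer_size": s}
         for e, g, s in entries])


class TestCalibrateFilter:
    def test_objective_prefers_fewer_hic_only(self):
        chic = _ep_df([(f"e{i}", f"g{i}", 9000) for i in range(5)])
        # resolution 10: the 5 shared plus 1 spurious; resolution 20: 3 spurious
        hic = {
            10_000: _ep_df([(f"e{i}", f"g{i}", 9000) for i in range(5)]
                           + [("x1", "gx1", 9000)]),
            20_000: _ep_df([(f"x{i}", f"gx{i}", 9000) for i in range(1, 4)]),
        }
        chosen, table = calibrate_hic_filter(hic, chic, [0.0])
        assert chosen["resolutions"] == (10_000,)
        assert chosen["shared"] == 5 and chosen["hic_only"] == 1

    def test_tie_broken_toward_stricter_filter(self):
        chic = _ep_df([("e1", "g1", 9000)])
        hic = {10_000: _ep_df([("e1", "g1", 9000)])}
        chosen, table = calibrate_hic_filter(hic, chic, [5000.0, 7500.0])
        # both cutoffs keep the single shared call; larger cutoff wins the tie
        assert chosen["size_cutoff"] == 7500.0

    def test_synthetic_regime_selects_7500_and_fine_resolutions(self):
        scen = simulate_ep_calibration(seed=0)
        hic = {r: _ep_df(v) for r, v in scen["hic_by_resolution"].items()}
        chic = _ep_df(scen["chic"])
        chosen, table = calibrate_hic_filter(
            hic, chic, candidate_size_cutoffs=[5000.0, 7500.0, 10_000.0])
        assert chosen["size_cutoff"] == 7500.0
        assert max(chosen["resolutions"]) <= 30_000

    def test_filtered_precision_at_least_unfiltered(self):
        scen = simulate_ep_calibration(seed=1)
        hic = {r: _ep_df(v) for r, v in scen["hic_by_resolution"].items()}
        chic = _ep_df(scen["chic"])
        chosen, _ = calibrate_hic_filter(
            hic, chic, candidate_size_cutoffs=[5000.0, 7500.0, 10_000.0])
        filtered = apply_ep_filter(hic, chosen)
        unfiltered = pd.concat(hic.values(), ignore_index=True).drop_duplicates(
            subset=["enhancer_id", "gene_id"])
        truth = scen["true_eps"]

        def precision(df):
            keys = set(zip(df["enhancer_id"], df["gene_id"]))
            return len(keys & truth) / len(keys)

        assert precision(filtered) >= precision(unfiltered)

    def test_spurious_hic_only_never_improves_score(self):
        chic = _ep_df([("e1", "g1", 9000)])
        base = {10_000: _ep_df([("e1", "g1", 9000)])}
        more = {10_000: _ep_df([("e1", "g1", 9000), ("sp", "gsp", 9000)])}
        s_base = calibrate_hic_filter(base, chic, [0.0])[0]["score"]
        s_more = calibrate_hic_filter(more, chic, [0.0])[0]["score"]
        assert s_more <= s_base

    def test_empty_chic_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            calibrate_hic_filter({10_000: _ep_df([])}, _ep_df([]), [0.0])


class TestNetworkAndCorrelation:
    def test_shared_enhancer_one_component_three_nodes(self):
        ep = _ep_df([("e1", "g1", 5000), ("e1", "g2", 5000)])
        out = ep_network_components(ep)
        assert len(out) == 1
        assert out.iloc[0]["n_nodes"] == 3 and out.iloc[0]["n_edges"] == 2

    def test_disjoint_pairs_one_component_each(self):
        ep = _ep_df([(f"e{i}", f"g{i}", 5000) for i in range(4)])
        out = ep_network_components(ep)
        assert len(out) == 4 and (out["n_nodes"] == 2).all()

    def test_component_census_matches_union_find_oracle(self, rng):
        edges = [(f"e{rng.integers(8)}", f"g{rng.integers(8)}", 5000)
                 for _ in range(20)]
        ep = _ep_df(edges).drop_duplicates(["enhancer_id", "gene_id"])
        out = ep_network_components(ep)

        # independent union-find
        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            parent[find(a)] = find(b)

        for r in ep.itertuples():
            union(("E", r.enhancer_id), ("P", r.gene_id))
        comps = {}
        for r in ep.itertuples():
            for node in (("E", r.enhancer_id), ("P", r.gene_id)):
                comps.setdefault(find(node), set()).add(node)
        sizes = sorted(len(v) for v in comps.values())
        assert sorted(out["n_nodes"]) == sizes

    def test_identical_vectors_r_one(self):
        ep = _ep_df([("e1", "g1", 1), ("e2", "g2", 1), ("e3", "g3", 1)])
        ep["logFC"] = [1.0, 2.0, 3.0]
        act = {"e1": 1.0, "e2": 2.0, "e3": 3.0}
        expr = {"g1": -1.0, "g2": -2.0, "g3": -3.0}
        out = directionality_correlation(ep, act, expr)
        assert out["activity"][0] == pytest.approx(1.0)
        assert out["expression"][0] == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson(self):
        ep = _ep_df([("e1", "g1", 1), ("e2", "g2", 1), ("e3", "g3", 1),
                     ("e4", "g4", 1)])
        x = np.array([0.5, -1.0, 2.0, 0.3])
        a = np.array([1.2, -0.4, 1.1, 0.0])
        ep["logFC"] = x
        act = dict(zip(ep["enhancer_id"], a))
        expr = dict(zip(ep["gene_id"], a))
        r_hand = (np.sum((a - a.mean()) * (x - x.mean()))
                  / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((x - x.mean()) ** 2)))
        out = directionality_correlation(ep, act, expr)
        assert out["activity"][0] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_errors(self):
        ep = _ep_df([("e1", "g1", 1), ("e2", "g2", 1), ("e3", "g3", 1)])
        ep["logFC"] = [1.0, 2.0, 3.0]
        act = {"e1": 5.0, "e2": 5.0, "e3": 5.0}
        with pytest.raises(ValueError, match="zero-variance"):
            directionality_correlation(ep, act, act)


class TestDissociation:
    genes = pd.DataFrame({
        "gene_id": ["g1", "g2"],
        "chrom": ["chr1", "chr1"],
        "start": [100_000, 500_000],
        "end": [120_000, 520_000],
        "strand": ["+", "+"],
    })
    repressive = iv(("chr1", 900_000, 950_000))

    def _pairs(self, logfc):
        # bin 10 covers gene g1; bin 90 covers the repressive region
        return sig_pairs([("chr1", 10, 90, logfc, 0.01)])

    def test_upregulated_gene_with_decreased_contact_listed(self):
        out = genes_dissociating_from_repressive_domains(
            self._pairs(-2.0), self.genes, self.repressive,
            {"g1": "up", "g2": "ns"}, resolution=10_000)
        assert out == ["g1"]

    def test_increased_contact_not_listed(self):
        out = genes_dissociating_from_repressive_domains(
            self._pairs(+2.0), self.genes, self.repressive,
            {"g1": "up", "g2": "ns"}, resolution=10_000)
        assert out == []

    def test_downregulated_gene_not_listed(self):
        out = genes_dissociating_from_repressive_domains(
            self._pairs(-2.0), self.genes, self.repressive,
            {"g1": "down", "g2": "ns"}, resolution=10_000)
        assert out == []


def test_combine_ep_sources_prefers_capture_record():
    chic = _ep_df([("e1", "g1", 9000)]).assign(source="cHiC_fragment")
    hic = _ep_df([("e1", "g1", 9000), ("e2", "g2", 8000)]).assign(source="HiC_10000")
    out = combine_ep_sources(chic, hic)
    assert len(out) == 2
    assert out[out["enhancer_id"] == "e1"]["source"].iloc[0] == "cHiC_fragment"
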