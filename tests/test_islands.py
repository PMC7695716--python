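import numpy as np
import pandas as pd
import pytest

from senloop.binding import call_peaks, consensus_peaks, diff_binding
from senloop.islands import (associate_islands_to_genes, call_islands,
                             classify_gene_topology, metagene_tes_profile,
                             scaled_island_profile)
from senloop.tracks import CoverageTrack

STEP = 50


def track(values, chrom="chr1"):
    return CoverageTrack(step=STEP, data={chrom: np.asarray(values, float)})


def diffregion(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction",
                                       "fdr", "max_reads"])


class TestCallIslands:
    ctcf = pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "end": [51_000]})

    def test_wide_loss_region_called(self):
        regions = diffregion([("chr1", 10_000, 15_000, "loss", 0.01, 400)])
        out = call_islands(regions, self.ctcf)
        assert len(out) == 1 and out.iloc[0]["width"] == 5_000
        assert not out.iloc[0]["ctcf_overlap"]

    def test_narrow_loss_region_rejected(self):
        regions = diffregion([("chr1", 10_000, 11_000, "loss", 0.01, 400)])
        assert len(call_islands(regions, self.ctcf)) == 0

    def test_gain_regions_never_called(self):
        regions = diffregion([("chr1", 10_000, 20_000, "gain", 0.01, 400)])
        assert len(call_islands(regions, self.ctcf)) == 0

    def test_ctcf_overlap_flagged(self):
        regions = diffregion([("chr1", 48_000, 55_000, "loss", 0.01, 400)])
        out = call_islands(regions, self.ctcf)
        assert out.iloc[0]["ctcf_overlap"]

    def test_recovery_on_generated_tracks(self, small_dataset):
        """Planted DRB-lost domains recovered; sharp CTCF peaks never called."""
        ds = small_dataset
        cov = ds.coverage[("senescent", False)]
        cov_drb = ds.coverage[("senescent", True)]
        drb_diff = diff_binding(cov["cohesin"], cov["input"],
                                cov_drb["cohesin"], cov_drb["input"])
        ctcf_peaks = consensus_peaks(
            [call_peaks(t, cov["input"]) for t in cov["ctcf"]])
        out = call_islands(drb_diff, ctcf_peaks)
        planted = ds.truth.islands
        # precision & recall by overlap
        tp = 0
        for r in out.itertuples():
            hit = planted[(planted["chrom"] == r.chrom)
                          & (planted["start"] < r.end) & (planted["end"] > r.start)]
            tp += len(hit) > 0
        recall_hits = 0
        for r in planted.itertuples():
            hit = out[(out["chrom"] == r.chrom)
                      & (out["start"] < r.end) & (out["end"] > r.start)]
            recall_hits += len(hit) > 0
        assert tp / len(out) >= 0.9
        assert recall_hits / len(planted) >= 0.9
        assert not out["ctcf_overlap"].any()

    def test_zero_islands_when_tracks_identical(self, small_dataset):
        cov = small_dataset.coverage[("senescent", False)]
        same = diff_binding(cov["cohesin"], cov["input"],
                            cov["cohesin"], cov["input"])
        out = call_islands(same, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert len(out) == 0


GENES = pd.DataFrame({
    "gene_id": ["hi_plus", "hi_minus", "lo"],
    "chrom": ["chr1"] * 3,
    "start": [100_000, 300_000, 500_000],
    "end": [150_000, 350_000, 550_000],
    "strand": ["+", "-", "+"],
})
GENES["tss"] = np.where(GENES["strand"] == "+", GENES["start"], GENES["end"])
GENES["tes"] = np.where(GENES["strand"] == "+", GENES["end"], GENES["start"])
EXPR = pd.DataFrame({
    "gene_id": GENES["gene_id"],
    "mean_log_tpm": [8.0, 7.0, 1.0],
})


def island(start, end, chrom="chr1"):
    return pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end],
                         "width": [end - start], "ctcf_overlap": [False],
                         "fdr": [0.01]})


class TestAssociation:
    def test_island_3kb_downstream_of_high_tpm_tes_associated(self):
        out = associate_islands_to_genes(island(153_000, 158_000), GENES, EXPR,
                                         high_expr_threshold=5.0)
        assert out.iloc[0]["gene_id"] == "hi_plus"

    def test_low_tpm_host_excluded(self):
        out = associate_islands_to_genes(island(553_000, 558_000), GENES, EXPR,
                                         high_expr_threshold=5.0)
        assert out.iloc[0]["gene_id"] is None

    def test_island_15kb_downstream_not_associated(self):
        out = associate_islands_to_genes(island(165_000, 170_000), GENES, EXPR,
                                         high_expr_threshold=5.0)
        assert out.iloc[0]["gene_id"] is None

    def test_minus_strand_window_upstream_of_interval(self):
        # minus-strand TES is the interval start; its window runs left
        out = associate_islands_to_genes(island(292_000, 298_000), GENES, EXPR,
                                         high_expr_threshold=5.0)
        assert out.iloc[0]["gene_id"] == "hi_minus"


class TestTopology:
    def test_convergent_pair_within_extension(self):
        genes = pd.DataFrame({
            "gene_id": ["a", "b"],
            "chrom": ["chr1", "chr1"],
            "start": [50_000, 105_000],
            "end": [100_000, 160_000],
            "strand": ["+", "-"],
        })
        genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
        genes["tes"] = np.where(genes["strand"] == "+", genes["end"], genes["start"])
        out = classify_gene_topology(genes, extension=10_000).set_index("gene_id")
        assert out.loc["a", "label"] == "convergent"
        assert out.loc["a", "partner"] == "b"
        assert out.loc["b", "label"] == "convergent"

    def test_lone_gene_isolated(self):
        out = classify_gene_topology(GENES, extension=10_000).set_index("gene_id")
        assert (out["label"] == "isolated").all()

    def test_tandem_overlapping_genes_are_other(self):
        genes = pd.DataFrame({
            "gene_id": ["a", "b"],
            "chrom": ["chr1", "chr1"],
            "start": [50_000, 90_000],
            "end": [100_000, 140_000],
            "strand": ["+", "+"],
        })
        genes["tss"] = genes["start"]
        genes["tes"] = genes["end"]
        out = classify_gene_topology(genes).set_index("gene_id")
        assert (out["label"] == "other").all()

    def test_generator_truth_matches(self, small_dataset):
        truth = small_dataset.truth
        out = classify_gene_topology(truth.genes).set_index("gene_id")
        for g in truth.genes.itertuples():
            assert out.loc[g.gene_id, "label"] == g.topology


class TestMetagene:
    def _topology(self, genes):
        return classify_gene_topology(genes)

    def test_constant_coverage_flat_profiles(self):
        cov = track(np.full(20_000, 3.0))
        topo = self._topology(GENES)
        prof, names = metagene_tes_profile(cov, GENES, topo, EXPR, n_groups=2,
                                           flank=20_000)
        assert np.allclose(prof[~np.isnan(prof)], 3.0)

    def test_island_downstream_of_high_group_only(self):
        v = np.full(20_000, 2.0)
        # islands downstream of hi_plus TES (150 kb) and hi_minus TES (300 kb,
        # minus strand: downstream = lower coordinates)
        v[3_000 + 40:3_000 + 240] = 40.0       # 152-162 kb
        v[5_800:5_960] = 40.0                  # 290-298 kb
        cov = track(v)
        topo = self._topology(GENES)
        prof, names = metagene_tes_profile(cov, GENES, topo, EXPR, n_groups=2,
                                           flank=20_000)
        n = prof.shape[1]
        down = slice(n // 2 + 1, n // 2 + n // 4)
        assert np.nanmean(prof[-1][down]) > np.nanmean(prof[0][down]) + 10

    def test_minus_strand_flip(self):
        # signal upstream (in genome coordinates) of a minus-strand TES must
        # appear downstream (right of centre) in the oriented profile
        genes = GENES[GENES["gene_id"] == "hi_minus"].reset_index(drop=True)
        expr = EXPR[EXPR["gene_id"] == "hi_minus"].reset_index(drop=True)
        v = np.full(20_000, 1.0)
        v[5_800:5_960] = 30.0  # 290-298 kb: genomically left of TES at 300 kb
        cov = track(v)
        topo = self._topology(genes)
        prof, _ = metagene_tes_profile(cov, genes, topo, expr, n_groups=1,
                                       flank=20_000)
        n = prof.shape[1]
        assert np.nanmean(prof[0][n // 2:]) > np.nanmean(prof[0][: n // 2])


class TestScaledProfile:
    def test_constant_coverage_constant_profile(self):
        cov = track(np.full(2_000, 3.0))
        prof = scaled_island_profile(cov, island(30_000, 40_000), flank=5_000,
                                     n_scaled_points=20)
        assert np.allclose(prof[~np.isnan(prof)], 3.0)

    def test_step_profile_body_vs_flank(self):
        v = np.full(2_000, 1.0)
        v[600:800] = 10.0  # body 30-40 kb
        cov = track(v)
        prof = scaled_island_profile(cov, island(30_000, 40_000), flank=5_000,
                                     n_scaled_points=20)
        n_flank = 5_000 // STEP
        assert np.allclose(prof[n_flank:n_flank + 20], 10.0)
        assert np.allclose(prof[:n_flank], 1.0)
        assert np.allclose(prof[-n_flank:], 1.0)

    def test_matches_interpolation_oracle(self, rng):
        v = rng.random(4_000)
        cov = track(v)
        isls = pd.DataFrame({
            "chrom": "chr1",
            "start": [10_000, 40_000, 80_000, 120_000, 150_000],
            "end": [18_000, 52_000, 86_000, 135_000, 160_000],
        })
        n_pts, flank = 30, 5_000
        prof = scaled_island_profile(cov, isls, flank=flank, n_scaled_points=n_pts)
        n_flank = flank // STEP
        rows = []
        for r in isls.itertuples():
            body = v[r.start // STEP: -(-r.end // STEP)]
            scaled = np.interp(np.linspace(0, 1, n_pts),
                               np.linspace(0, 1, len(body)), body)
            left = v[r.start // STEP - n_flank: r.start // STEP]
            right = v[-(-r.end // STEP): -(-r.end // STEP) + n_flank]
            rows.append(np.concatenate([left, scaled, right]))
        assert np.allclose(prof, np.mean(rows, axis=0))

    def test_empty_islands_error(self):
        with pytest.raises(ValueError, match="islands"):
            scaled_island_profile(track(np.ones(100)),
                                  pd.DataFrame(columns=["chrom", "start", "end"]))


def test_island_host_expression_and_signal_correlation(small_dataset):
    """Host genes are highly expressed; island signal tracks expression."""
    from scipy import stats

    ds = small_dataset
    expr = ds.truth.expression.set_index("gene_id")["mean_log_tpm"]
    thresh = np.quantile(expr.to_numpy(), 0.75)
    hosts = ds.truth.islands["gene_id"]
    assert (expr[hosts] >= thresh).mean() >= 0.85
    cov = ds.coverage[("senescent", False)]["cohesin"][0]
    heights = [cov.values_in(r.chrom, r.start, r.end).mean()
               for r in ds.truth.islands.itertuples()]
    rho = stats.spearmanr(heights, expr[hosts].to_numpy()).statistic
    assert rho > 0
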