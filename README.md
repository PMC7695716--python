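# senloop

Integrative Hi-C + ChIP-seq analysis of senescence-associated chromatin-loop
rewiring.

## The problem

When human diploid fibroblasts enter oncogene-induced senescence, their
regulatory genome is rewired: enhancer–promoter (EP) contacts change, cohesin
redistributes on chromatin — including wide, CTCF-independent,
transcription-dependent "cohesin islands" at the 3′ ends of highly expressed
genes — while the large-scale architecture (A/B compartments, TADs) stays
comparatively stable. Detecting this rewiring requires a chain of analyses
over binned contact matrices and ChIP-seq-style coverage: normalization,
differential testing, annotation against regulatory elements, and aggregate
visual summaries. `senloop` implements that chain as a tested, reusable
library, together with a synthetic-data generator that plants known
compartments, TAD borders, loops, differential interactions, EP changes and
cohesin islands, so every stage is verifiable without external sequencing
data.

## What it computes

- **Contact matrices** (`senloop.contacts`): sparse-triplet I/O, low-coverage
  bin masking, ICE balancing (find biases *b* with
  raw<sub>ij</sub>/(b<sub>i</sub>b<sub>j</sub>) having equal row sums),
  distance correction (observed/expected with E[d] = mean of diagonal *d*),
  and library-size-normalized replicate aggregation.
- **Architecture** (`senloop.architecture`): A/B compartment scores from PCA
  of the Pearson-correlation transform of the 100 kb obs/exp matrix, with the
  component chosen and sign-fixed by correlation with a reference activity
  track (A = positive); TAD borders as insulation-score minima at 40 kb with
  1–10 confidence scores, cross-replicate consensus (scores > 7 in every
  replicate), and NMI comparison of border sets.
- **Differential interactions** (`senloop.diff_interactions`): per-bin-pair
  counts across replicates, low-count/diagonal filtering, loess trended
  normalization between libraries, and a negative-binomial
  quasi-likelihood-style F-test with abundance-trended, empirically shrunk
  dispersions; Benjamini–Hochberg control at 5% FDR.
- **Regulatory annotation** (`senloop.regulatory`): enhancers = active-mark
  peaks supported by accessibility, merged under 12.5 kb, minus promoter
  windows; promoters = TSS ± 2.5 kb of differentially expressed genes; EP
  annotation of significant pairs; calibration of the binned-map EP filter
  against a fragment-resolution capture baseline (maximize shared −
  capture-unsupported calls over enhancer-size cutoffs × resolution subsets);
  EP network components; directionality correlations; genes dissociating from
  repressive domains.
- **Binding** (`senloop.binding`): enrichment peak calling over input,
  ≥2-replicate consensus, windowed differential binding (input-subtracted,
  depth-normalized, variance-moderated, 5% FDR + 100-read floor), and
  classification of changes against loop anchors (± 20 kb pads).
- **Cohesin islands** (`senloop.islands`): loss-direction regions > 2 kb from
  the ± elongation-inhibitor (DRB) contrast, CTCF-overlap flags, association
  to genes via [TES, TES+10 kb) windows plus a high-expression filter,
  isolated/convergent gene topology, and expression-stratified TES
  meta-profiles.
- **Aggregation** (`senloop.aggregation`): APA-style 11 × 11 neighbourhoods
  (200 kb at 20 kb) around anchor pairs, missing-value-aware averaging, and
  differential aggregates.
- **Synthetic data** (`senloop.synthetic`): the two-condition generator with
  full planted-truth export; `senloop.pipeline.run_all` orchestrates every
  stage and `compare_to_truth` scores calls against the plants.

## Worked example

```python
from senloop.synthetic import SyntheticConfig, simulate_all
from senloop.pipeline import run_all, compare_to_truth

cfg = SyntheticConfig(seed=1)          # 2 chromosomes x 20 Mb, 2+2 replicates
ds = simulate_all(cfg)
report = run_all(ds)
metrics = compare_to_truth(report, ds.truth, cfg)
s = report["stages"]
print("significant differential pairs:", s["diff_interactions"]["n_significant"],
      "of", s["diff_interactions"]["n_tested"], "tested")
print("cohesin islands:", s["islands"]["n_islands"],
      "| CTCF-overlapping:", s["islands"]["n_ctcf_overlapping"])
print("island recall: %.2f  precision: %.2f" % (
    metrics["islands"]["recall"], metrics["islands"]["precision"]))
print("compartment sign agreement: %.3f" % metrics["compartment_sign_agreement"])
print("border F1 (+-1 bin): %.3f" % metrics["border_f1"])
```

prints

```
significant differential pairs: 18 of 930795 tested
cohesin islands: 10 | CTCF-overlapping: 0
island recall: 1.00  precision: 1.00
compartment sign agreement: 1.000
border F1 (+-1 bin): 0.866
```

i.e. at 20 kb resolution 18 bin pairs change significantly between the
conditions (the generator planted 20, so most are recovered with no false
positives), all 10 planted transcription-dependent cohesin islands are called
without touching a CTCF site, every 100 kb bin lands in its planted
compartment, and consensus TAD borders recover the planted border set at
F1 ≈ 0.87 within one 40 kb bin.

A command-line entry point wraps the common steps:

```bash
senloop simulate --seed 1 --out data/      # synthetic dataset + manifest
senloop run --seed 1 --out results/        # full pipeline + report.json/md
senloop balance matrix.txt bins.bed --out balanced.txt
senloop oe matrix.txt bins.bed --out oe.txt
senloop tads matrix.txt bins.bed --out borders.bed
```

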