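# Methods

This note documents the models, estimators and design choices behind
`senloop`, and what its synthetic validation does and does not demonstrate.

## Contact-matrix normalization

Matrices are per-chromosome, symmetric, binned (0-based half-open bins,
bin = ⌊position / resolution⌋), intra-chromosomal only: every downstream
analysis here (compartments, borders, differential pairs, EP annotation,
aggregate neighbourhoods) is intra-chromosomal, so inter-chromosomal support
was left out of scope.

**Masking.** Bins whose marginal contact sum falls below a quantile of the
non-zero marginals (default 0.05) are masked, along with zero-marginal bins;
masked rows/columns are excluded from every later computation. The masking
quantile is a package choice, not an externally fixed constant.

**ICE balancing.** Iterative correction multiplies rows/columns by
1/√(rowsum/mean) until the coefficient of variation of unmasked row sums
falls below `tol` (default 1e−5, max 200 sweeps; non-convergence is an
error carrying the last CV). Biases are renormalized to mean 1 so the
matrix scale is preserved; balancing a balanced matrix therefore returns
biases ≈ 1 (idempotence, asserted in tests).

**Distance correction.** The expected value at offset d is the mean of
unmasked entries on diagonal d of the balanced matrix; obs/exp = entry /
expectation. Exact invariances used as oracles: matrices that are pure
functions of |i−j| map to all ones, and global rescaling leaves obs/exp
unchanged.

**Replicate aggregation** scales each replicate to the mean library size and
takes the per-pixel arithmetic mean. The combined matrix is used only for
visualization-style computations (compartment calling on combined maps,
aggregate neighbourhoods), where the mean carries the needed content; this
is deliberately simpler than a count-model-based combination and is
documented as such.

## Compartments and TAD borders

Compartment scores come from PCA of the Pearson-correlation transform of
the 100 kb obs/exp matrix (standard compartment practice: the correlation
transform sharpens the plaid pattern). Among the first three components the
one with the largest |Pearson r| against a per-bin reference activity track
is selected; below a floor of |r| = 0.2 the caller refuses ("no
compartment-like component"). The sign is flipped so the correlation is
positive, making active (A) bins positive by convention. The floor is a
design choice; nothing in the underlying method fixes it.

Borders are insulation-score minima: for bin i the score is the mean of the
w×w square `values[i−w:i, i:i+w]` (default w = 10 bins at 40 kb, i.e. a
400 kb window). All strict local minima with positive prominence are
reported; confidence scores 1–10 are the decile ranks of the minima's
prominences, so the deepest valleys score 10. This insulation caller is a
stand-in with the same output contract (positions + 1–10 scores) as
likelihood-based TAD callers; the consensus rule and the NMI comparison —
the parts that carry the analysis — operate identically on either. Consensus
keeps borders scored above `min_score` (default 7) in **every** replicate,
within a position tolerance (default 1 bin in the pipeline; the strict
"exact position" variant is tolerance 0). NMI uses the binary
border/non-border labelling of bins with arithmetic-mean normalization; a
constant labelling (empty border set) has zero entropy and NMI 0 by
convention.

## Differential bin-pair testing

Counts for pairs (i < j; diagonals excluded) with total ≥ `min_total_count`
(default 10 — the underlying filtering idea fixes no number) are tested for
a condition effect with ≥ 2 replicates per condition:

1. **Trended normalization.** Per library, the log2 ratio to the per-pair
   geometric mean is smoothed against average log2 abundance by loess
   (span 0.3, two robustifying iterations, `delta` interpolation for
   near-linear cost at ~10⁶ pairs); the smooth is the library's per-pair
   offset. Under 50 pairs a global median offset is used (with a warning).
2. **Dispersion.** Method-of-moments NB dispersion per pair, pooled within
   groups, shrunk toward a 20-bin abundance trend with prior weight 10
   (empirical-Bayes squeeze).
3. **Test.** Group means are offset-weighted Poisson-consistent estimators;
   the NB deviance difference between common-mean and two-mean fits is an
   LR statistic. A quasi-dispersion per pair (residual deviance / df,
   squeezed toward its abundance trend with prior df 20) divides the LR,
   and the ratio is referred to F(1, df_resid + 20). The median-based
   quasi-dispersion trend is multiplied by the inverse χ² median consistency
   factor (median(χ²_df)/df) — without it the trend underestimates the unit
   quasi-dispersion at small df and the null is anti-conservative. The
   50-seed null simulation in the acceptance suite is the calibration
   oracle for this whole construction.
4. **Multiplicity.** Benjamini–Hochberg across all tested pairs; 5% FDR.

Exact symmetries (tested): permuting replicates within a condition changes
nothing; swapping condition labels negates every log2 fold change (computed
with symmetric prior counts of 0.5) and preserves p-values; BH significant
sets are nested across FDR levels.

Like any between-library normalization, the loess trend assumes changes are
a minority at every abundance; a change stratum that *owns* the top of the
abundance range is absorbed into the trend. The calibration simulator
therefore draws changed pairs from within the bulk abundance range, which is
also the realistic regime.

## Enhancer–promoter annotation and the capture calibration

Enhancers (per condition, then unioned): active-mark peaks overlapping ≥ 1
accessibility peak, merged when gaps are < 12.5 kb, promoter windows
subtracted. Promoters: TSS ± 2.5 kb, DE genes only. A significant pair is an
EP interaction when one bin overlaps an enhancer and the other a promoter;
all enhancer × promoter combinations are emitted, separations ≥ 2 Mb are
dropped, and (enhancer, gene) pairs found by both capture and binned maps
keep the capture record.

The calibration formalizes "keep what the capture technology confirms" as an
explicit objective: for each candidate (enhancer-size cutoff, resolution
subset), score = |shared with capture| − |binned-only|, computed within
captured regions; ties go to the stricter filter (larger cutoff, then fewer
and finer resolutions). Whether the original procedure was this exact
objective or a qualitative inspection is not documentable; the explicit
objective is this package's formalization, and the synthetic regime in
`simulate_ep_calibration` (only enhancers > 7.5 kb reproduce across
technologies; coarse bins add spurious calls) verifies that it selects the
intended cutoff and improves precision. Pearson correlation is used for the
directionality analyses since all inputs are log-scale effect sizes.

## Differential binding and loop classification

The windowed differential caller replaces an HMM-based tool with a
transparent test whose outputs (interval, direction, FDR, read floor) are
all the downstream logic consumes: 200 bp windows, per-replicate depth
normalization by the **median window count** (robust to localized
condition-specific signal, unlike totals, which the planted-signal test
exposed), scaled input subtraction, square-root variance stabilization,
3-window smoothing, and a variance-moderated t-test (pooled variance
squeezed toward a 20-bin abundance trend, prior df 20). Adjacent significant
windows of one direction merge; a region needs ≥ 100 reads in its maximum
window (replicates summed) in at least one condition — the floor is applied
per window maximum because "per location" does not pin down a region-level
rule. Changes are classified against loops by their midpoints: at_anchor
(within anchor ± 20 kb), inside (within the span), outside — a partition,
asserted exhaustively. Anchor co-binding uses nearest peak centre within
10 kb of the anchor interval.

## Cohesin islands

Operational definition: regions that significantly **lose** cohesin when
transcription elongation is inhibited (the ±DRB contrast, condition order:
untreated vs DRB), wider than 2 kb. No maximum width is imposed — the
observed 2–20 kb range is a result, not a rule — and widths are reported so
the distribution can be inspected. CTCF overlap is recorded (expected
false). Gene association: strand-directed [TES, TES + 10 kb) windows, plus a
high-expression filter defaulting to the top quartile of mean log-TPM, since
"highly expressed" has no canonical cutoff. An optional association mode
admitting gene-body/promoter overlap exists but is off by default.
Convergent genes are opposite-strand pairs whose [TES, TES + 10 kb)
extensions overlap (the extension reuses the TES-window length because the
"extended 3′ end" is otherwise unquantified); isolated genes have no
neighbour within 10 kb of the gene body. Meta-profiles centre at the TES
(isolated) or the inter-TES midpoint (convergent pairs), flip minus-strand
genes, and stratify by log-TPM quantiles; island bodies in scaled profiles
are linearly interpolated to a fixed number of points with native-scale
5 kb flanks.

## Aggregate neighbourhoods

200 kb windows around each anchor's bin at 20 kb resolution give 11 × 11
pixel sub-matrices of the obs/exp **combined** matrix (obs/exp rather than
balanced counts because windows span varying genomic distances). Pixels off
the matrix edge or on masked bins are missing; the aggregate divides each
pixel's sum by its number of non-missing contributions, and differential
aggregates subtract on co-defined pixels only. Island–peak anchor pairs
pair centres within 150 kb (a 250 kb variant is a flag) and at least two
bins apart so neighbourhoods avoid the diagonal.

## The synthetic generator

The generator defines the study conditions: 2 chromosomes × 20 Mb, 2
replicates per condition, 2 × 10⁷ unique contacts per replicate, NB
dispersion 0.01, alternating 2 Mb A/B blocks, ~19 planted borders per
chromosome (10 random + the compartment block edges, which insulate by
construction), 10 loops (3× pixels, same-compartment anchors), 20
differential pairs (4-fold, 100–600 kb separation, disjoint from loops), 80
genes (20% in convergent pairs with 1–5 kb TES gaps), 40 enhancers
(3–12 kb), 20 DE genes (4-fold), 10 islands of 3–18 kb hosted downstream of
isolated genes' TESs with ~9 of 10 hosts from the top expression quartile,
and coverage tracks at 50 bp steps with ≤ 1 kb CTCF-co-located peaks in all
conditions and island plateaus (height increasing with host log-TPM) only in
the untreated stressed condition. Expected contacts follow power-law decay
with exponent −1, floored beyond 2 Mb so distal pixels stay non-degenerate.
One global seed expands to per-stage child streams (annotation, expression,
contacts, coverage), so stages regenerate independently and identical
config+seed is byte-identical.

Problem sizes were chosen so that a single CPU runs the full pipeline in
seconds while planted features remain statistically detectable at 2+2
replicates: with ~10⁶ tested pairs, BH demands p ≈ 10⁻⁶ of a true change,
which 4-fold changes at 100–600 kb separations reach at this depth and
dispersion. The generator emulates: distance decay, compartment plaid, TAD
insulation, focal loops, replicate noise, condition-specific coverage
domains, and expression-coupled signal. It does **not** emulate restriction
-fragment geometry, mappability or GC bias structure (its biases are
bin-independent, so ICE has an easy job), inter-chromosomal contacts,
copy-number variation, or read-level artefacts — so green tests demonstrate
algorithmic correctness and calibration under the stated noise model, not
robustness to every artefact of real libraries. Zero NB dispersion falls
back to Poisson sampling (documented contract).

## Known limitations

- The insulation border caller is a functional stand-in, not a
  re-implementation of likelihood-based TAD callers; confidence deciles are
  relative within a chromosome, so a chromosome with only weak minima still
  scores its best minima 10.
- The NB quasi-likelihood test is a from-scratch construction calibrated by
  simulation; it is conservative under the complete null (mean observed FDP
  ≈ 0–2% at nominal 5%).
- Exact-bin NMI between condition consensus border sets is sensitive to
  ±1-bin jitter; it is reported descriptively.
- `aggregate_replicates` is a library-size-normalized mean, appropriate for
  the visualization/aggregation uses it serves here, not a replacement for a
  count-model combination in inference.
- Multi-resolution differential runs are driven by looping
  `run_all(diff_resolution=...)`; the pipeline default reports 20 kb.
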