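# Methods

This note documents the models, parameter choices and numerical decisions
behind `fivec_locus`, and what the synthetic-data results do and do not
demonstrate about real 5C data.

## The measurement model

A 5C design interrogates only forward-reverse probe pairs, so a library is
a rectangular (forward × reverse) count matrix rather than a symmetric
fragment map. The pair distance is the distance between restriction
fragment midpoints. All coordinates are 0-based half-open; BED is read and
written natively in that convention, and TSVs carry a header comment
stating it.

## Loess with a weighted SD

All expectation models are Loess-style local regressions: for each support
distance, the `k = ceil(span · n)` nearest cells (minimum 5) are weighted
with the tricube kernel, giving a weighted mean *and* a weighted SD per
distance — both are needed because the calling statistic is
Z = (obs − exp)/sd. statsmodels' `lowess` returns only the smoothed mean,
so the smoother is implemented here (vectorized for probe-level profiles,
sliding-window for the ~145k-cell global fits) and checked against a
brute-force oracle in the tests. Support is capped at 1500 points
(quantile-spaced) with linear interpolation between them.

Numerical guards: the SD is floored at `max(1e-3 · mean, 1e-9)` so Z stays
finite on near-constant strata; a fit with all cells at a single distance
is a degenerate-fit error.

Span defaults: 0.05 for the QC/normalization decay curve (a broad,
stable trend is wanted there) and 0.01 for the loop-calling expected model
(a tight local fit; this is the conventional value for 5C peak calling).
Probe-level profiles reuse the global span on the probe's own cells.

## QC pipeline (order fixed: purge → singletons → normalization)

**Cis-purge.** Each probe's smoothed profile is compared with the global
curve; its score is the mean |deviation| in units of the global SD — the
scaled Z-score distance of the probe from the global Loess — thresholded at
0.85. Two details matter in practice:

* *Like-for-like smoothing.* The reference is the global curve re-smoothed
  with the same window on the probe's own cells, so the curvature bias of
  small-window smoothing on a steep decay cancels instead of inflating
  every probe's score.
* *Spike-robust scoring.* Cells that the singleton filter would remove
  (Z ≥ 25) are excluded from both the profiles and the SD denominator
  during scoring only; left in, a handful of extreme spikes inflate the
  global SD enough to hide genuinely corrupted probes. Their actual removal
  remains the singleton stage's job, so stage contracts are unchanged.

An alternative scaling (`zscore`: standardize scores across probes before
thresholding) is config-selectable but not the default — it removes a
fixed ~40% fraction of probes regardless of data quality and is not
idempotent, whereas the SD-units reading removes none when all probes
behave identically and is stable under re-application.

**Singleton removal.** Cells with Z ≥ 25 (inclusive) against the post-purge
decay curve are masked individually. The pipeline repeats the step with a
refreshed curve until no new cell is masked (≤ 5 passes): very large spikes
inflate the local SD and can shield each other from a single pass.

**Profile normalization.** Each probe's correction factor is the *median*
over its cells of global/probe-smoothed ratio; each cell is multiplied by
the factors of both of its probes. Median rather than mean: individual
extreme cells (residual spikes, genuine loops) and near-zero smoothed
values in sparse long-distance cells otherwise dominate the factor. The
within-library scale is deliberately not removed (multiplying a library by
c multiplies its normalized output by c); probes with an all-zero profile
cannot be corrected and are masked. The factors are retained on the matrix
(`fwd_scale`/`rev_scale`) for noise propagation downstream.

**Binning.** Overlapping 150 kb windows every 15 kb; the per-bin-pair
statistic is the *mean* over contributing unmasked pairs (not the sum), so
uneven probe coverage does not masquerade as signal. Only fully contained
windows are emitted.

## TAD calling

The insulation score of bin *b* sums the binned signal over upstream ×
downstream bin pairs within ±500 kb of the bin midpoint (the insulation
square), normalized by the mean over scored bins; bins whose window does
not fit in the data are unscored. Boundaries are strict local minima
within a centered 435 kb window, ties to the leftmost bin, flat windows
excluded; no strength threshold is applied, but a strength (flanking
local-maximum score minus minimum) is reported for downstream filtering.
Boundaries from replicates are matched greedily within 200 kb (twice the
observed reproducibility) and averaged; unmatched boundaries are reported
as replicate-specific rather than guessed into the consensus. Gene-density
classes compare TAD kb-per-gene with the 75 kb/gene mouse genome average.

## Loop calling

Per library: expected model (Loess α = 0.01 on the normalized matrix) →
Z scores → two-parameter Weibull fitted by maximum likelihood to the Z
distribution → upper-tail p-values → Benjamini–Hochberg q over all
unmasked cells → significant iff q < 0.05. Consensus keeps pairs
significant *and interrogated* in both replicates; the consensus q is the
max of the two (conservative). Cell-type comparisons are restricted to
pairs interrogated in all contributing libraries, yielding three disjoint
sets (A-specific, B-specific, common).

Weibull support: Z scores are shifted to positive support by
−min(Z) + 1e-6 before fitting (the shift is recorded); fitting positive Z
only is selectable but measured to be far too conservative on realistic
matrices.

**Counting-noise floor.** The Z denominator in *peak calling* is floored at
the cell's propagated sampling SD, sqrt(scale_i · scale_j · expected): a
Poisson count rescaled by probe correction factors carries at least that
much noise, which the distance-pooled Loess SD underestimates for strongly
corrected probes in sparse long-distance cells. Without the floor,
reproducible two-count cells at multi-megabase distances surface as
"loops". The plain (obs − exp)/sd transform remains available and is the
default of `z_transform`; the floor is the documented default of
`call_library`.

## Annotation and enrichment

Enhancers: merge H3K4me1 peaks at ≤ 5 kb end-to-end, H3K27ac likewise,
pair merged regions across marks at ≤ 2 kb, take union spans, union any
overlapping candidates, and label E1..En in genomic order; clusters form
at < 10 kb end-to-end (strict). Two promoter windows coexist by design:
5 kb for the PP/PN/NN classification and 10 kb for enhancer-target
assignment. Anchor-feature distance is 0 when the feature overlaps the
fragment interval, else the interval gap. Loop/enhancer involvement is
reported under both accounting modes (unique loops touching an enhancer;
(loop, enhancer-unit) rows), since they answer different questions.
Reported percentages: two decimals, half-up, except the headline
involvement percentages, which floor to integers.

Enrichment: anchors extend to the nearest opposite-orientation interrogated
fragment on each side (one-sided at region edges); binding is ≥ 1 bp
overlap of a peak with either extended anchor; the background is all
interrogated, unmasked pairs minus the significant set; the Fisher test is
two-sided (one-sided selectable) with Haldane–Anscombe odds ratios when a
cell is zero.

## The synthetic-data generator

The generator emulates a 5.3 Mb locus (chr3:89,900,000–95,200,000) tiled
by ~763 alternating probes (381 forward / 382 reverse when no fragments
are excluded). Expected signal for pair (i, j):

    depth-scaled × d^decay_exponent × TAD gain × loop gain × bias_i × bias_j

with defaults chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| decay_exponent | −1.0 | canonical intra-chromosomal contact scaling at 0.1–5 Mb |
| TAD layout | 7 TADs, boundaries ≥ 700 kb apart | seven-domain organization with gene-rich/poor contrast |
| intra_boost | 3.0 | within-domain contact gain at matched distance |
| cross_pair_boost | TAD2–TAD5 ×2 | compartment-like contact between the two gene-poor domains |
| probe_bias_sd | 0.3 | log-normal per-probe efficiency spread (unit mean), shared across replicates as sequence-driven biases are |
| depth | 10⁶ expected counts/library | mean ~7 counts per interrogated pair |
| singleton_rate | 0.001 | rare ligation/PCR jackpots |
| spike_fold | 50 × max(cell expectation, library mean) | spikes are *absolute* extremes — a jackpot's magnitude is unrelated to the cell's true contact level, and anything milder would be both unrealistic and undetectable by the Z ≥ 25 rule |
| bad_probe_count | 4/replicate | profiles replaced by a distance-shuffled copy — guaranteed to break the decay relation the purge tests for |
| planted loops | 100 pairs, fold 4, same-TAD, 100–600 kb | ~0.07% of pairs (the real locus shows ~0.8% significant); placed in the locus's intra-domain enhancer–promoter distance range, where a 4-fold enrichment is statistically measurable at this depth — beyond ~1 Mb expected counts drop below 1 and no method can see a 4-fold change |

Counting noise is Poisson, drawn independently per replicate; gene
annotations place one gene per 21–36 kb (gene-rich) or 166–400 kb
(gene-poor) TAD; enhancer-signature mark pairs appear only in gene-rich
TADs; CTCF/Rad21/Brg1 peaks are placed preferentially in gene-rich TADs and
at planted loop anchors. Every planted feature is recorded in a
GroundTruth object.

**What passing tests show — and don't.** Under these conditions the
pipeline recovers planted boundaries with ≤ 100 kb replicate discrepancy,
recovers fold-4 loops with recall ≈ 0.85 and precision ≈ 0.93, keeps the
null consensus rate around 10⁻⁴, and removes planted biases, spikes and bad
probes. Matrix agreement with the bias-free expectation is evaluated on the
log scale, the standard comparison for contact data whose values span
orders of magnitude; linear Pearson is dominated by the few
shortest-distance cells, including any jackpot spike whose local Z sits
below the 25-SD removal rule (local SD at short range includes the
probe-bias spread, so such spikes are genuinely unremovable under that
rule). Real 5C data differ in ways the generator does not model:
overdispersed (not Poisson) counts, restriction-site-density and
mappability structure, distance-dependent bias, partial digestion, and
trans contacts. The results demonstrate correctness of the implementation
under the stated model, not performance guarantees on arbitrary libraries.

## Problem sizes

The default simulations run the full 763-probe, 145,542-pair design; a
two-replicate normalize + loop-call cycle takes a few seconds, and the
replicate-reproducibility and false-discovery summaries average 20
simulated replicate pairs.

## Known limitations

* Matrix balancing (ICE/KR) and trans-contact normalization are out of
  scope; the correction is per-probe multiplicative only.
* One boundary per 435 kb: closely spaced or nested domains are merged.
* The Weibull tail is a pragmatic fit to a mixed Z distribution, not a
  calibrated null; FDR control is empirical (verified on the null
  simulation), not exact.
* Enhancer calling uses peak intervals only — no signal ranking, so no
  super-enhancer scoring beyond spatial clustering.
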