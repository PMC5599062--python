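# fivec-locus

Analysis of chromosome conformation capture carbon copy (5C) data for a
single multi-megabase locus: technical-bias correction of probe-level
contact matrices, insulation-index TAD calling, statistical calling of
chromatin looping interactions with replicate consensus, enhancer/promoter
annotation of the resulting interactome, and Fisher-exact enrichment of
architectural-protein binding (CTCF, Rad21, Brg1) at loop anchors.

It is written for regulatory-genomics analysts working with targeted 5C
designs — the motivating case is a 5.3 Mb region of mouse chromosome 3
around the Epidermal Differentiation Complex (EDC), interrogated by 381
forward and 382 reverse probes in an alternating design (145,542
forward-reverse fragment pairs). Because such 5C libraries are rarely
deposited, the package ships a first-class synthetic-data generator that
reproduces the statistical structure the analysis assumes (power-law
distance decay, TAD blocks, planted loops, probe biases, singleton spikes,
Poisson counting noise), so every stage is testable against known ground
truth.

## The method

For a library with observed contact counts *y(i,j)* between forward
fragment *i* and reverse fragment *j* at genomic distance
*d* = |mid(i) − mid(j)|:

1. **Bias correction.** A Loess curve (locally weighted mean *μ(d)* and SD
   *σ(d)*) is fitted per library. Probes whose own smoothed profile sits
   more than 0.85 SD-units from the global curve are purged; isolated cells
   with *Z* = (*y* − *μ*)/*σ* ≥ 25 are masked as singletons; each remaining
   probe's profile is rescaled onto the global curve (multiplicative
   per-probe correction factors).
2. **TADs.** The normalized matrix is binned in 150 kb windows every 15 kb.
   The insulation score of a bin is the summed signal crossing it within
   ±500 kb, divided by the mean over bins; local minima within a 435 kb
   window are TAD boundaries, and boundaries from the two replicates are
   averaged (they typically agree to well within ±100 kb). TADs are
   classified gene-rich/gene-poor by kb-per-gene against the 75 kb/gene
   genome average.
3. **Loops.** A tighter Loess (span α = 0.01) gives the distance-matched
   expectation; Z scores are fitted with a two-parameter Weibull whose
   upper tail supplies p-values; Benjamini–Hochberg q < 0.05 defines
   significant calls, and only calls reproducible in both replicates are
   kept.
4. **Annotation.** Enhancers = merged H3K4me1 and H3K27ac peak regions
   within 2 kb end-to-end (marks pre-merged at 5 kb; clusters at < 10 kb);
   loops are classified promoter–promoter / promoter–none / none–none (TSS
   within 5 kb of an anchor fragment), linked to enhancers and target TSSs
   (10 kb windows), and labelled intra-/inter-TAD.
5. **Enrichment.** Anchor fragments are extended to the nearest
   opposite-orientation interrogated fragments; two-sided Fisher exact
   tests compare protein binding among significant loops versus all other
   interrogated pairs, plus pairwise co-occupancy percentages.

## Worked example

Run the full pipeline end-to-end on synthetic data at the default (study)
scale:

```bash
fivec-locus run --seed 3 --outdir run1
```

This simulates two replicate libraries (763 probes, depth 10⁶, seven TADs,
100 planted loops), normalizes each, calls TADs and loops, annotates and
tests enrichment. The manifest written to `run1/manifest.json` reports, for
seed 3:

```
simulate : 763 probes (381 forward / 382 reverse), 145542 interrogated pairs
normalize: rep1 1 probe purged, 146 singletons; rep2 0 probes, 194 singletons
tads     : 6 consolidated boundaries -> 7 TADs
           (gene_rich, gene_poor, gene_rich, gene_rich, gene_poor, gene_rich, gene_rich)
loops    : 363 / 571 significant per replicate, 87 in consensus
enrich   : CTCF  odds ratio 6.0   p = 7.7e-06
           Rad21 odds ratio 11.7  p = 3.1e-07
           Brg1  odds ratio 48.9  p = 7.4e-10
```

Reading this: the seven planted domains and their gene-density classes are
recovered exactly; per-replicate loop calls shrink to a high-precision
consensus after requiring reproducibility; and because the generator places
protein peaks preferentially at planted loop anchors, all three proteins
come out strongly enriched at loop anchors — the behaviour expected of
architectural proteins at a locus like this. Stage outputs (normalized
matrices, insulation profiles, TAD BED, consensus loop table, enhancer
network, enrichment tables) are plain TSV/BED/JSON files in the output
directory.

The stages are also available individually (`simulate`, `normalize`,
`call-loops`) and as library functions
(`fivec_locus.normalization.normalize_library`,
`fivec_locus.loop_calling.call_library`, ...).

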