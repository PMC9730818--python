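# Methods

## Coordinate and overlap conventions

All intervals are 0-based half-open (BED). Adjacency (`end == start`) is
not overlap but counts as a zero-base gap for distance purposes. Strand is
parsed and carried for provenance but ignored in every overlap and
distance computation: DSB calls and downloaded peak sets are unstranded
observations. Duplicate intervals are retained with a warning rather than
silently deduplicated, since duplicate rows in peak files are usually an
upstream artifact the analyst should see.

## The permutation enrichment test

The statistic is the number of query (DSB) intervals sharing at least
`min_overlap_bp` (default 1) bases with ≥ 1 feature interval, each query
counted at most once. The null preserves each interval's chromosome and
length and redraws its start uniformly on `{0 … chrom_len − len}`;
shuffled intervals may overlap one another, and no exclusion zones (gaps,
blacklists) are modeled — the most conservative reading of a plain
interval shuffle. The empirical p is the fraction of iterations whose null
count is **equal to or higher than** the observed count, with no +1
correction; a zero exceedance count is displayed as the resolution bound
`p < 1/N`. Because the statistic is a discrete count, the achievable
p-grid is coarse and the test is conservative near any nominal level —
the null-calibration test asserts the p ≤ 0.05 fraction stays inside
0.05 ± 0.04 but in practice it sits slightly below 0.05, never above.

Each iteration draws from its own child of `SeedSequence(seed)`, so
iterations are order-independent; the enrichment loop draws starts in a
single vectorized call per iteration, consuming the stream exactly as an
explicit shuffle would (asserted by a test).

## Region signal summaries

`mean_signal_over_region` implements both conventions of the standard
average-over-bed utility: `mean0` (uncovered bases contribute zero;
divide by region length) and `mean` (divide by covered bases). `mean0` is
the default for ML feature signals because DSB regions routinely extend
past peak-coverage boundaries; the radial scorer uses `mean` (covered
bases only) because a DSB extending past the scored 1-Mb table should be
scored by the bins it actually overlaps. Both paths are checked against a
per-base brute-force accumulator to 1e-12.

## Profiles

Each DSB is represented by its interval midpoint `⌊(start+end)/2⌋`, which
keeps every DSB in exactly one bin and makes bin totals interpretable as
DSB counts. Offsets are DSB midpoint minus feature center; `nearest` mode
uses the closest same-chromosome center (ties to the leftmost feature),
`all` mode counts the DSB once per feature center within the window. The
window (20 kb) and bin count (50) give 400-bp bins; offsets on
`[−10000, 10000)` map to bins 0–49, so a +2-kb offset is bin 30 and −2 kb
is bin 20.

## Gene size classes

Half-open boundaries in kb: [1, 100), [100, 300), [300, 800), [800, ∞);
genes under 1 kb are unclassified. A hit spanning genes of two classes is
tallied once in each class, so stacked per-class totals can exceed the
number of hits — per-class counts are independent tallies, not a
partition. When several gene intervals share a symbol, the longest span
represents the gene.

## Radial scoring

Per-DSB score = base-pair-weighted mean of overlapped bin values (an
unweighted per-bin mean is available). The genomic background is the
multiset of all bin values, one entry per bin. DSBs overlapping no scored
bin are counted and reported as unscored, never dropped. Histogram edges
default to 20 equal-width bins over the pooled score range; the shift
test is a one-sided Mann–Whitney U (DSB scores greater than background).

## Matched-null classification

One null region per real DSB, same chromosome and length, uniformly
placed and rejection-resampled (cap 1000 attempts) until it overlaps
nothing in the exclusion set (recommended: the union of all DSB sets).
Feature columns are mean signal over the region (signal mode; sum
available) or edge distance in bp to the nearest feature (distance mode);
a chromosome with no feature yields the chromosome length as an
order-preserving sentinel, avoiding missing values. The classifier is a
700-tree random forest with default `mtry = √p`, evaluated out-of-bag
(every sample scored by the trees that did not draw it), which uses the
whole matrix for both fitting and honest evaluation; a stratified
train/test split is available. Importance is reported both ways the
ensemble literature uses: permutation importance on accuracy
(mean-decrease-accuracy analog) and impurity importance
(mean-decrease-Gini analog). Classification targets the condition-unique
DSB subset in the pipeline, where the induced signal is sharpest.

## The synthetic generator

The generator's defaults define the study conditions every statistical
test runs under; they emulate the *shape* of a Break-seq + ENCODE study at
roughly 1/100 genome scale:

| parameter | default | rationale |
|---|---|---|
| genome | 3 × 10 Mb | ~1/100 of a human genome; enrichment at 1000 iterations runs in well under a second |
| genes per size class | 300 / 60 / 12 / 4 | small genes dominate, a handful of > 800 kb giants |
| gene length within class | log-scale, Beta(1,5)-skewed toward the class floor | real gene-length distributions are strongly right-skewed; keeps the genic fraction near 53% so placement stays feasible |
| gene placement | non-overlapping, gaps grow quadratically along each chromosome; chromosome weights 0.6ⁱ | creates the intra- and inter-chromosome gene-density gradient that radial positioning tracks |
| expressed subset | 40%, stratified by size class, probability ∝ local gene density² | transcription concentrates in gene-dense clusters; stratification keeps the expressed genic mass (hence mark coverage) stable across seeds |
| H3K36me3-like blocks | central 24% of each expressed gene body | yields ~5% genome coverage, the regime where a 50% planted fraction is unambiguous yet overlap-by-chance stays realistic |
| CTCF-like sites | 50% of TSSs + 150 isolated intergenic anchors (200 bp) | TSS-associated plus loop-boundary sites |
| signal tracks | elevated 5.0 over features, baseline 0.1, Gaussian jitter per segment, 10-kb baseline tiles | region means behave like continuous coverage instead of a two-valued indicator; without jitter the classifier's ranking metrics are dominated by ties |
| radial score | per-10-kb bin, 0.2 + 0.8 · genic-fraction / max | 10 kb is 1/100 of the 1-Mb bins used on a full-size genome, matching the genome's own scale; score increases with gene density, emulating the radial-center preference of gene-dense chromatin |
| DSB counts | NT 200, DMSO 400, APH 700 | the observed 2111/3927/7002 scaled ≈ 1/10 |
| shared core | 80% of NT reused in each induced set | spontaneous breaks persist under treatment |
| planted fractions | f_mark = 0.5 inside mark blocks; f_ctcf = 0.2 at ±2 kb from CTCF-like sites | the two planted signatures: mark enrichment and the bifurcated CTCF profile |
| DSB length | lognormal, median 1 kb, σ = 0.5, clipped to [100, 8000] | Break-seq-like call widths |

All randomness flows from one seed through named substreams (genes,
expression, features, tracks, one per DSB condition); the manifest records
every planted assignment per DSB (`background`, `shared-core`, `mark`,
`ctcf-offset`), making planted-effect recovery measurable.

**What the generator does not emulate:** sequence content (no GC or
mappability structure, so no need for matched-composition nulls),
assembly gaps, replication timing, expression levels beyond a binary
expressed flag, and peak-calling noise (features are exact intervals).
Passing tests therefore demonstrate the statistics' correctness and
power under clean planted structure, not robustness to alignment or
calling artifacts in real data.

**Null calibration uses a true null.** The calibration check generates
data with *all* planted placement disabled (f_mark = 0 **and**
f_ctcf = 0). CTCF-offset planting is a real geometric dependence between
DSBs and annotation-anchored sites — under it the DSB set is not
exchangeable with the shuffle null, so it has no place in a calibration
of the test's false-positive rate.

## Degenerate inputs and numeric choices

Empty DSB set → enrichment warns and returns p = 1 (genic fraction and
radial scoring raise instead, as their outputs would be undefined). Empty
feature set → observed 0 and p = 1 (ties count as exceedance). An
interval longer than its chromosome is an input error for the shuffle. A
gene size class with zero total length reports density `None`. Matrix
construction is deterministic; only the classifier and null-sampler vary
with their seeds, and every result object records the seed it used.

## Problem sizes used by the automated checks

Acceptance-style checks run at the generator defaults (30-Mb genome,
1000-iteration enrichment): 200 datasets for null calibration, 100 for
planted recovery, 20 seeded runs for each classifier property, 3000
seeded shuffles for the uniformity chi-square — sizes chosen so the full
suite completes in a few minutes on one core while keeping every binomial
acceptance band comfortably wider than Monte-Carlo noise.

## Known limitations

- The enrichment null models no exclusion zones; on real genomes with
  assembly gaps the test is slightly liberal for features depleted in
  gaps.
- `all`-mode profiles count DSB–feature pairs, so dense feature clusters
  can count one DSB repeatedly; `nearest` mode is the default reading.
- Out-of-bag AUROC is a near-unbiased but slightly pessimistic estimate
  relative to a fully refit held-out evaluation.
- The bigWig reader materializes the whole file as segments; it is meant
  for moderate-resolution tracks, not base-pair-resolution whole-genome
  coverage.
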