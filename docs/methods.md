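# Methods

This note documents the models, parameter choices and numerical details
behind `consensv`, and what its simulation-based tests do and do not
establish about real data.

## Data model and coordinate conventions

Internally all intervals are 0-based half-open, so `end - start` is
always the reference-span length. On-disk formats keep their native
conventions: the tab-separated call/locus dialect and VCF are 1-based
inclusive (a record with POS=101, END=200 is the internal span
`[100, 200)`), BED is 0-based half-open. One deliberate VCF quirk is
handled on read: when htslib derives a symbolic record's end from SVLEN
rather than END it adds one extra base; the reader normalizes this so
that END- and SVLEN-specified records of the same event agree.

Calls are unstranded reference intervals — the three-type reduction
(DEL / INS / MIS) carries no strand or orientation. Insertions may have
an empty reference span; their `size` is the inserted-sequence length
estimate. Copy-number gains and duplications are represented as INS at
the duplicated span with `APPROXIMATE` precision, because intensity- and
depth-based detection says nothing about where the extra copy landed.
Zygosity per call, breakend algebra and multi-sample records are out of
scope.

## Clustering

**Spanning events.** Two DEL or MIS calls on the same chromosome are
linked iff their reciprocal overlap strictly exceeds the threshold for
their pair, and clusters are connected components (so membership is
transitive: a chain A–B–C clusters even when A–C alone would not).
Threshold lookup precedence: explicit source-pair override → explicit
precision-class-pair override → 0.2 if either call is from an
outer-boundary source → 0.5 default. The looser outer-boundary default
reflects that genome-map calls only bracket events, so demanding 50%
reciprocal overlap against an exact-breakpoint call would reject true
matches. All values are user-configurable; thresholds must lie in
(0, 1] and are validated before any compute.

**Insertions.** Each INS call is reduced to a representative breakpoint
— the midpoint of its reference span (equal to the start for zero-span
calls), chosen because it is symmetric under breakpoint jitter. Mean
shift with a flat kernel moves each point to the mean of the points
within its own bandwidth, iterating until movement < 1 bp or 100
iterations. Bandwidths are per precision class (20 bp breakpoint-exact,
300 bp approximate, 5,000 bp outer boundary): the scales are ordered by
the semantics of the classes and adjustable; nothing in the method
depends on their exact values. Two calls are co-clustered
(transitively) when their converged modes lie within the larger of
their two bandwidths, letting a coarse caller adopt a precise one
without forcing precise callers apart.

**Consensus and idempotence.** A cluster's locus takes its coordinates
from the most precise members (breakpoint > approximate > outer
boundary), with the median of starts/ends breaking ties among equally
precise members. Median consensus has one subtle consequence: the
consensus span of a chained cluster is pulled toward its middle, and
two clusters that were never linked can end up with consensus spans
whose reciprocal overlap exceeds the threshold. The merge step
therefore iterates to a fixed point — consensus loci are re-clustered
(represented by pseudo-calls carrying their most precise member's
class) until no further merge occurs. This guarantees that emitted loci
re-cluster to singletons under the same configuration, i.e. the locus
set is maximally merged. Convergence is certain because the cluster
count strictly decreases; in practice one extra iteration at most is
seen on realistic densities.

A size gate (default 100 bp – 1 Mbp, inclusive) is applied before
clustering. Clustering is stratified by chromosome and canonical type;
inter-chromosomal events and decomposition of single outer-boundary
calls into multiple events are not modeled.

## Support scoring

The bitflag is `4·assembly + 2·multi_source + 1·force_called`.

*Assembly / force-call consistency.* An evidence event matches a DEL or
INS locus when the types agree, the event length is within ±50%
(relative tolerance, configurable) of the predicted size, and the event
position lies within the locus span ± 2,000 bp — the same flank used to
extract sequence for local assembly, so evidence outside it could not
have been observed. MIS loci (e.g. inversions) have no single indel
signature; they are accepted on any discontinuous-alignment event
covering ≥ 50% of the locus span. These numeric criteria are this
package's choices; the tolerance is deliberately loose because
assembled and remapped sizes of true events routinely deviate by tens
of percent in repeat-rich contexts.

*Force calling* accepts a locus when at least one spanning long read is
consistent — deliberately weaker than assembly support. The bit is
withheld from loci whose only discovery source is the force-calling
technology itself, since a method's own reads corroborating its own
call carry no independent information.

*Multi-source* counts distinct data sources (technologies), not
programs: five short-read callers on the same library are one source.

Evidence is consumed as pre-extracted records (TSV, or an optional
SAM/BAM adapter that takes CIGAR indels ≥ 50 bp); running the assembler
and aligner themselves is out of scope.

## Annotation

Known-variant matching requires the same canonical type and reciprocal
overlap ≥ 0.5 against the merged locus span. Note the comparator is
inclusive here but strict in clustering — the two rules are
intentionally different and separately tested. The exonic summary
restricts to loci with span < 100 kbp (avoiding a handful of huge
events dominating the base-pair accounting), merges overlapping locus
spans and overlapping exons before counting, and reports overlap bp,
exon records hit, and the fraction of merged exon sequence covered.

## SNP concordance (homozScore)

For a deletion locus, `homozScore = #HOM / (#HOM + #HET)` over the
genotyped SNVs inside the locus span. The statistic rests on a simple
model: a hemizygous deletion in unique sequence leaves one haplotype,
so every SNV there should be called homozygous. Gates:

* at least 5 SNVs in the region, otherwise the score is undefined and
  excluded from summaries (small counts make the fraction meaningless);
* concordance requires a score strictly greater than 0.8 rather than 1,
  absorbing genotyping error and breakpoint imprecision;
* mean regional coverage classifies interpretability: < 25X (about half
  a 48X genome average — what a hemizygous deletion should show) marks
  likely-unique sequence; > 50X suggests a paralogous region whose
  mis-mapped reads create spurious heterozygotes. Both thresholds are
  configurable and should track the dataset's genome-wide coverage.

Genotypes are read from standard VCF GT fields (0/1 and 1/2 → HET,
1/1 → HOM; hom-ref and half-missing genotypes skipped; PASS biallelic
SNVs only). X/Y handling and phasing are out of scope; callers should
restrict input loci to autosomes.

## Evaluation

Per-caller FDR = unsupported/total called; sensitivity =
supported/|support set|. The support-set denominator is always the one
supplied by the caller of the function and is echoed in the output
header, because published sensitivity figures are frequently ambiguous
about their denominator. The source-pair matrix counts loci containing
both sources off-diagonal and exactly-one-source loci on the diagonal.
Size histograms use log-spaced bins with strict bounds (100 bp < size
< 100 kbp by default).

## Simulator

The generator emulates the statistical structure the pipeline assumes,
not sequence-level reality. Defaults describe the study conditions the
package targets:

* **Genome**: 22 autosomes at hg19-scale lengths (~2.88 Gbp).
  Coordinates only; no sequence, repeats or mappability.
* **Truth set**: 2,000 non-overlapping events, split
  DEL/INS/MIS = 1040/905/55 (the ~52/45/3 proportions of multi-source
  personal-genome SV sets). Sizes mix a normal Alu-like mode
  (300 ± 30 bp, weight 0.4 — the dominant feature of human indel-SV
  size spectra) with a log-uniform component over 100 bp – 1 Mbp.
  Non-overlap (500 bp minimum spacing) keeps locus↔truth matching
  unambiguous.
* **Call sets**: two sources by default — a short-read paired-end
  caller (approximate precision) and a long-read caller (breakpoint
  precision) — each with sensitivity 0.9 and FDR 0.1. Breakpoint jitter
  sd for an event of size s is `min(0.05·s, 150 bp)`: proportional for
  small events, saturating at insert-size/probe-spacing scale, since no
  caller's breakpoint error grows without bound with event size (and a
  multi-kbp error could never be corroborated from a 2-kbp assembly
  window anyway). Reported sizes get 5% relative error. Spurious calls
  are placed away from truth events at a rate giving the configured
  expected false fraction.
* **SNVs and coverage**: 1 SNV/kbp inside deletion loci. True unique
  deletions: HOM with probability 1 − e (e = 0.02 genotyping error) at
  half the 48X genome coverage. False loci: HET with probability
  h = 0.6 (a typical het share of variant sites) at full coverage. A
  5% paralog-like fraction gets doubled coverage and 50% spurious
  heterozygotes regardless of truth.
* **Evidence**: truth-matched loci yield a consistent contig with
  probability 0.8 (local assembly does not always produce the variant
  allele) and Poisson(10) spanning long reads (10X long-read depth),
  each consistent with probability 0.5 (a heterozygous event appears in
  about half the reads). Spurious loci yield records with no events.

All sampling flows from one seed through fixed per-stage streams
(truth / per-source call sets / SNVs / evidence), so stages can be
re-run independently and the full pipeline is byte-deterministic.

**What passing tests show — and don't.** On this generator the pipeline
recovers ≥ 95% of truth events as supported loci and reproduces each
caller's configured FDR within binomial error, and homozScore matches
its analytic expectations (mean 1 − e on true deletions, 1 − h on false
ones). These are internal-consistency guarantees: real data add
mappability structure, clustered and overlapping events, complex
rearrangements, reference errors and caller-correlated artifacts that
the simulator deliberately omits, so measured performance on real
genomes will be worse and must be established against orthogonal
validation, not inferred from these tests.

## Problem sizes and numerical choices

The test suite and the reference script run simulations at 2,000 truth
events (≈ 4,000 calls) — large enough for 3-sigma binomial checks on
rates near 0.1 while keeping the whole suite in seconds. Mean-shift
convergence uses a 1 bp movement tolerance and a 100-iteration cap;
median consensus coordinates round half away from zero and swap
inverted spans defensively; degenerate inputs (empty call sets, empty
clusters, zero-length intervals, empty support sets) return empty
results or explicit errors rather than NaNs, except sensitivity against
an empty support set, which is NaN and flagged.

## Known limitations

* Outer-boundary calls spanning multiple distinct events are treated as
  one call; decomposing them requires curation the package does not do.
* The MIS consistency rule (≥ 50% span coverage by any discontinuous
  alignment) is a minimal testable contract, not a model of inversion
  breakpoint geometry.
* The simulator's spurious calls are uniform over the genome, while
  real artifacts concentrate at repeats and assembly gaps; measured
  FDRs on real data are therefore source-correlated in ways the
  recovery tests cannot exercise.
* Insertion placement is local: insertional translocations (sequence
  gained far from its origin) are not represented.
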