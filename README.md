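# consensv

Consensus structural-variant (SV) merging, evidence scoring and
benchmarking across heterogeneous data sources.

## The problem

No single SV caller or data type sees the whole picture of structural
variation in a personal genome: paired-end short reads, read-depth
profiles, split reads, long reads, mate-pair libraries, aCGH and
genome-mapping platforms each detect different event types, sizes and
contexts, with very different breakpoint precision and error profiles.
`consensv` is an infrastructure for combining them. It takes per-caller
call sets, standardizes them, merges them into *reference-inconsistent
loci* (regions where at least one method disagrees with the reference
assembly — true SVs or mapping artifacts), and then scores every locus
with independent evidence so that downstream analysis can rank loci by
degree of corroboration instead of trusting any single method.

It is aimed at people building or evaluating SV call sets: genome
analysts merging multi-technology data for one sample, and method
developers who need a controlled benchmark with a known truth set.

## The method

**Standardization.** Every caller-specific record is reduced to one of
three canonical types: deletion (DEL, sample missing reference
sequence), insertion (INS, sample has extra sequence), and mismatch
(MIS, different sequence over a reference span, e.g. inversions).
Duplications and copy-number gains become insertions at the duplicated
span, since array/read-depth data carry no placement information for
the extra copy. Each call carries a precision class: `BREAKPOINT`
(exact-breakpoint callers), `APPROXIMATE` (read-depth, aCGH), or
`OUTER_BOUNDARY` (genome maps reporting only the enclosing region).

**Clustering.** Reference-spanning events (DEL, MIS) are linked when
their reciprocal overlap

    RO(A, B) = min(|A ∩ B| / |A|, |A ∩ B| / |B|)

strictly exceeds a per-pair threshold (default 0.5; 0.2 for any pair
involving an outer-boundary source), and loci are the connected
components of the link graph, stratified by chromosome and type.
Insertions, which have near-zero reference span and breakpoints shifted
by repeats and microhomology, are instead clustered by 1-D mean shift
(flat kernel) on their representative breakpoints, with per-precision
bandwidths (20 / 300 / 5,000 bp) so precise callers cluster at smaller
scales. Consensus locus coordinates come from the most precise members
(median tie-break). A size gate of 100 bp – 1 Mbp is applied first.

**Support bitflag.** Each locus is scored 0–7:

| bit | evidence |
|----:|----------|
|  +4 | assembly support — a locally assembled contig, remapped to the reference, shows an event consistent in type and size (±50%) within 2,000 bp of the locus |
|  +2 | multi-source support — calls from ≥ 2 distinct technologies (programs on the same data count once) |
|  +1 | long-read force call — ≥ 1 spanning long read consistent with the event (withheld when the locus was discovered only by the long-read source) |

A locus with bitflag > 0 is a supported SV; e.g. assembly + multi-source
= 6, no support = 0.

**Annotation and concordance.** Loci are matched against a known-variant
catalog (same type, reciprocal overlap ≥ 0.5 — inclusive, unlike the
strict clustering comparison) and feature tracks (genes, exons, gaps,
repeats), with an exonic-content summary over sub-100-kbp loci. For
deletion loci, the `homozScore` — the fraction of homozygous SNVs inside
the predicted deletion — checks concordance with SNV genotypes: a real
hemizygous deletion in unique (low-coverage) sequence should show only
homozygous SNVs, so a score > 0.8 over ≥ 5 SNVs is called concordant.

**Evaluation.** Against any support set (assembly-supported loci, or a
simulated truth), the package reports per-caller FDR
(= unsupported/total called) and sensitivity (= supported/|support
set|), a symmetric source-pair support matrix, and log-spaced size
histograms per type.

**Simulation.** A seeded generator produces non-overlapping truth SVs
(log-uniform sizes with an Alu-like mode at ~300 bp), per-source noisy
call sets (configurable sensitivity, FDR, breakpoint jitter, size
error), SNV genotypes with coverage (hemizygous deletions at half
coverage; paralog-like loci at elevated coverage with spurious
heterozygotes), and contig/long-read evidence records — so every stage
of the pipeline is testable offline with full determinism under one
seed.

## Worked example

Simulate a 400-event study with two sources (a short-read caller and a
long-read caller, sensitivity 0.9, FDR 0.1 each), merge, score, and
benchmark:

```
$ consensv simulate --seed 7 --n-sv 400 --out-dir demo/sim
simulated 400 truth events -> 799 calls -> 489 loci

$ consensv support --loci demo/sim/loci.tsv --contigs demo/sim/contigs.tsv \
      --reads demo/sim/reads.tsv --out-dir demo/sup
scored 489 loci; 396 supported (bitflag > 0)

$ consensv evaluate --loci demo/sup/loci_scored.tsv --out-dir demo/eval
     caller  total_called  supported  unsupported      fdr  sensitivity
BreakDancer           395        353           42 0.106329     0.891414
    PBHoney           404        353           51 0.126238     0.891414
```

Reading: 799 noisy calls merged into 489 loci (truth events seen by both
sources collapse to one locus; ~10% of each call set is spurious and
stays unsupported). With the supported loci as the support set, each
caller's measured FDR lands near its configured 0.1 and each recovers
~89% of the supported set. The concordance stage separates locus
classes as the statistic intends:

```
$ consensv concordance --loci demo/sup/loci_scored.tsv --snvs demo/sim/snvs.vcf \
      --coverage demo/sim/coverage.tsv --out-dir demo/conc
$ cat demo/conc/concordance_summary.tsv
class	n	n_concordant	fraction
supported-high-cov	8	0	0.0000
supported-low-cov	36	36	1.0000
supported-mid-cov	38	38	1.0000
unsupported	15	1	0.0667
```

True deletions in unique sequence (coverage < 25X) are homozygous-
concordant; paralog-like high-coverage loci and unsupported (false)
deletions are not.

All thresholds and bandwidths live in one YAML config (see
`consensv.PipelineConfig`); every run writes a JSON manifest with the
effective config, input digests and seed.

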