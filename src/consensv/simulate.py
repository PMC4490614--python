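"""Synthetic truth sets, noisy call sets, SNV genotypes and evidence.

The generator emulates the statistical structure the consensus pipeline
assumes, so every stage is testable offline:

* a **truth set** of non-overlapping deletions, insertions and mismatches
  whose size distribution mixes a log-uniform component over
  [100 bp, 1 Mbp] with an Alu-like mode near 300 bp (the characteristic
  peak of Alu transposon dimorphisms in human SV size spectra);
* per-source **call sets**: each truth event is reported with the
  profile's sensitivity, with Gaussian breakpoint jitter and relative size
  error; spurious calls are added so the expected false fraction of the
  emitted set equals the profile's FDR;
* **SNV genotypes** for deletion loci: SNVs inside true deletions are
  homozygous apart from a genotyping-error rate, SNVs inside false
  deletions are heterozygous at the genome het fraction; each locus also
  receives a mean coverage, elevated for a configurable fraction of
  paralog-like regions;
* **evidence records**: truth-matched loci yield consistent contigs and
  long reads at configured rates; spurious loci yield records with no
  consistent events.

All randomness derives from a single top-level seed through fixed
per-stage streams, so stages can be re-run independently and the full
pipeline is byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import ConsensvError, Locus, Precision, SVCall, SVType
from .clustering import reciprocal_overlap
from .concordance import SNVRecord, Zygosity
from .support import EvidenceEvent, EvidenceRecord

#: Approximate human autosome lengths (Mbp-rounded), hg19 scale.
DEFAULT_GENOME: tuple[tuple[str, int], ...] = tuple(
    (f"chr{i}", length * 1_000_000)
    for i, length in enumerate(
        [249, 243, 198, 191, 181, 171, 159, 146, 141, 136,
         135, 134, 115, 107, 103, 90, 81, 78, 59, 63, 48, 51],
        start=1,
    )
)


@dataclass(frozen=True)
class TruthSV:
    id: str
    chrom: str
    start: int
    end: int  # == start for insertions
    svtype: SVType
    size: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class SourceProfile:
    """Noise profile of one (caller, data source) pair.

    Breakpoint jitter sd (bp) for an event of size ``s`` is
    ``jitter_bp + min(jitter_frac * s, jitter_cap_bp)``: proportional to
    event size for small events but saturating at the method's intrinsic
    resolution (insert-size / probe-spacing scale), since no caller's
    breakpoint error grows without bound with event size.
    ``size_error_frac`` is the relative sd of the reported size.
    """

    caller: str
    source: str
    precision: Precision = Precision.BREAKPOINT
    sensitivity: float = 0.9
    fdr: float = 0.1
    jitter_frac: float = 0.05
    jitter_bp: float = 0.0
    jitter_cap_bp: float = 150.0
    size_error_frac: float = 0.05

    def jitter_sd(self, size: int) -> float:
        return self.jitter_bp + min(self.jitter_frac * size, self.jitter_cap_bp)

    def __post_init__(self) -> None:
        for name in ("sensitivity", "fdr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConsensvError(f"profile {self.caller}: {name}={v} outside [0,1]")
        if self.fdr >= 1.0 and self.sensitivity > 0:
            raise ConsensvError("fdr must be < 1")


@dataclass
class SnvConfig:
    het_fraction: float = 0.6  # HET probability outside real deletions
    genotype_error: float = 0.02  # P(HET call) inside a real unique deletion
    density_per_kbp: float = 1.0
    mean_coverage: float = 48.0  # genome-wide short-read average
    coverage_sd: float = 8.0
    deletion_coverage_factor: float = 0.5  # hemizygous deletion: one haplotype left
    paralog_fraction: float = 0.05  # loci sitting in paralog-like sequence
    paralog_multiplier: float = 2.0  # their apparent coverage multiplier
    paralog_het_fraction: float = 0.5  # mis-mapped paralog reads fake heterozygotes


@dataclass
class EvidenceConfig:
    contig_rate: float = 0.8  # P(a true locus yields a consistent contig)
    long_read_depth: float = 10.0  # mean spanning long reads per locus
    consistent_read_fraction: float = 0.5
    size_noise_frac: float = 0.05
    position_jitter_bp: float = 50.0


@dataclass
class SimConfig:
    """End-to-end simulation conditions.

    Defaults mirror the study design the pipeline targets: ~2,000 truth
    events split DEL/INS/MIS roughly 52/45/3, two data sources (a
    short-read caller and a long-read caller) at sensitivity 0.9 and FDR
    0.1, Illumina-scale 48X coverage, and 10X long-read depth.
    """

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    n_sv: dict = field(
        default_factory=lambda: {SVType.DEL: 1040, SVType.INS: 905, SVType.MIS: 55}
    )
    size_min: int = 100
    size_max: int = 1_000_000
    alu_weight: float = 0.4
    alu_size: float = 300.0
    alu_sd: float = 30.0
    min_gap: int = 500  # enforced spacing between truth events
    profiles: list[SourceProfile] = field(
        default_factory=lambda: [
            SourceProfile(
                caller="BreakDancer", source="Illumina HiSeq", precision=Precision.APPROXIMATE
            ),
            SourceProfile(
                caller="PBHoney", source="PacBio RS", precision=Precision.BREAKPOINT
            ),
        ]
    )
    snv: SnvConfig = field(default_factory=SnvConfig)
    evidence: EvidenceConfig = field(default_factory=EvidenceConfig)


# fixed per-stage stream tags so stages can be re-run independently
_STAGE = {"truth": 1, "callset": 2, "snv": 3, "evidence": 4, "spurious": 5}


def _rng(config_seed: int, stage: str, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng([_STAGE[stage], sub, int(config_seed)])


def _sample_sizes(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """Mixture: Alu-like normal mode at ~300 bp + log-uniform [size_min, size_max]."""
    is_alu = rng.random(n) < cfg.alu_weight
    sizes = np.empty(n)
    n_alu = int(is_alu.sum())
    sizes[is_alu] = rng.normal(cfg.alu_size, cfg.alu_sd, n_alu)
    log_lo, log_hi = np.log(cfg.size_min), np.log(cfg.size_max)
    sizes[~is_alu] = np.exp(rng.uniform(log_lo, log_hi, n - n_alu))
    return np.clip(np.round(sizes), cfg.size_min, cfg.size_max).astype(int)


class _Placer:
    """Rejection-samples non-overlapping positions on the genome."""

    def __init__(self, genome: Sequence[tuple[str, int]], min_gap: int):
        self.genome = list(genome)
        self.min_gap = min_gap
        lengths = np.array([l for _, l in self.genome], dtype=float)
        self.weights = lengths / lengths.sum()
        self.trees: dict[str, IntervalTree] = {c: IntervalTree() for c, _ in self.genome}

    def place(self, rng: np.random.Generator, span: int, max_tries: int = 200) -> tuple[str, int]:
        for _ in range(max_tries):
            ci = rng.choice(len(self.genome), p=self.weights)
            chrom, length = self.genome[ci]
            if length <= span + 2 * self.min_gap:
                continue
            start = int(rng.integers(self.min_gap, length - span - self.min_gap))
            if not self.trees[chrom].overlap(start - self.min_gap, start + span + self.min_gap):
                return chrom, start
        raise ConsensvError(
            "could not place event without overlap; genome too small for the "
            "requested number/size of events"
        )

    def reserve(self, chrom: str, start: int, span: int) -> None:
        self.trees[chrom].addi(start, start + max(span, 1))


def simulate_truth(config: SimConfig) -> list[TruthSV]:
    """Draw the non-overlapping truth SV set; deterministic under the seed."""
    max_len = max((l for _, l in config.genome), default=0)
    if max_len <= config.size_max + 2 * config.min_gap and sum(config.n_sv.values()) > 0:
        raise ConsensvError("genome chromosomes must exceed the maximum SV size")
    rng = _rng(config.seed, "truth")
    placer = _Placer(config.genome, config.min_gap)
    events: list[TruthSV] = []
    k = 0
    for svtype in (SVType.DEL, SVType.INS, SVType.MIS):
        n = int(config.n_sv.get(svtype, 0))
        sizes = _sample_sizes(rng, n, config)
        for size in sizes:
            span = 0 if svtype == SVType.INS else int(size)
            # reserve the insertion's size on the reference too, so a later
            # deletion cannot be drawn on top of an insertion breakpoint
            reserve_span = max(int(size), 1)
            chrom, start = placer.place(rng, reserve_span)
            placer.reserve(chrom, start, reserve_span)
            k += 1
            events.append(
                TruthSV(
                    id=f"truth_{k:05d}",
                    chrom=chrom,
                    start=start,
                    end=start + span,
                    svtype=svtype,
                    size=int(size),
                )
            )
    events.sort(key=lambda e: (e.chrom, e.start, e.id))
    return events


def simulate_callset(
    truth: Sequence[TruthSV],
    profile: SourceProfile,
    seed: int,
    *,
    genome: Sequence[tuple[str, int]] = DEFAULT_GENOME,
    size_min: int = 100,
    size_max: int = 1_000_000,
    _sub: int = 0,
    _config: SimConfig | None = None,
) -> list[SVCall]:
    """Emit one noisy call set from a truth set under a source profile.

    Each truth event is reported with probability ``sensitivity``, its
    breakpoints jittered (sd = jitter_bp + jitter_frac * size) and size
    perturbed.  Spurious calls, drawn from the same size distribution and
    placed away from every truth event, are appended so the expected false
    fraction equals ``fdr``.
    """
    cfg = _config or SimConfig(seed=seed, genome=tuple(genome), size_min=size_min, size_max=size_max)
    rng = _rng(seed, "callset", _sub)
    calls: list[SVCall] = []
    k = 0
    for ev in truth:
        if rng.random() >= profile.sensitivity:
            continue
        sd = profile.jitter_sd(ev.size)
        if ev.svtype == SVType.INS:
            pos = max(0, int(round(ev.start + rng.normal(0, sd))))
            size = max(1, int(round(ev.size * (1 + rng.normal(0, profile.size_error_frac)))))
            start = end = pos
        else:
            start = int(round(ev.start + rng.normal(0, sd)))
            end = int(round(ev.end + rng.normal(0, sd)))
            if end < start:
                start, end = end, start
            start = max(0, start)
            end = max(start + 1, end)
            size = end - start
        k += 1
        calls.append(
            SVCall(
                id=f"{profile.caller}_{k:05d}",
                caller=profile.caller,
                source=profile.source,
                chrom=ev.chrom,
                start=start,
                end=end,
                svtype=ev.svtype,
                size=size,
                precision=profile.precision,
                original_type=ev.svtype.value,
            )
        )

    # spurious calls: expected fraction fdr of the emitted set
    n_true = len(calls)
    if profile.fdr > 0 and n_true > 0:
        n_spur = int(rng.poisson(n_true * profile.fdr / (1.0 - profile.fdr)))
    elif profile.fdr > 0:
        n_spur = int(rng.poisson(10))  # sensitivity 0: still emit noise
    else:
        n_spur = 0
    if n_spur:
        placer = _Placer(cfg.genome, cfg.min_gap)
        for ev in truth:
            placer.reserve(ev.chrom, ev.start, max(ev.size, 1))
        types = [SVType.DEL, SVType.INS, SVType.MIS]
        probs = np.array([cfg.n_sv.get(t, 0) for t in types], dtype=float)
        probs = probs / probs.sum() if probs.sum() else np.array([1 / 3] * 3)
        sizes = _sample_sizes(rng, n_spur, cfg)
        for size in sizes:
            svtype = types[int(rng.choice(3, p=probs))]
            chrom, start = placer.place(rng, int(size))
            placer.reserve(chrom, start, int(size))
            span = 0 if svtype == SVType.INS else int(size)
            k += 1
            calls.append(
                SVCall(
                    id=f"{profile.caller}_{k:05d}",
                    caller=profile.caller,
                    source=profile.source,
                    chrom=chrom,
                    start=start,
                    end=start + span,
                    svtype=svtype,
                    size=int(size),
                    precision=profile.precision,
                    original_type=svtype.value,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.id))
    return calls


def simulate_callsets(truth: Sequence[TruthSV], config: SimConfig) -> dict[str, list[SVCall]]:
    """One call set per configured profile, keyed by caller name."""
    return {
        profile.caller: simulate_callset(
            truth, profile, config.seed, _sub=i, _config=config
        )
        for i, profile in enumerate(config.profiles)
    }


def match_loci_to_truth(
    loci: Sequence[Locus],
    truth: Sequence[TruthSV],
    min_ro: float = 0.5,
    ins_max_distance: int | None = None,
) -> dict[str, str]:
    """Map locus id -> truth id for loci explained by a truth event.

    Reference-spanning loci match a same-type truth event at reciprocal
    overlap >= min_ro.  Insertion loci (near-zero span) match the nearest
    truth insertion whose breakpoint lies within ``ins_max_distance``
    (default: max(300 bp, half the truth size)) and whose size agrees
    within a factor of two.
    """
    matches: dict[str, str] = {}
    span_truth: dict[str, IntervalTree] = {}
    ins_truth: dict[str, list[TruthSV]] = {}
    for ev in truth:
        if ev.svtype == SVType.INS:
            ins_truth.setdefault(ev.chrom, []).append(ev)
        else:
            span_truth.setdefault(ev.chrom, IntervalTree()).addi(ev.start, ev.end, ev)
    for chrom in ins_truth:
        ins_truth[chrom].sort(key=lambda e: e.start)

    for locus in loci:
        if locus.svtype == SVType.INS:
            candidates = ins_truth.get(locus.chrom, [])
            pos = locus.midpoint
            best = None
            for ev in candidates:
                limit = ins_max_distance if ins_max_distance is not None else max(
                    300, ev.size // 2
                )
                d = abs(ev.start - pos)
                if d > limit:
                    continue
                ratio = locus.size / ev.size if ev.size else 0.0
                if not 0.5 <= ratio <= 2.0:
                    continue
                if best is None or d < best[0]:
                    best = (d, ev)
            if best is not None:
                matches[locus.id] = best[1].id
        else:
            tree = span_truth.get(locus.chrom)
            if tree is None:
                continue
            best = None
            for iv in tree.overlap(locus.start, locus.end):
                ev = iv.data
                if ev.svtype != locus.svtype:
                    continue
                ro = reciprocal_overlap(locus, ev)
                if ro >= min_ro and (best is None or ro > best[0]):
                    best = (ro, ev)
            if best is not None:
                matches[locus.id] = best[1].id
    return matches


def simulate_snvs(
    deletion_loci: Sequence[Locus],
    truth_match: Mapping[str, str],
    config: SimConfig,
) -> tuple[list[SNVRecord], dict[str, float]]:
    """SNV genotypes and mean coverage for deletion loci.

    Inside loci that match a true deletion, SNVs are homozygous with
    probability 1 - genotype_error (the deleted haplotype cannot
    contribute a second allele); inside false-deletion loci they are
    heterozygous with probability het_fraction.  A ``paralog_fraction``
    of loci emulates paralogous sequence: apparent coverage is multiplied
    and mis-mapped paralog reads produce heterozygous calls even over a
    real deletion.  True unique deletions get roughly half the genome
    average coverage (one haplotype remains); false loci sit at the
    genome average.
    """
    rng = _rng(config.seed, "snv")
    snv_cfg = config.snv
    snvs: list[SNVRecord] = []
    coverage: dict[str, float] = {}
    for locus in sorted(deletion_loci, key=lambda l: (l.chrom, l.start, l.id)):
        if locus.svtype != SVType.DEL:
            continue
        is_true = locus.id in truth_match
        is_paralog = rng.random() < snv_cfg.paralog_fraction
        if is_paralog:
            mean = snv_cfg.mean_coverage * snv_cfg.paralog_multiplier
        elif is_true:
            mean = snv_cfg.mean_coverage * snv_cfg.deletion_coverage_factor
        else:
            mean = snv_cfg.mean_coverage
        coverage[locus.id] = max(0.0, float(rng.normal(mean, snv_cfg.coverage_sd)))
        n = int(rng.poisson(snv_cfg.density_per_kbp * locus.span / 1000.0))
        if n == 0:
            continue
        positions = np.sort(rng.integers(locus.start, max(locus.end, locus.start + 1), n))
        for pos in positions:
            if is_paralog:
                p_het = snv_cfg.paralog_het_fraction
            elif is_true:
                p_het = snv_cfg.genotype_error
            else:
                p_het = snv_cfg.het_fraction
            zyg = Zygosity.HET if rng.random() < p_het else Zygosity.HOM
            snvs.append(SNVRecord(chrom=locus.chrom, pos=int(pos), zygosity=zyg))
    snvs.sort(key=lambda s: (s.chrom, s.pos))
    return snvs, coverage


def simulate_evidence(
    loci: Sequence[Locus],
    truth: Sequence[TruthSV],
    config: SimConfig,
    truth_match: Mapping[str, str] | None = None,
) -> tuple[list[EvidenceRecord], list[EvidenceRecord]]:
    """Contig and long-read evidence for merged loci.

    Truth-matched loci receive a consistent contig with probability
    ``contig_rate`` and Poisson(``long_read_depth``) spanning long reads,
    each consistent with probability ``consistent_read_fraction``.
    Spurious loci receive contigs/reads carrying no events.
    Returns (contig_records, read_records).
    """
    if truth_match is None:
        truth_match = match_loci_to_truth(loci, truth)
    truth_by_id = {ev.id: ev for ev in truth}
    ev_cfg = config.evidence
    rng = _rng(config.seed, "evidence")
    contig_records: list[EvidenceRecord] = []
    read_records: list[EvidenceRecord] = []

    def consistent_event(ev: TruthSV) -> EvidenceEvent:
        op = SVType.DEL if ev.svtype in (SVType.DEL, SVType.MIS) else SVType.INS
        length = max(1, int(round(ev.size * (1 + rng.normal(0, ev_cfg.size_noise_frac)))))
        if ev.svtype == SVType.MIS:
            # a mismatch shows as a discontinuous alignment covering the span
            pos, length = ev.start, max(ev.span, 1)
        else:
            pos = max(0, int(round(ev.start + rng.normal(0, ev_cfg.position_jitter_bp))))
        return EvidenceEvent(op=op, position=pos, length=length)

    for locus in sorted(loci, key=lambda l: (l.chrom, l.start, l.id)):
        matched = truth_by_id.get(truth_match.get(locus.id, ""))
        if rng.random() < ev_cfg.contig_rate:
            events = (consistent_event(matched),) if matched is not None else ()
            contig_records.append(
                EvidenceRecord(
                    locus_id=locus.id,
                    kind="CONTIG",
                    events=events,
                    spans_locus=True,
                    record_id=f"{locus.id}_contig",
                )
            )
        n_reads = int(rng.poisson(ev_cfg.long_read_depth))
        for r in range(n_reads):
            consistent = (
                matched is not None and rng.random() < ev_cfg.consistent_read_fraction
            )
            read_records.append(
                EvidenceRecord(
                    locus_id=locus.id,
                    kind="LONG_READ",
                    events=(consistent_event(matched),) if consistent else (),
                    spans_locus=True,
                    record_id=f"{locus.id}_read{r}",
                )
            )
    return contig_records, read_records


# ---------------------------------------------------------------------------
# Emitters for the plain-text interchange artifacts.

def write_truth_bed(truth: Sequence[TruthSV], path: str | Path) -> None:
    """Truth events as BED6-like rows: chrom, start, end, id, size, type."""
    with open(path, "w") as fh:
        for ev in truth:
            fh.write(
                f"{ev.chrom}\t{ev.start}\t{ev.end}\t{ev.id}\t{ev.size}\t{ev.svtype.value}\n"
            )


def read_truth_bed(path: str | Path) -> list[TruthSV]:
    from .io import read_bed

    truth = []
    for chrom, start, end, *rest in read_bed(path, min_fields=6):
        truth.append(
            TruthSV(
                id=rest[0],
                chrom=chrom,
                start=start,
                end=end,
                size=int(rest[1]),
                svtype=SVType(rest[2]),
            )
        )
    return truth


def write_snv_vcf(
    snvs: Sequence[SNVRecord], genome: Sequence[tuple[str, int]], path: str | Path
) -> None:
    """Minimal genotyped single-sample VCF (synthetic alleles A>G)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=consensv-simulate\n")
        for chrom, length in genome:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for snv in sorted(snvs, key=lambda s: (s.chrom, s.pos)):
            gt = "1/1" if snv.zygosity == Zygosity.HOM else "0/1"
            fh.write(
                f"{snv.chrom}\t{snv.pos + 1}\t.\tA\tG\t60\tPASS\t.\tGT\t{gt}\n"
            )
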