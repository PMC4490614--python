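"""SNP-concordance statistic (homozScore) for deletion loci.

A real hemizygous deletion in unique sequence removes one haplotype, so
every SNV genotyped inside the deleted region should appear homozygous.
The homozScore of a deletion locus is the fraction of its SNVs genotyped
homozygous; scores near 1 corroborate the deletion, while scores near the
genome-wide heterozygous fraction suggest a false call.  To keep the
statistic meaningful:

* only loci containing at least 5 SNVs are scored (smaller counts are
  reported as undefined and excluded from summaries);
* a locus is called concordant when homozScore is strictly greater than
  0.8 rather than 1, absorbing SNV genotyping error and breakpoint
  imprecision;
* the per-locus mean read coverage gates interpretation: regions below
  ~half the genome-wide average (default < 25X for a 48X genome) are
  likely unique, while > 50X suggests a paralogous region whose
  mis-mapped reads produce spurious heterozygotes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .model import ConsensvError, Locus, SVType


class Zygosity(str, Enum):
    HOM = "HOM"
    HET = "HET"


class CoverageClass(str, Enum):
    LOW = "LOW"
    MID = "MID"
    HIGH = "HIGH"


@dataclass(frozen=True)
class SNVRecord:
    chrom: str
    pos: int  # 0-based
    zygosity: Zygosity

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ConsensvError("SNV position must be >= 0")


@dataclass(frozen=True)
class HomozResult:
    locus_id: str
    n_snvs: int
    homoz_score: float | None  # undefined when n_snvs < min_snvs
    mean_coverage: float
    coverage_class: CoverageClass
    concordant: bool  # homoz_score strictly > threshold


@dataclass
class ConcordanceConfig:
    min_snvs: int = 5
    low_cov: float = 25.0
    high_cov: float = 50.0
    score_threshold: float = 0.8


def coverage_class(mean_coverage: float, low_cov: float = 25.0, high_cov: float = 50.0) -> CoverageClass:
    if mean_coverage < low_cov:
        return CoverageClass.LOW
    if mean_coverage > high_cov:
        return CoverageClass.HIGH
    return CoverageClass.MID


def homoz_score(
    locus: Locus,
    snvs: Iterable[SNVRecord],
    mean_coverage: float,
    config: ConcordanceConfig | None = None,
) -> HomozResult:
    """Fraction of homozygous SNVs inside a predicted deletion.

    ``snvs`` may be any SNV collection; only records on the locus
    chromosome with position inside the locus span are counted.  The score
    is undefined (None, never concordant) when fewer than ``min_snvs``
    SNVs fall in the region.
    """
    config = config or ConcordanceConfig()
    if locus.svtype != SVType.DEL:
        raise ConsensvError(
            f"homozScore applies to deletion loci; locus {locus.id!r} is {locus.svtype.value}"
        )
    n_hom = n_het = 0
    for snv in snvs:
        if snv.chrom != locus.chrom or not (locus.start <= snv.pos < locus.end):
            continue
        if snv.zygosity == Zygosity.HOM:
            n_hom += 1
        else:
            n_het += 1
    n = n_hom + n_het
    if n < config.min_snvs:
        score: float | None = None
        concordant = False
    else:
        score = n_hom / n
        concordant = score > config.score_threshold
    return HomozResult(
        locus_id=locus.id,
        n_snvs=n,
        homoz_score=score,
        mean_coverage=mean_coverage,
        coverage_class=coverage_class(mean_coverage, config.low_cov, config.high_cov),
        concordant=concordant,
    )


def score_deletions(
    loci: Sequence[Locus],
    snvs: Sequence[SNVRecord],
    coverage: Mapping[str, float],
    config: ConcordanceConfig | None = None,
) -> list[HomozResult]:
    """homozScore for every deletion locus, indexing SNVs by chromosome."""
    config = config or ConcordanceConfig()
    by_chrom: dict[str, list[SNVRecord]] = {}
    for snv in snvs:
        by_chrom.setdefault(snv.chrom, []).append(snv)
    results = []
    for locus in loci:
        if locus.svtype != SVType.DEL:
            continue
        results.append(
            homoz_score(
                locus,
                by_chrom.get(locus.chrom, []),
                float(coverage.get(locus.id, 0.0)),
                config,
            )
        )
    return results


def concordance_summary(
    results: Sequence[HomozResult],
    bitflags: Mapping[str, int],
    config: ConcordanceConfig | None = None,
) -> pd.DataFrame:
    """Concordant fractions for three locus classes.

    Classes follow the standard presentation: unsupported loci (bitflag
    0), supported SVs in low-coverage (likely unique) regions, and
    supported SVs in high-coverage (likely paralogous) regions.  Only
    results with a defined homozScore contribute.  Returns a table with
    columns class, n, n_concordant, fraction (zero rows when all classes
    are empty).
    """
    config = config or ConcordanceConfig()
    counts: dict[str, list[int]] = {}
    for res in results:
        if res.homoz_score is None:
            continue
        flag = bitflags.get(res.locus_id, 0)
        if flag == 0:
            cls = "unsupported"
        elif res.coverage_class == CoverageClass.LOW:
            cls = "supported-low-cov"
        elif res.coverage_class == CoverageClass.HIGH:
            cls = "supported-high-cov"
        else:
            cls = "supported-mid-cov"
        n, k = counts.setdefault(cls, [0, 0])
        counts[cls][0] = n + 1
        counts[cls][1] = k + int(res.concordant)
    rows = [
        {
            "class": cls,
            "n": n,
            "n_concordant": k,
            "fraction": k / n if n else 0.0,
        }
        for cls, (n, k) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["class", "n", "n_concordant", "fraction"])


def read_snv_vcf(path: str | Path) -> list[SNVRecord]:
    """Read zygosities from a genotyped VCF (first sample).

    PASS (or unfiltered) biallelic SNVs only; genotypes with any missing
    allele are skipped.  Het = any two distinct non-reference-pattern
    alleles (0/1, 1/2); hom-alt (1/1) = HOM.  Hom-ref sites carry no
    information about a deletion and are skipped.
    """
    records: list[SNVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.filter.keys() and "PASS" not in rec.filter.keys():
                continue
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            if not rec.samples:
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or any(a is None for a in gt) or len(gt) != 2:
                continue
            a, b = gt
            if a == b == 0:
                continue
            zyg = Zygosity.HOM if a == b else Zygosity.HET
            records.append(SNVRecord(chrom=rec.chrom, pos=rec.start, zygosity=zyg))
    return records


def write_homoz_tsv(results: Sequence[HomozResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#LOCUS_ID\tN_SNVS\tHOMOZ_SCORE\tMEAN_COV\tCOV_CLASS\tCONCORDANT\n")
        for r in results:
            score = f"{r.homoz_score:.4f}" if r.homoz_score is not None else "."
            fh.write(
                f"{r.locus_id}\t{r.n_snvs}\t{score}\t{r.mean_coverage:.2f}\t"
                f"{r.coverage_class.value}\t{int(r.concordant)}\n"
            )
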