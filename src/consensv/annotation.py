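"""Known-variant catalog matching and genomic feature annotation.

Loci are compared to a catalog of known structural variants (a DGV-style
BED with an SV type per record): a catalog entry matches when it has the
same canonical type and at least 50% reciprocal overlap with the locus
span.  Note the comparator is *inclusive* here (>= min_ro), unlike the
strictly-greater comparison used for clustering.

Feature tracks (genes, exons, gaps, repeats) annotate loci with simple
overlaps; the exonic-content summary reports how much merged exon
sequence the sub-100-kbp loci cover, avoiding large-event bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .model import (
    Annotation,
    AnnotationKind,
    Locus,
    MalformedRecordError,
    SVType,
)
from .clustering import reciprocal_overlap
from .io import read_bed


@dataclass(frozen=True)
class KnownVariant:
    chrom: str
    start: int
    end: int
    svtype: SVType
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise MalformedRecordError(
                f"known variant {self.source_id!r}: end < start"
            )


@dataclass
class FeatureTrack:
    """One kind of genomic feature (GENE, EXON, GAP, REPEAT) as labeled intervals."""

    kind: AnnotationKind
    records: list[tuple[str, int, int, str]]  # (chrom, start, end, label)

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, label in self.records:
            if end <= start:
                continue  # zero-length features carry no overlap
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, label)

    def overlapping(self, chrom: str, start: int, end: int):
        tree = self._trees.get(chrom)
        if tree is None or end <= start:
            return []
        return sorted(tree.overlap(start, end), key=lambda iv: (iv.begin, iv.end, iv.data))


class KnownVariantCatalog:
    """Chromosome-indexed catalog of known SVs."""

    def __init__(self, variants: Iterable[KnownVariant]):
        self.variants = list(variants)
        self._trees: dict[str, IntervalTree] = {}
        for kv in self.variants:
            if kv.end > kv.start:
                self._trees.setdefault(kv.chrom, IntervalTree()).addi(kv.start, kv.end, kv)

    def candidates(self, chrom: str, start: int, end: int) -> list[KnownVariant]:
        tree = self._trees.get(chrom)
        if tree is None or end <= start:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end)),
            key=lambda kv: (kv.start, kv.end, kv.source_id),
        )


def read_catalog(path: str | Path) -> KnownVariantCatalog:
    """Read a BED4+ known-variant catalog: chrom, start, end, type[, id]."""
    variants = []
    for row in read_bed(path, min_fields=4):
        chrom, start, end, svtype, *rest = row
        variants.append(
            KnownVariant(
                chrom=chrom,
                start=start,
                end=end,
                svtype=SVType(svtype),
                source_id=rest[0] if rest else f"{chrom}:{start}-{end}",
            )
        )
    return KnownVariantCatalog(variants)


def read_feature_track(path: str | Path, kind: AnnotationKind | str) -> FeatureTrack:
    """Read a BED track; column 4 (if present) is the feature label."""
    kind = AnnotationKind(kind)
    records = []
    for row in read_bed(path, min_fields=3):
        chrom, start, end, *rest = row
        records.append((chrom, start, end, rest[0] if rest else f"{chrom}:{start}-{end}"))
    return FeatureTrack(kind=kind, records=records)


def match_known(
    locus: Locus,
    catalog: KnownVariantCatalog,
    min_ro: float = 0.5,
) -> list[KnownVariant]:
    """Catalog entries of the same type with reciprocal overlap >= min_ro.

    The locus is labeled "in catalog" iff the returned list is non-empty.
    Deterministic: candidates are returned in genomic order regardless of
    catalog insertion order.
    """
    return [
        kv
        for kv in catalog.candidates(locus.chrom, locus.start, locus.end)
        if kv.svtype == locus.svtype and reciprocal_overlap(locus, kv) >= min_ro
    ]


def annotate_features(locus: Locus, tracks: Sequence[FeatureTrack]) -> list[Annotation]:
    """One annotation per overlapping feature (overlap_bp > 0)."""
    annotations = []
    for track in tracks:
        for iv in track.overlapping(locus.chrom, locus.start, locus.end):
            ov = min(locus.end, iv.end) - max(locus.start, iv.begin)
            if ov <= 0:
                continue
            denom = max(locus.span, iv.end - iv.begin)
            annotations.append(
                Annotation(
                    kind=track.kind,
                    label=str(iv.data),
                    overlap_bp=ov,
                    reciprocal_overlap=(
                        min(ov / locus.span, ov / (iv.end - iv.begin))
                        if locus.span > 0
                        else 0.0
                    ),
                )
            )
    return annotations


def annotate_loci(
    loci: Sequence[Locus],
    catalog: KnownVariantCatalog | None = None,
    tracks: Sequence[FeatureTrack] = (),
    min_ro: float = 0.5,
) -> list[Locus]:
    """Attach known-variant and feature annotations to every locus."""
    out = []
    for locus in loci:
        annotations = []
        if catalog is not None:
            for kv in match_known(locus, catalog, min_ro):
                annotations.append(
                    Annotation(
                        kind=AnnotationKind.KNOWN_VARIANT,
                        label=kv.source_id,
                        overlap_bp=min(locus.end, kv.end) - max(locus.start, kv.start),
                        reciprocal_overlap=reciprocal_overlap(locus, kv),
                    )
                )
        annotations.extend(annotate_features(locus, tracks))
        locus.annotations = annotations
        out.append(locus)
    return out


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def exonic_summary(
    loci: Sequence[Locus],
    exons: FeatureTrack,
    size_cap: int = 100_000,
) -> dict:
    """Exonic SV content for loci with reference span below ``size_cap``.

    Locus spans are merged per chromosome before base-pair accounting, as
    are exons, so overlapping loci/exons are never double-counted.
    Returns n_loci_used, genome_bp_spanned, exonic_bp_overlapped,
    n_exons_hit (exon records touched), and fraction_exonic
    (= exonic bp / total merged exon bp).
    """
    used = [l for l in loci if l.span < size_cap]
    locus_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for l in used:
        if l.span > 0:
            locus_by_chrom.setdefault(l.chrom, []).append((l.start, l.end))
    merged_loci = {c: _merge_intervals(ivs) for c, ivs in locus_by_chrom.items()}

    exon_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _label in exons.records:
        if end > start:
            exon_by_chrom.setdefault(chrom, []).append((start, end))
    merged_exons = {c: _merge_intervals(ivs) for c, ivs in exon_by_chrom.items()}

    genome_bp = sum(e - s for ivs in merged_loci.values() for s, e in ivs)
    total_exon_bp = sum(e - s for ivs in merged_exons.values() for s, e in ivs)

    exonic_bp = 0
    for chrom, locus_ivs in merged_loci.items():
        exon_ivs = merged_exons.get(chrom, [])
        i = j = 0  # two-pointer sweep over sorted disjoint interval lists
        while i < len(locus_ivs) and j < len(exon_ivs):
            ls, le = locus_ivs[i]
            es, ee = exon_ivs[j]
            ov = min(le, ee) - max(ls, es)
            if ov > 0:
                exonic_bp += ov
            if le < ee:
                i += 1
            else:
                j += 1

    n_exons_hit = 0
    for chrom, start, end, _label in exons.records:
        if end <= start:
            continue
        for ls, le in merged_loci.get(chrom, []):
            if ls < end and le > start:
                n_exons_hit += 1
                break

    return {
        "n_loci_used": len(used),
        "genome_bp_spanned": genome_bp,
        "exonic_bp_overlapped": exonic_bp,
        "n_exons_hit": n_exons_hit,
        "fraction_exonic": (exonic_bp / total_exon_bp) if total_exon_bp else 0.0,
    }
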