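"""Evidence scoring: the 0-7 support bitflag per locus.

Each reference-inconsistent locus is assessed on three independent
support characteristics, each carrying a bit value:

* **assembly support (+4)** — at least one locally assembled contig,
  remapped to the reference, shows an event consistent in type and size
  with the predicted SV;
* **multi-source support (+2)** — the locus was discovered by calls from
  at least two distinct data sources (technologies; multiple programs run
  on the same data count once);
* **long-read force calling (+1)** — at least one long read spanning the
  locus is consistent with the predicted event, without requiring
  assembly.  Loci whose only discovery source *is* the force-calling
  technology do not receive this bit (their reads are not independent
  corroboration).

A locus is a supported SV iff its bitflag is non-zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .model import ConsensvError, Locus, SVType
from .io import EVIDENCE_COLUMNS, FormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvidenceEvent:
    """One indel observed when evidence sequence is mapped across a locus."""

    op: SVType  # DEL or INS
    position: int  # 0-based reference position of the event
    length: int  # bp

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConsensvError("evidence event length must be positive")
        if self.op not in (SVType.DEL, SVType.INS):
            raise ConsensvError("evidence event op must be DEL or INS")


@dataclass(frozen=True)
class EvidenceRecord:
    """Events observed from one contig or one long read at a locus."""

    locus_id: str
    kind: str  # "CONTIG" or "LONG_READ"
    events: tuple[EvidenceEvent, ...] = ()
    spans_locus: bool = True
    record_id: str = ""


@dataclass(frozen=True)
class SupportResult:
    locus_id: str
    assembly: bool
    multi_source: bool
    force_called: bool
    bitflag: int

    def __post_init__(self) -> None:
        expected = 4 * self.assembly + 2 * self.multi_source + 1 * self.force_called
        if self.bitflag != expected:
            raise ConsensvError(
                f"bitflag {self.bitflag} inconsistent with booleans (expected {expected})"
            )


@dataclass
class SupportConfig:
    """Consistency tolerances for evidence assessment.

    ``size_tolerance`` is the allowed relative deviation of an observed
    event length from the predicted size; ``window`` is the flank (bp)
    around the locus span within which the event must fall, matching the
    sequence-extraction window used for local assembly.
    ``force_call_source`` names the long-read technology whose reads drive
    force calling; loci discovered only by that source are excluded from
    the force-call bit.
    """

    size_tolerance: float = 0.5
    window: int = 2000
    mis_min_overlap: float = 0.5
    force_call_source: str = "PacBio RS"


def compute_bitflag(assembly: bool, multi: bool, forced: bool) -> int:
    """4*assembly + 2*multi + 1*forced; a locus is a supported SV iff > 0."""
    return 4 * bool(assembly) + 2 * bool(multi) + 1 * bool(forced)


def decompose_bitflag(bitflag: int) -> tuple[bool, bool, bool]:
    """Inverse of :func:`compute_bitflag` (assembly, multi, forced)."""
    if not 0 <= bitflag <= 7:
        raise ConsensvError(f"bitflag {bitflag} outside 0-7")
    return bool(bitflag & 4), bool(bitflag & 2), bool(bitflag & 1)


def assess_consistency(
    locus: Locus,
    evidence: EvidenceRecord | None,
    size_tolerance: float = 0.5,
    window: int = 2000,
    mis_min_overlap: float = 0.5,
) -> bool:
    """Is this evidence record consistent with the predicted event?

    For DEL/INS loci: true iff the record contains an event of matching
    type whose length is within ``size_tolerance`` (relative) of the locus
    size and whose position lies within ``window`` bp of the locus span.
    Mismatch loci (e.g. inversions) have no single indel signature; they
    are supported by any discontinuous-alignment event covering at least
    ``mis_min_overlap`` of the locus span.  Absent or empty evidence is
    never consistent.
    """
    if evidence is None or not evidence.events:
        return False
    lo = locus.start - window
    hi = locus.end + window
    if locus.svtype == SVType.MIS:
        span = max(locus.span, 1)
        for ev in evidence.events:
            ov = min(locus.end, ev.position + ev.length) - max(locus.start, ev.position)
            if ov / span >= mis_min_overlap:
                return True
        return False
    for ev in evidence.events:
        if ev.op != locus.svtype:
            continue
        if not (lo <= ev.position <= hi):
            continue
        if abs(ev.length - locus.size) <= size_tolerance * locus.size:
            return True
    return False


def force_call(
    locus: Locus,
    reads: Iterable[EvidenceRecord],
    size_tolerance: float = 0.5,
    window: int = 2000,
    mis_min_overlap: float = 0.5,
) -> bool:
    """True iff at least one spanning long read is consistent with the event."""
    for read in reads:
        if read.kind != "LONG_READ" or not read.spans_locus:
            continue
        if assess_consistency(locus, read, size_tolerance, window, mis_min_overlap):
            return True
    return False


def multi_source(locus: Locus) -> bool:
    """True iff the locus has calls from >= 2 distinct data sources.

    Sources are technologies, not programs: several programs run on the
    same data contribute one source.
    """
    return len(locus.sources) >= 2


def score_loci(
    loci: Sequence[Locus],
    contig_evidence: Iterable[EvidenceRecord] = (),
    read_evidence: Iterable[EvidenceRecord] = (),
    config: SupportConfig | None = None,
) -> list[SupportResult]:
    """Score every locus; evidence is matched to loci by locus id.

    Evidence referencing an unknown locus id is skipped with a warning.
    The force-call bit is withheld from loci whose only discovery source
    is the force-calling technology.
    """
    config = config or SupportConfig()
    known = {l.id for l in loci}
    contigs: dict[str, list[EvidenceRecord]] = {}
    reads: dict[str, list[EvidenceRecord]] = {}
    for rec in contig_evidence:
        if rec.locus_id not in known:
            warnings.warn(f"contig evidence references unknown locus {rec.locus_id!r}; skipped")
            continue
        contigs.setdefault(rec.locus_id, []).append(rec)
    for rec in read_evidence:
        if rec.locus_id not in known:
            warnings.warn(f"read evidence references unknown locus {rec.locus_id!r}; skipped")
            continue
        reads.setdefault(rec.locus_id, []).append(rec)

    results = []
    for locus in loci:
        assembly = any(
            assess_consistency(
                locus, rec, config.size_tolerance, config.window, config.mis_min_overlap
            )
            for rec in contigs.get(locus.id, [])
        )
        multi = multi_source(locus)
        if locus.sources <= {config.force_call_source}:
            forced = False
        else:
            forced = force_call(
                locus,
                reads.get(locus.id, []),
                config.size_tolerance,
                config.window,
                config.mis_min_overlap,
            )
        results.append(
            SupportResult(
                locus_id=locus.id,
                assembly=assembly,
                multi_source=multi,
                force_called=forced,
                bitflag=compute_bitflag(assembly, multi, forced),
            )
        )
    return results


def apply_support(loci: Sequence[Locus], results: Sequence[SupportResult]) -> list[Locus]:
    """Return loci with bitflags filled in from their support results."""
    by_id = {r.locus_id: r for r in results}
    return [l.with_bitflag(by_id[l.id].bitflag if l.id in by_id else 0) for l in loci]


# ---------------------------------------------------------------------------
# Evidence TSV interchange: LOCUS_ID, KIND, OP, POS (1-based), LEN, SPANS(0/1),
# RECORD (groups events belonging to one contig/read; optional on read).

def read_evidence_tsv(path: str | Path) -> list[EvidenceRecord]:
    path = Path(path)
    groups: dict[tuple[str, str, str], dict] = {}
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file (missing header)")
        header = header_line.lstrip("#").strip().split("\t")
        for col in EVIDENCE_COLUMNS[:-1]:  # RECORD optional
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        idx = {c: header.index(c) for c in header}
        has_record = "RECORD" in idx
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            try:
                locus_id = f[idx["LOCUS_ID"]]
                kind = f[idx["KIND"]]
                rid = f[idx["RECORD"]] if has_record else f"row{lineno}"
                spans = f[idx["SPANS"]] == "1"
                key = (locus_id, kind, rid)
                grp = groups.setdefault(
                    key, {"spans": spans, "events": [], "order": len(groups)}
                )
                op = f[idx["OP"]]
                if op not in (".", ""):
                    grp["events"].append(
                        EvidenceEvent(
                            op=SVType(op),
                            position=int(f[idx["POS"]]) - 1,
                            length=int(f[idx["LEN"]]),
                        )
                    )
            except (ValueError, ConsensvError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    records = []
    for (locus_id, kind, rid), grp in sorted(groups.items(), key=lambda kv: kv[1]["order"]):
        records.append(
            EvidenceRecord(
                locus_id=locus_id,
                kind=kind,
                events=tuple(grp["events"]),
                spans_locus=grp["spans"],
                record_id=rid,
            )
        )
    return records


def write_evidence_tsv(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(EVIDENCE_COLUMNS) + "\n")
        for i, rec in enumerate(records):
            rid = rec.record_id or f"rec{i}"
            rows = rec.events or (None,)
            for ev in rows:
                fh.write(
                    "\t".join(
                        [
                            rec.locus_id,
                            rec.kind,
                            ev.op.value if ev else ".",
                            str(ev.position + 1) if ev else "0",
                            str(ev.length) if ev else "0",
                            "1" if rec.spans_locus else "0",
                            rid,
                        ]
                    )
                    + "\n"
                )


def evidence_from_alignments(
    path: str | Path,
    loci: Sequence[Locus],
    *,
    kind: str = "LONG_READ",
    min_event_len: int = 50,
    window: int = 2000,
) -> list[EvidenceRecord]:
    """Optional adapter: extract indel evidence from a SAM/BAM file.

    Walks each aligned read's CIGAR, records insertion/deletion operations
    of at least ``min_event_len`` bp, and attaches the read to every locus
    whose window it overlaps.  ``spans_locus`` is true when the alignment
    covers the full locus span.
    """
    import pysam

    by_chrom: dict[str, list[Locus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    records: list[EvidenceRecord] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        for aln in af:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            events = []
            ref_pos = aln.reference_start
            for op, length in aln.cigartuples:
                if op == 1 and length >= min_event_len:  # I
                    events.append(EvidenceEvent(SVType.INS, ref_pos, length))
                elif op == 2 and length >= min_event_len:  # D
                    events.append(EvidenceEvent(SVType.DEL, ref_pos, length))
                if op in (0, 2, 3, 7, 8):  # consumes reference
                    ref_pos += length
            aln_end = ref_pos
            for locus in by_chrom.get(aln.reference_name, []):
                if aln.reference_start <= locus.end + window and aln_end >= locus.start - window:
                    in_window = tuple(
                        ev
                        for ev in events
                        if locus.start - window <= ev.position <= locus.end + window
                    )
                    records.append(
                        EvidenceRecord(
                            locus_id=locus.id,
                            kind=kind,
                            events=in_window,
                            spans_locus=aln.reference_start <= locus.start
                            and aln_end >= locus.end,
                            record_id=aln.query_name or "",
                        )
                    )
    return records
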