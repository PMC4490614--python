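"""Canonical data model for consensus structural-variant merging.

Every caller-specific record is reduced to one of three canonical event
types before any merging happens:

* ``DEL`` — the sample is missing sequence that is present in the reference,
* ``INS`` — the sample carries extra sequence relative to the reference,
* ``MIS`` — the sample carries *different* sequence over a reference span
  (inversions and other copy-neutral rearrangements).

Calls additionally carry a *precision class* describing how literally their
coordinates can be trusted: split-read/assembly callers report exact
breakpoints, read-depth and array callers report approximate spans, and
genome-mapping platforms report only outer boundaries of the disturbed
region.  The precision class drives threshold and bandwidth selection during
clustering.

Internal coordinates are 0-based half-open throughout; on-disk interchange
formats keep their native conventions and the readers/writers in
:mod:`consensv.io` translate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping


class ConsensvError(Exception):
    """Base class for all package errors."""


class MalformedRecordError(ConsensvError):
    """An input record violates basic structural constraints (e.g. end < start)."""


class UnknownTypeError(ConsensvError):
    """A caller type label has no mapping to a canonical type."""


class ConfigError(ConsensvError):
    """A configuration value is contradictory or out of range."""


class SVType(str, Enum):
    DEL = "DEL"
    INS = "INS"
    MIS = "MIS"


class Precision(str, Enum):
    BREAKPOINT = "BREAKPOINT"
    APPROXIMATE = "APPROXIMATE"
    OUTER_BOUNDARY = "OUTER_BOUNDARY"


#: Lower rank = more precise; used for consensus-coordinate precedence.
PRECISION_RANK: dict[Precision, int] = {
    Precision.BREAKPOINT: 0,
    Precision.APPROXIMATE: 1,
    Precision.OUTER_BOUNDARY: 2,
}


class AnnotationKind(str, Enum):
    KNOWN_VARIANT = "KNOWN_VARIANT"
    GENE = "GENE"
    EXON = "EXON"
    GAP = "GAP"
    REPEAT = "REPEAT"


#: Default reduction of caller labels to the three canonical types.
#: Inversions are sequence mismatches; duplications and copy-number gains
#: are represented as insertions at the duplicated span because array and
#: read-depth data carry no placement information for the extra copy.
DEFAULT_TYPE_MAP: dict[str, SVType] = {
    "DEL": SVType.DEL,
    "DELETION": SVType.DEL,
    "LOSS": SVType.DEL,
    "INS": SVType.INS,
    "INSERTION": SVType.INS,
    "DUP": SVType.INS,
    "DUP:TANDEM": SVType.INS,
    "DUPLICATION": SVType.INS,
    "GAIN": SVType.INS,
    "MEI": SVType.INS,
    "INV": SVType.MIS,
    "INVERSION": SVType.MIS,
    "MIS": SVType.MIS,
    "MISMATCH": SVType.MIS,
}


@dataclass(frozen=True)
class SVCall:
    """One standardized structural-variant call.

    Coordinates are 0-based half-open on the reference.  For insertions the
    reference span may be empty (``end == start``); ``size`` then estimates
    the inserted-sequence length.  For deletions and mismatches ``size`` is
    the reference-span length unless the caller reported otherwise.
    """

    id: str
    caller: str
    source: str
    chrom: str
    start: int
    end: int
    svtype: SVType
    size: int
    precision: Precision = Precision.APPROXIMATE
    original_type: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise MalformedRecordError(
                f"call {self.id!r}: negative coordinate ({self.start}, {self.end})"
            )
        if self.end < self.start:
            raise MalformedRecordError(
                f"call {self.id!r}: end < start ({self.end} < {self.start})"
            )
        if self.size < 1:
            raise MalformedRecordError(f"call {self.id!r}: size must be >= 1")

    @property
    def span(self) -> int:
        """Reference-span length in bp (0 for breakpoint-only insertions)."""
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + self.span // 2


@dataclass(frozen=True)
class Annotation:
    """Overlap of a locus with a catalog entry or genomic feature."""

    kind: AnnotationKind
    label: str
    overlap_bp: int
    reciprocal_overlap: float

    def __post_init__(self) -> None:
        if self.overlap_bp < 0:
            raise MalformedRecordError("annotation overlap_bp must be >= 0")
        if not 0.0 <= self.reciprocal_overlap <= 1.0:
            raise MalformedRecordError("annotation reciprocal_overlap outside [0,1]")


@dataclass
class Locus:
    """A reference-inconsistent locus: a cluster of calls with consensus coordinates.

    ``bitflag`` encodes evidence support: +4 assembly, +2 multi-source,
    +1 long-read force call.  A locus is a supported SV iff ``bitflag > 0``.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: SVType
    size: int
    members: tuple[str, ...]
    sources: frozenset[str]
    callers: frozenset[str]
    bitflag: int = 0
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise MalformedRecordError(f"locus {self.id!r}: members must be non-empty")
        if not 0 <= self.bitflag <= 7:
            raise MalformedRecordError(f"locus {self.id!r}: bitflag outside 0-7")
        if self.end < self.start:
            raise MalformedRecordError(f"locus {self.id!r}: end < start")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + self.span // 2

    @property
    def supported(self) -> bool:
        return self.bitflag > 0

    def with_bitflag(self, bitflag: int) -> "Locus":
        out = replace(self)
        out.bitflag = bitflag
        return out


def standardize_call(
    raw: Mapping[str, object],
    type_map: Mapping[str, SVType] | None = None,
    *,
    caller: str,
    source: str,
    precision: Precision = Precision.APPROXIMATE,
    id: str | None = None,
) -> SVCall:
    """Reduce a caller-specific record to a canonical :class:`SVCall`.

    ``raw`` must provide ``chrom``, ``start``, ``end`` (0-based half-open)
    and ``type`` (the caller's label).  ``size`` is optional; when absent it
    defaults to the reference span (and must then be positive).

    Raises :class:`UnknownTypeError` for labels absent from ``type_map`` and
    :class:`MalformedRecordError` for structurally invalid coordinates.
    """
    tmap = DEFAULT_TYPE_MAP if type_map is None else type_map
    label = str(raw["type"]).strip()
    try:
        svtype = tmap[label.upper()] if isinstance(tmap, dict) else tmap[label]
    except KeyError:
        raise UnknownTypeError(
            f"unrecognized SV type label {label!r} (no entry in type map)"
        ) from None
    svtype = SVType(svtype)
    start = int(raw["start"])  # type: ignore[arg-type]
    end = int(raw["end"])  # type: ignore[arg-type]
    if end < start:
        raise MalformedRecordError(f"record {raw!r}: end < start")
    size = raw.get("size")
    if size is None:
        size = end - start
    size = int(size)  # type: ignore[arg-type]
    return SVCall(
        id=id if id is not None else str(raw.get("id", f"{caller}:{raw['chrom']}:{start}")),
        caller=caller,
        source=source,
        chrom=str(raw["chrom"]),
        start=start,
        end=end,
        svtype=svtype,
        size=size,
        precision=Precision(precision),
        original_type=label,
    )


def locus_from_call(call: SVCall, locus_id: str | None = None) -> Locus:
    """Promote a single call to a singleton locus (identity consensus)."""
    return Locus(
        id=locus_id if locus_id is not None else call.id,
        chrom=call.chrom,
        start=call.start,
        end=call.end,
        svtype=call.svtype,
        size=call.size,
        members=(call.id,),
        sources=frozenset({call.source}),
        callers=frozenset({call.caller}),
    )


def sort_key(item: SVCall | Locus) -> tuple:
    """Deterministic genomic sort order: (chrom, start, end, id)."""
    return (item.chrom, item.start, item.end, item.id)


def validate_locus_invariants(locus: Locus, calls_by_id: Mapping[str, SVCall]) -> None:
    """Check that a locus's source set equals the union of its members' sources."""
    expected = frozenset(calls_by_id[m].source for m in locus.members if m in calls_by_id)
    if expected and expected != locus.sources:
        raise MalformedRecordError(
            f"locus {locus.id!r}: sources {set(locus.sources)} != member union {set(expected)}"
        )


def unique_ids(items: Iterable[SVCall | Locus]) -> None:
    seen: set[str] = set()
    for it in items:
        if it.id in seen:
            raise MalformedRecordError(f"duplicate id {it.id!r}")
        seen.add(it.id)
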