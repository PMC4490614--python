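"""Readers and writers for the interchange formats.

Formats handled here:

* the tab-separated call/locus interchange dialect (1-based inclusive
  coordinates on disk, ``#``-prefixed header),
* VCF 4.2 via pysam (``SVTYPE``/``END``/``SVLEN`` INFO keys and the
  symbolic ALTs ``<DEL>``, ``<INS>``, ``<INV>``, ``<DUP>``),
* BED (0-based half-open) for known-variant catalogs and feature tracks,
* the evidence TSV consumed by the support stage,
* SNV VCFs with genotypes, and a per-locus coverage TSV.

On-disk coordinate conventions are translated at the boundary: internally
everything is 0-based half-open, so a VCF/TSV record with POS=101, END=200
(1-based inclusive) becomes the internal span ``[100, 200)``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .model import (
    Annotation,
    AnnotationKind,
    ConsensvError,
    Locus,
    MalformedRecordError,
    Precision,
    SVCall,
    SVType,
    standardize_call,
)

CALLSET_COLUMNS = [
    "CHROM", "START", "END", "TYPE", "SIZE", "CALLER", "SOURCE", "PRECISION", "ID",
]

LOCUS_COLUMNS = [
    "CHROM", "START", "END", "TYPE", "SIZE", "ID",
    "MEMBERS", "SOURCES", "CALLERS", "BITFLAG", "ANNOTATIONS",
]

EVIDENCE_COLUMNS = ["LOCUS_ID", "KIND", "OP", "POS", "LEN", "SPANS", "RECORD"]


class FormatError(ConsensvError):
    """Raised on parse failures; names the offending file, line or column."""


def _parse_header(line: str, path: str) -> list[str]:
    if not line.startswith("#"):
        raise FormatError(f"{path}: line 1: expected '#'-prefixed header")
    return line.lstrip("#").strip().split("\t")


def read_callset_tsv(path: str | Path) -> list[SVCall]:
    """Read standardized calls from the tab-separated dialect.

    Coordinates on disk are 1-based inclusive; they are converted to the
    internal 0-based half-open convention (START-1, END).
    """
    path = Path(path)
    calls: list[SVCall] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file (missing header)")
        header = _parse_header(header_line, str(path))
        for col in CALLSET_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            try:
                calls.append(
                    SVCall(
                        id=fields[idx["ID"]],
                        caller=fields[idx["CALLER"]],
                        source=fields[idx["SOURCE"]],
                        chrom=fields[idx["CHROM"]],
                        start=int(fields[idx["START"]]) - 1,
                        end=int(fields[idx["END"]]),
                        svtype=SVType(fields[idx["TYPE"]]),
                        size=int(fields[idx["SIZE"]]),
                        precision=Precision(fields[idx["PRECISION"]]),
                    )
                )
            except (ValueError, MalformedRecordError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return calls


def write_callset_tsv(calls: Iterable[SVCall], path: str | Path) -> None:
    """Write calls sorted by (chrom, start); inverse of :func:`read_callset_tsv`."""
    rows = sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.id))
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CALLSET_COLUMNS) + "\n")
        for c in rows:
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.start + 1),
                        str(c.end),
                        c.svtype.value,
                        str(c.size),
                        c.caller,
                        c.source,
                        c.precision.value,
                        c.id,
                    ]
                )
                + "\n"
            )


_SYMBOLIC_ALTS = {"<DEL>": "DEL", "<INS>": "INS", "<INV>": "INV", "<DUP>": "DUP"}


def read_callset_vcf(
    path: str | Path,
    *,
    caller: str,
    source: str,
    precision: Precision = Precision.APPROXIMATE,
    type_map=None,
) -> list[SVCall]:
    """Read SV calls from a VCF, honoring SVTYPE/END/SVLEN and symbolic ALTs."""
    calls: list[SVCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            label = rec.info.get("SVTYPE")
            if label is None and rec.alts:
                label = _SYMBOLIC_ALTS.get(rec.alts[0])
            if label is None:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos}: no SVTYPE or symbolic ALT"
                )
            start = rec.start  # pysam: 0-based
            end = rec.stop  # honors INFO/END
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            size = abs(int(svlen)) if svlen is not None else None
            # htslib computes stop = start + |SVLEN| + 1 when it falls back on
            # SVLEN; the END convention (1-based inclusive) gives start + |SVLEN|
            if size and end == start + size + 1:
                end = start + size
            if str(label).upper() in ("INS", "DUP", "GAIN", "MEI") and end <= start + 1:
                end = start  # breakpoint-only insertion: empty reference span
            calls.append(
                standardize_call(
                    {
                        "chrom": rec.chrom,
                        "start": start,
                        "end": end,
                        "type": str(label),
                        "size": size if size else max(end - start, 1),
                        "id": rec.id or f"{caller}:{rec.chrom}:{rec.pos}:{i}",
                    },
                    type_map,
                    caller=caller,
                    source=source,
                    precision=precision,
                )
            )
    return calls


def read_callset(
    path: str | Path,
    format: str = "TSV",
    *,
    caller: str | None = None,
    source: str | None = None,
    precision: Precision = Precision.APPROXIMATE,
) -> list[SVCall]:
    """Dispatch on format name: ``TSV`` (the native dialect) or ``VCF``."""
    fmt = format.upper()
    if fmt in ("TSV", "SV_TSV"):
        return read_callset_tsv(path)
    if fmt == "VCF":
        if caller is None or source is None:
            raise ConsensvError("VCF callsets require caller= and source=")
        return read_callset_vcf(path, caller=caller, source=source, precision=precision)
    raise ConsensvError(f"unknown callset format {format!r}")


def _format_annotations(annotations: Sequence[Annotation]) -> str:
    if not annotations:
        return "."
    return ";".join(
        f"{a.kind.value}:{a.label}:{a.overlap_bp}:{a.reciprocal_overlap:.4f}"
        for a in annotations
    )


def _parse_annotations(text: str) -> list[Annotation]:
    if text in (".", ""):
        return []
    out = []
    for part in text.split(";"):
        if part.count(":") < 3:
            raise FormatError(f"malformed annotation field {part!r}")
        kind, rest = part.split(":", 1)
        label, bp, ro = rest.rsplit(":", 2)
        out.append(Annotation(AnnotationKind(kind), label, int(bp), float(ro)))
    return out


def write_loci(loci: Iterable[Locus], path: str | Path) -> None:
    """Write loci deterministically, sorted by (chrom, start)."""
    rows = sorted(loci, key=lambda l: (l.chrom, l.start, l.end, l.id))
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(LOCUS_COLUMNS) + "\n")
        for l in rows:
            fh.write(
                "\t".join(
                    [
                        l.chrom,
                        str(l.start + 1),
                        str(l.end),
                        l.svtype.value,
                        str(l.size),
                        l.id,
                        ",".join(l.members),
                        ",".join(sorted(l.sources)),
                        ",".join(sorted(l.callers)),
                        str(l.bitflag),
                        _format_annotations(l.annotations),
                    ]
                )
                + "\n"
            )


def read_loci(path: str | Path) -> list[Locus]:
    path = Path(path)
    loci: list[Locus] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file (missing header)")
        header = _parse_header(header_line, str(path))
        for col in LOCUS_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            try:
                loci.append(
                    Locus(
                        id=f[idx["ID"]],
                        chrom=f[idx["CHROM"]],
                        start=int(f[idx["START"]]) - 1,
                        end=int(f[idx["END"]]),
                        svtype=SVType(f[idx["TYPE"]]),
                        size=int(f[idx["SIZE"]]),
                        members=tuple(f[idx["MEMBERS"]].split(",")),
                        sources=frozenset(f[idx["SOURCES"]].split(",")),
                        callers=frozenset(f[idx["CALLERS"]].split(",")),
                        bitflag=int(f[idx["BITFLAG"]]),
                        annotations=_parse_annotations(f[idx["ANNOTATIONS"]]),
                    )
                )
            except (ValueError, MalformedRecordError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return loci


def read_bed(path: str | Path, *, min_fields: int = 3) -> list[tuple]:
    """Read a BED-like file (0-based half-open) into (chrom, start, end, *rest) tuples."""
    path = Path(path)
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < min_fields:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= {min_fields} columns"
                )
            try:
                rows.append((f[0], int(f[1]), int(f[2]), *f[3:]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return rows


def write_bed(rows: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_coverage_tsv(path: str | Path) -> dict[str, float]:
    """Per-locus mean coverage: columns LOCUS_ID, MEAN_COV."""
    cov: dict[str, float] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: line {lineno}: expected LOCUS_ID, MEAN_COV")
            cov[row[0]] = float(row[1])
    return cov


def write_coverage_tsv(cov: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#LOCUS_ID\tMEAN_COV\n")
        for lid in sorted(cov):
            fh.write(f"{lid}\t{cov[lid]:.2f}\n")
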