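"""Grouping standardized calls into reference-inconsistent loci.

Two clustering regimes, matching the geometry of the events:

* **Reference-spanning events** (deletions and mismatches) are linked when
  their reciprocal overlap strictly exceeds a per-pair threshold, and
  clusters are the connected components of the resulting link graph.  The
  threshold depends on the precision of the two calls: exact-breakpoint
  callers agree tightly (default 50%), while outer-boundary sources such as
  genome maps only bracket the event, so any pair involving one is held to
  a looser 20% default.
* **Insertions** have (near-)zero reference span, and repeat context or
  microhomology can shift the reported breakpoint without the calls
  overlapping at all.  Each insertion is reduced to a representative
  breakpoint (the midpoint of its reference span) and clustered by 1-D
  mean shift with a flat kernel, with the kernel bandwidth set per
  precision class so that precise callers cluster at smaller scales.

Clustering is stratified by chromosome and canonical type; a deletion
never merges with an insertion or mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

import numpy as np

from .model import (
    ConfigError,
    ConsensvError,
    Locus,
    PRECISION_RANK,
    Precision,
    SVCall,
    SVType,
)


def reciprocal_overlap(a, b) -> float:
    """min(overlap/len(a), overlap/len(b)) for two reference intervals.

    Returns 0.0 for different chromosomes, disjoint intervals, or when
    either interval has zero length.  Symmetric by construction.
    """
    if a.chrom != b.chrom:
        return 0.0
    la = a.end - a.start
    lb = b.end - b.start
    if la <= 0 or lb <= 0:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / la, ov / lb)


@dataclass
class ThresholdMatrix:
    """Per-pair minimum reciprocal-overlap thresholds.

    Lookup precedence for a pair of calls: explicit source-pair override,
    then explicit precision-class-pair override, then the outer-boundary
    default when either call is an outer-boundary source, then the global
    default.  All thresholds must lie in (0, 1]; the comparison against
    them is strict (calls are linked iff RO > threshold).
    """

    default_ro: float = 0.5
    outer_boundary_ro: float = 0.2
    pair_ro: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in [("default", self.default_ro), ("outer_boundary", self.outer_boundary_ro)]:
            if not 0.0 < value <= 1.0:
                raise ConfigError(f"threshold {name}={value} outside (0, 1]")
        for key, value in self.pair_ro.items():
            if not 0.0 < value <= 1.0:
                raise ConfigError(f"pair threshold {set(key)}={value} outside (0, 1]")

    def threshold(self, a: SVCall, b: SVCall) -> float:
        source_key = frozenset({a.source, b.source})
        if source_key in self.pair_ro:
            return self.pair_ro[source_key]
        class_key = frozenset({a.precision.value, b.precision.value})
        if class_key in self.pair_ro:
            return self.pair_ro[class_key]
        if Precision.OUTER_BOUNDARY in (a.precision, b.precision):
            return self.outer_boundary_ro
        return self.default_ro


@dataclass
class BandwidthConfig:
    """Per-precision-class flat-kernel bandwidths (bp) for insertion clustering."""

    bandwidths: dict[Precision, int] = field(
        default_factory=lambda: {
            Precision.BREAKPOINT: 20,
            Precision.APPROXIMATE: 300,
            Precision.OUTER_BOUNDARY: 5000,
        }
    )

    def __post_init__(self) -> None:
        for cls, bw in self.bandwidths.items():
            if bw <= 0:
                raise ConfigError(f"bandwidth for {cls} must be positive, got {bw}")

    def bandwidth(self, call: SVCall) -> int:
        return self.bandwidths[call.precision]


class _UnionFind:
    """Path-compressed union-find over 0..n-1."""

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)

    def components(self) -> list[list[int]]:
        groups: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            groups.setdefault(self.find(i), []).append(i)
        return [groups[r] for r in sorted(groups)]


def size_filter(
    calls: Iterable[SVCall], size_min: int = 100, size_max: int = 1_000_000
) -> list[SVCall]:
    """Retain calls within the configured size range (inclusive)."""
    return [c for c in calls if size_min <= c.size <= size_max]


def cluster_spanning(
    calls: Sequence[SVCall], thresholds: ThresholdMatrix | None = None
) -> list[list[SVCall]]:
    """Cluster reference-spanning calls (DEL, MIS) by reciprocal overlap.

    Two calls are linked iff RO > threshold for their source/precision
    pair; clusters are connected components of the link graph (so
    membership is transitive even when a pair of members does not itself
    exceed the threshold).  Every call lands in exactly one cluster.
    """
    thresholds = thresholds or ThresholdMatrix()
    for c in calls:
        if c.svtype == SVType.INS:
            raise ConsensvError(
                f"call {c.id!r} is INS; insertions are clustered by mean shift"
            )
    strata: dict[tuple[str, SVType], list[SVCall]] = {}
    for c in calls:
        strata.setdefault((c.chrom, c.svtype), []).append(c)

    clusters: list[list[SVCall]] = []
    for key in sorted(strata, key=lambda k: (k[0], k[1].value)):
        group = sorted(strata[key], key=lambda c: (c.start, c.end, c.id))
        uf = _UnionFind(len(group))
        # sorted by start: any overlapping pair (i earlier) satisfies start_j < end_i
        for i, a in enumerate(group):
            for j in range(i + 1, len(group)):
                b = group[j]
                if b.start >= a.end:
                    break
                if reciprocal_overlap(a, b) > thresholds.threshold(a, b):
                    uf.union(i, j)
        for comp in uf.components():
            clusters.append([group[i] for i in comp])
    return clusters


def _mean_shift_modes(
    positions: np.ndarray, bandwidths: np.ndarray, max_iter: int = 100, tol: float = 1.0
) -> np.ndarray:
    """Flat-kernel 1-D mean shift; each point seeks the mean of the points
    within its own bandwidth until movement < tol bp or max_iter."""
    order = np.argsort(positions, kind="stable")
    sorted_pos = positions[order].astype(float)
    modes = positions.astype(float).copy()
    for i in range(len(positions)):
        x = modes[i]
        bw = bandwidths[i]
        for _ in range(max_iter):
            lo = np.searchsorted(sorted_pos, x - bw, side="left")
            hi = np.searchsorted(sorted_pos, x + bw, side="right")
            new_x = sorted_pos[lo:hi].mean() if hi > lo else x
            if abs(new_x - x) < tol:
                x = new_x
                break
            x = new_x
        modes[i] = x
    return modes


def cluster_insertions(
    calls: Sequence[SVCall], bandwidths: BandwidthConfig | None = None
) -> list[list[SVCall]]:
    """Cluster insertion calls by multi-scale 1-D mean shift on breakpoints.

    Each call's representative breakpoint is the midpoint of its reference
    span; the flat-kernel bandwidth is taken from the call's precision
    class.  After convergence, two calls are co-clustered (transitively)
    when their modes lie within the larger of their two bandwidths.
    """
    bandwidths = bandwidths or BandwidthConfig()
    for c in calls:
        if c.svtype != SVType.INS:
            raise ConsensvError(f"call {c.id!r} is not INS")
    strata: dict[str, list[SVCall]] = {}
    for c in calls:
        strata.setdefault(c.chrom, []).append(c)

    clusters: list[list[SVCall]] = []
    for chrom in sorted(strata):
        group = sorted(strata[chrom], key=lambda c: (c.midpoint, c.start, c.id))
        pos = np.array([c.midpoint for c in group], dtype=float)
        bws = np.array([bandwidths.bandwidth(c) for c in group], dtype=float)
        modes = _mean_shift_modes(pos, bws)
        uf = _UnionFind(len(group))
        order = np.argsort(modes, kind="stable")
        max_bw = float(bws.max()) if len(bws) else 0.0
        for a_idx in range(len(group)):
            i = int(order[a_idx])
            for b_idx in range(a_idx + 1, len(group)):
                j = int(order[b_idx])
                gap = modes[j] - modes[i]
                if gap > max_bw:
                    break  # modes sorted: no later pair with i can qualify
                if gap <= max(bws[i], bws[j]):
                    uf.union(i, j)
        for comp in uf.components():
            clusters.append([group[i] for i in comp])
    return clusters


def merge_cluster(cluster: Sequence[SVCall], locus_id: str | None = None) -> Locus:
    """Merge one cluster into a locus with consensus coordinates.

    The consensus span is taken from the most precise members (breakpoint
    callers outrank approximate callers, which outrank outer-boundary
    sources); ties among equally precise members are broken by the median
    of their starts/ends.  Sources and callers are unions over all members.
    """
    if not cluster:
        raise ConsensvError("cannot merge an empty cluster")
    types = {c.svtype for c in cluster}
    if len(types) > 1:
        raise ConsensvError(
            f"mixed svtypes in one cluster: {sorted(t.value for t in types)}"
        )
    chroms = {c.chrom for c in cluster}
    if len(chroms) > 1:
        raise ConsensvError(f"mixed chromosomes in one cluster: {sorted(chroms)}")
    best_rank = min(PRECISION_RANK[c.precision] for c in cluster)
    best = [c for c in cluster if PRECISION_RANK[c.precision] == best_rank]
    start = int(round(median(c.start for c in best)))
    end = int(round(median(c.end for c in best)))
    if end < start:
        start, end = end, start
    size = int(round(median(c.size for c in best)))
    members = tuple(c.id for c in sorted(cluster, key=lambda c: (c.start, c.end, c.id)))
    return Locus(
        id=locus_id if locus_id is not None else members[0],
        chrom=next(iter(chroms)),
        start=start,
        end=end,
        svtype=next(iter(types)),
        size=max(size, 1),
        members=members,
        sources=frozenset(c.source for c in cluster),
        callers=frozenset(c.caller for c in cluster),
    )


def cluster_and_merge(
    calls: Sequence[SVCall],
    thresholds: ThresholdMatrix | None = None,
    bandwidths: BandwidthConfig | None = None,
    size_min: int = 100,
    size_max: int = 1_000_000,
) -> list[Locus]:
    """Full merge step: size gate, cluster spanning + insertions, merge,
    sort by (chrom, start) and assign deterministic locus ids.

    Merging iterates to a fixed point: after consensus coordinates are
    taken, two clusters' spans can drift closer than any of their member
    pairs were (the median pulls a chained cluster toward its middle), so
    the consensus loci are re-clustered — represented by pseudo-calls
    carrying their most precise member's class — until no further merge
    occurs.  The emitted loci therefore re-cluster to singletons under the
    same thresholds.
    """
    kept = size_filter(calls, size_min, size_max)
    spanning = [c for c in kept if c.svtype in (SVType.DEL, SVType.MIS)]
    insertions = [c for c in kept if c.svtype == SVType.INS]
    groups: list[list[SVCall]] = cluster_spanning(spanning, thresholds)
    groups += cluster_insertions(insertions, bandwidths)

    for _ in range(20):  # converges: group count strictly decreases
        loci = [merge_cluster(g) for g in groups]
        pseudo = []
        for i, (locus, group) in enumerate(zip(loci, groups)):
            best = min(PRECISION_RANK[c.precision] for c in group)
            sources = {c.source for c in group}
            pseudo.append(
                SVCall(
                    id=str(i),
                    caller="",
                    source=next(iter(sources)) if len(sources) == 1 else "|".join(sorted(sources)),
                    chrom=locus.chrom,
                    start=locus.start,
                    end=locus.end,
                    svtype=locus.svtype,
                    size=locus.size,
                    precision=[p for p, r in PRECISION_RANK.items() if r == best][0],
                )
            )
        spanning_pseudo = [p for p in pseudo if p.svtype in (SVType.DEL, SVType.MIS)]
        ins_pseudo = [p for p in pseudo if p.svtype == SVType.INS]
        meta = cluster_spanning(spanning_pseudo, thresholds) + cluster_insertions(
            ins_pseudo, bandwidths
        )
        if all(len(m) == 1 for m in meta):
            break
        groups = [
            [c for p in m for c in groups[int(p.id)]] for m in meta
        ]
    loci = [merge_cluster(g) for g in groups]
    loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.svtype.value, l.id))
    width = max(5, len(str(len(loci))))
    out = []
    for i, l in enumerate(loci, start=1):
        l.id = f"locus_{i:0{width}d}"
        out.append(l)
    return out
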