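"""Reciprocal-overlap clustering, mean-shift insertion clustering, consensus merge."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from consensv import (
    BandwidthConfig,
    ConsensvError,
    Precision,
    SVType,
    ThresholdMatrix,
    cluster_insertions,
    cluster_spanning,
    merge_cluster,
    reciprocal_overlap,
)
from consensv.clustering import cluster_and_merge, size_filter
from consensv.model import ConfigError
from tests.conftest import make_call


class Interval:
    def __init__(self, chrom, start, end):
        self.chrom, self.start, self.end = chrom, start, end


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((100, 200), (100, 200), 1.0),
        ((100, 200), (150, 250), 0.5),
        ((0, 1000), (0, 100), 0.1),  # min(100/1000, 100/100)
        ((0, 100), (200, 300), 0.0),
        ((0, 100), (100, 200), 0.0),  # touching, half-open: no overlap
        ((100, 100), (50, 150), 0.0),  # zero-length interval
    ],
)
def test_reciprocal_overlap_values(a, b, expected):
    ia, ib = Interval("chr1", *a), Interval("chr1", *b)
    assert reciprocal_overlap(ia, ib) == pytest.approx(expected)
    assert reciprocal_overlap(ib, ia) == pytest.approx(expected)  # symmetric


def test_reciprocal_overlap_across_chromosomes_is_zero():
    assert reciprocal_overlap(Interval("chr1", 0, 100), Interval("chr2", 0, 100)) == 0.0


def brute_force_components(calls, thresholds):
    """Independent oracle: all-pairs link graph + networkx connected components."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(c.id for c in calls)
    for i, a in enumerate(calls):
        for b in calls[i + 1 :]:
            if a.svtype != b.svtype or a.chrom != b.chrom:
                continue
            if reciprocal_overlap(a, b) > thresholds.threshold(a, b):
                g.add_edge(a.id, b.id)
    return {frozenset(comp) for comp in nx.connected_components(g)}


def as_id_sets(clusters):
    return {frozenset(c.id for c in cl) for cl in clusters}


class TestClusterSpanning:
    def test_pair_above_threshold_groups(self):
        a = make_call(id="a", start=100, end=600)
        b = make_call(id="b", caller="BreakDancer", start=150, end=650)
        # RO = 450/500 = 0.9 > 0.5
        clusters = cluster_spanning([a, b])
        assert as_id_sets(clusters) == {frozenset({"a", "b"})}

    def test_pair_at_exactly_threshold_does_not_group(self):
        # RO exactly 0.5; comparison is strict (>)
        a = make_call(id="a", start=0, end=100)
        b = make_call(id="b", start=50, end=150)
        assert len(cluster_spanning([a, b])) == 2

    def test_type_strata_never_merge(self):
        a = make_call(id="a", svtype=SVType.DEL)
        b = make_call(id="b", svtype=SVType.MIS)
        assert len(cluster_spanning([a, b])) == 2

    def test_transitive_chain_forms_single_cluster(self):
        # A-B and B-C linked at RO 0.6; A-C only ~0.3: transitive closure
        a = make_call(id="a", start=0, end=1000)
        b = make_call(id="b", start=400, end=1400)
        c = make_call(id="c", start=800, end=1800)
        thresholds = ThresholdMatrix()
        assert reciprocal_overlap(a, b) == pytest.approx(0.6)
        assert reciprocal_overlap(b, c) == pytest.approx(0.6)
        assert reciprocal_overlap(a, c) == pytest.approx(0.2)
        clusters = cluster_spanning([a, b, c], thresholds)
        assert as_id_sets(clusters) == brute_force_components([a, b, c], thresholds)
        assert as_id_sets(clusters) == {frozenset({"a", "b", "c"})}

    def test_outer_boundary_pair_uses_looser_threshold(self):
        # RO ~0.27: below the 0.5 default but above the 0.2 outer-boundary default
        a = make_call(id="a", start=0, end=1000, precision=Precision.BREAKPOINT)
        b = make_call(
            id="b", source="BioNano Irys", start=200, end=3200,
            precision=Precision.OUTER_BOUNDARY,
        )
        assert reciprocal_overlap(a, b) == pytest.approx(800 / 3000)
        assert len(cluster_spanning([a, b])) == 1
        tight = ThresholdMatrix(outer_boundary_ro=0.3)
        assert len(cluster_spanning([a, b], tight)) == 2

    def test_source_pair_override_takes_precedence(self):
        a = make_call(id="a", source="S1", start=0, end=1000)
        b = make_call(id="b", source="S2", start=300, end=1300)  # RO 0.7
        loose = ThresholdMatrix(pair_ro={frozenset({"S1", "S2"}): 0.9})
        assert len(cluster_spanning([a, b], loose)) == 2

    def test_insertions_are_rejected(self):
        with pytest.raises(ConsensvError):
            cluster_spanning([make_call(id="a", svtype=SVType.INS, end=1000, size=300)])

    def test_empty_input(self):
        assert cluster_spanning([]) == []

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle_on_random_instances(self, data):
        n = data.draw(st.integers(0, 50))
        calls = []
        for i in range(n):
            start = data.draw(st.integers(0, 5000))
            length = data.draw(st.integers(1, 3000))
            calls.append(
                make_call(
                    id=f"c{i}",
                    chrom=data.draw(st.sampled_from(["chr1", "chr2"])),
                    start=start,
                    end=start + length,
                    svtype=data.draw(st.sampled_from([SVType.DEL, SVType.MIS])),
                    precision=data.draw(st.sampled_from(list(Precision))),
                )
            )
        thresholds = ThresholdMatrix()
        clusters = cluster_spanning(calls, thresholds)
        # partition property: every call in exactly one cluster
        ids = sorted(c.id for cl in clusters for c in cl)
        assert ids == sorted(c.id for c in calls)
        assert as_id_sets(clusters) == brute_force_components(calls, thresholds)

    def test_monotonicity_lowering_thresholds_never_splits(self):
        rng = np.random.default_rng(7)
        calls = []
        for i in range(80):
            start = int(rng.integers(0, 20_000))
            calls.append(
                make_call(id=f"c{i}", start=start, end=start + int(rng.integers(100, 5000)))
            )
        n_tight = len(cluster_spanning(calls, ThresholdMatrix(default_ro=0.7, outer_boundary_ro=0.7)))
        n_loose = len(cluster_spanning(calls, ThresholdMatrix(default_ro=0.3, outer_boundary_ro=0.3)))
        assert n_loose <= n_tight


class TestClusterInsertions:
    def ins(self, id, pos, size=300, precision=Precision.BREAKPOINT, chrom="chr1"):
        return make_call(
            id=id, chrom=chrom, start=pos, end=pos, svtype=SVType.INS,
            size=size, precision=precision,
        )

    def test_nearby_breakpoints_form_one_cluster_at_their_mean(self):
        calls = [self.ins("a", 1000), self.ins("b", 1005), self.ins("c", 998)]
        bw = BandwidthConfig(bandwidths={p: 50 for p in Precision})
        clusters = cluster_insertions(calls, bw)
        assert as_id_sets(clusters) == {frozenset({"a", "b", "c"})}
        # flat-kernel fixed point is the mean of all three points
        from consensv.clustering import _mean_shift_modes

        modes = _mean_shift_modes(np.array([1000.0, 1005.0, 998.0]), np.array([50.0] * 3))
        assert np.allclose(modes, 1001.0)

    def test_distant_breakpoints_stay_separate(self):
        bw = BandwidthConfig(bandwidths={p: 50 for p in Precision})
        clusters = cluster_insertions([self.ins("a", 1000), self.ins("b", 90_000)], bw)
        assert len(clusters) == 2

    def test_empty_input(self):
        assert cluster_insertions([]) == []

    def test_per_class_bandwidths_allow_coarse_caller_to_join(self):
        # 150 bp apart: beyond the 20 bp breakpoint bandwidth but within the
        # 300 bp approximate bandwidth of the coarser caller
        a = self.ins("a", 1000, precision=Precision.BREAKPOINT)
        b = self.ins("b", 1150, precision=Precision.APPROXIMATE)
        assert as_id_sets(cluster_insertions([a, b])) == {frozenset({"a", "b"})}
        both_precise = [
            self.ins("a", 1000, precision=Precision.BREAKPOINT),
            self.ins("b", 1150, precision=Precision.BREAKPOINT),
        ]
        assert len(cluster_insertions(both_precise)) == 2

    def test_chromosome_stratification(self):
        clusters = cluster_insertions(
            [self.ins("a", 1000, chrom="chr1"), self.ins("b", 1000, chrom="chr2")]
        )
        assert len(clusters) == 2

    def test_agrees_with_sklearn_mean_shift_at_uniform_bandwidth(self):
        from sklearn.cluster import MeanShift

        rng = np.random.default_rng(11)
        centers = [5_000, 12_000, 40_000]
        positions = np.sort(
            np.concatenate([rng.normal(c, 30, 15) for c in centers]).round()
        ).astype(int)
        calls = [self.ins(f"c{i}", int(p)) for i, p in enumerate(positions)]
        bw = BandwidthConfig(bandwidths={p: 500 for p in Precision})
        ours = cluster_insertions(calls, bw)
        sk = MeanShift(bandwidth=500).fit(positions.reshape(-1, 1))
        sk_partition = {}
        for call, label in zip(calls, sk.labels_):
            sk_partition.setdefault(label, set()).add(call.id)
        assert as_id_sets(ours) == set(map(frozenset, sk_partition.values()))


class TestMergeCluster:
    def test_precision_precedence_picks_breakpoint_span(self):
        precise = make_call(id="a", start=100, end=600, precision=Precision.BREAKPOINT)
        coarse = make_call(
            id="b", caller="CNVnator", start=50, end=700, precision=Precision.APPROXIMATE
        )
        locus = merge_cluster([coarse, precise])
        assert (locus.start, locus.end) == (100, 600)
        assert locus.callers == frozenset({"Crest", "CNVnator"})

    def test_tied_precision_uses_median_coordinates(self):
        a = make_call(id="a", start=100, end=600)
        b = make_call(id="b", start=102, end=598)
        locus = merge_cluster([a, b])
        assert (locus.start, locus.end) == (101, 599)

    def test_singleton_cluster_is_identity(self):
        call = make_call(id="a", start=123, end=456)
        locus = merge_cluster([call])
        assert (locus.start, locus.end, locus.svtype, locus.size) == (123, 456, call.svtype, call.size)
        assert locus.members == ("a",)

    def test_sources_and_callers_are_unions(self):
        a = make_call(id="a", caller="Crest", source="Illumina HiSeq")
        b = make_call(id="b", caller="PBHoney", source="PacBio RS")
        locus = merge_cluster([a, b])
        assert locus.sources == frozenset({"Illumina HiSeq", "PacBio RS"})

    def test_mixed_svtype_is_an_error(self):
        with pytest.raises(ConsensvError, match="mixed"):
            merge_cluster([make_call(id="a"), make_call(id="b", svtype=SVType.MIS)])

    def test_empty_cluster_is_an_error(self):
        with pytest.raises(ConsensvError):
            merge_cluster([])


class TestClusterAndMerge:
    def test_size_gate_applied_before_clustering(self):
        small = make_call(id="s", start=0, end=50, size=50)
        ok = make_call(id="o", start=1000, end=1500)
        huge = make_call(id="h", start=10_000, end=2_010_000, size=2_000_000)
        loci = cluster_and_merge([small, ok, huge])
        assert [l.members for l in loci] == [("o",)]
        assert size_filter([small, ok, huge]) == [ok]
        assert size_filter([small], size_min=10) == [small]

    def test_idempotence_reclustering_loci_gives_singletons(self):
        rng = np.random.default_rng(3)
        calls = []
        for i in range(60):
            start = int(rng.integers(0, 50_000))
            calls.append(
                make_call(id=f"c{i}", start=start, end=start + int(rng.integers(100, 4000)))
            )
        loci = cluster_and_merge(calls)
        as_calls = [
            make_call(id=l.id, start=l.start, end=l.end, svtype=l.svtype, size=l.size)
            for l in loci
        ]
        re_loci = cluster_and_merge(as_calls)
        assert len(re_loci) == len(loci)
        assert all(len(l.members) == 1 for l in re_loci)

    def test_locus_ids_deterministic_and_sorted(self):
        calls = [
            make_call(id="b", chrom="chr2", start=100, end=600),
            make_call(id="a", chrom="chr1", start=100, end=600),
        ]
        loci = cluster_and_merge(calls)
        assert [l.chrom for l in loci] == ["chr1", "chr2"]
        assert loci[0].id == "locus_00001"


def test_threshold_matrix_validation():
    with pytest.raises(ConfigError):
        ThresholdMatrix(default_ro=1.5)
    with pytest.raises(ConfigError):
        ThresholdMatrix(pair_ro={frozenset({"a", "b"}): 0.0})
    with pytest.raises(ConfigError):
        BandwidthConfig(bandwidths={Precision.BREAKPOINT: 0})
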