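"""Evidence consistency assessment, force calling, and the support bitflag."""

import pytest
from hypothesis import given, strategies as st

from consensv import (
    ConsensvError,
    EvidenceEvent,
    EvidenceRecord,
    SupportConfig,
    SVType,
    assess_consistency,
    compute_bitflag,
    decompose_bitflag,
    force_call,
    multi_source,
    score_loci,
)
from consensv.support import (
    SupportResult,
    apply_support,
    read_evidence_tsv,
    write_evidence_tsv,
)
from tests.conftest import make_locus


def contig(locus_id="L1", events=(), spans=True):
    return EvidenceRecord(locus_id=locus_id, kind="CONTIG", events=tuple(events), spans_locus=spans)


def read(locus_id="L1", events=(), spans=True, rid="r"):
    return EvidenceRecord(
        locus_id=locus_id, kind="LONG_READ", events=tuple(events), spans_locus=spans, record_id=rid
    )


class TestBitflag:
    @pytest.mark.parametrize(
        "assembly,multi,forced,expected",
        [
            (True, True, False, 6),
            (False, False, False, 0),
            (True, True, True, 7),
            (True, False, False, 4),
            (False, True, False, 2),
            (False, False, True, 1),
            (True, False, True, 5),
            (False, True, True, 3),
        ],
    )
    def test_all_combinations(self, assembly, multi, forced, expected):
        assert compute_bitflag(assembly, multi, forced) == expected

    @given(st.booleans(), st.booleans(), st.booleans())
    def test_decomposition_is_a_bijection(self, a, m, f):
        flag = compute_bitflag(a, m, f)
        assert 0 <= flag <= 7
        assert decompose_bitflag(flag) == (a, m, f)
        assert compute_bitflag(*decompose_bitflag(flag)) == flag

    def test_supported_means_nonzero(self):
        assert compute_bitflag(False, False, False) == 0
        for flag in range(1, 8):
            assert compute_bitflag(*decompose_bitflag(flag)) > 0


class TestAssessConsistency:
    def test_matching_type_and_size_within_tolerance(self):
        locus = make_locus(start=10_000, end=10_500, svtype=SVType.DEL, size=500)
        ev = contig(events=[EvidenceEvent(SVType.DEL, 10_010, 480)])
        assert assess_consistency(locus, ev, size_tolerance=0.5) is True

    def test_size_outside_tolerance_fails(self):
        locus = make_locus(start=10_000, end=10_500, svtype=SVType.DEL, size=500)
        ev = contig(events=[EvidenceEvent(SVType.DEL, 10_010, 120)])
        assert assess_consistency(locus, ev, size_tolerance=0.5) is False
        # boundary: |250-500| = 250 = 0.5*500 is within (<=)
        ev2 = contig(events=[EvidenceEvent(SVType.DEL, 10_010, 250)])
        assert assess_consistency(locus, ev2, size_tolerance=0.5) is True

    def test_type_mismatch_fails(self):
        locus = make_locus(start=10_000, end=10_500, svtype=SVType.DEL, size=500)
        ev = contig(events=[EvidenceEvent(SVType.INS, 10_010, 300)])
        assert assess_consistency(locus, ev) is False

    def test_event_outside_window_fails(self):
        locus = make_locus(start=10_000, end=10_500, svtype=SVType.DEL, size=500)
        far = contig(events=[EvidenceEvent(SVType.DEL, 20_000, 500)])
        assert assess_consistency(locus, far, window=2000) is False
        near = contig(events=[EvidenceEvent(SVType.DEL, 8_200, 500)])
        assert assess_consistency(locus, near, window=2000) is True

    def test_absent_or_empty_evidence_is_false(self):
        locus = make_locus()
        assert assess_consistency(locus, None) is False
        assert assess_consistency(locus, contig(events=[])) is False

    def test_mismatch_locus_supported_by_spanning_discontinuity(self):
        locus = make_locus(start=5_000, end=6_000, svtype=SVType.MIS, size=1000)
        covering = contig(events=[EvidenceEvent(SVType.DEL, 5_100, 800)])  # 80% of span
        assert assess_consistency(locus, covering) is True
        marginal = contig(events=[EvidenceEvent(SVType.DEL, 5_800, 300)])  # 20%
        assert assess_consistency(locus, marginal) is False


class TestForceCall:
    def test_single_consistent_read_among_many_suffices(self):
        locus = make_locus(start=10_000, end=10_500, svtype=SVType.DEL, size=500)
        reads = [read(events=[], rid=f"r{i}") for i in range(9)]
        reads.append(read(events=[EvidenceEvent(SVType.DEL, 10_000, 510)], rid="hit"))
        assert force_call(locus, reads) is True

    def test_no_spanning_reads_is_false(self):
        locus = make_locus()
        assert force_call(locus, []) is False
        non_spanning = read(events=[EvidenceEvent(SVType.DEL, 1_000, 500)], spans=False)
        assert force_call(locus, [non_spanning]) is False

    def test_all_type_mismatched_reads_fail(self):
        locus = make_locus(start=1_000, end=1_500, svtype=SVType.DEL, size=500)
        reads = [
            read(events=[EvidenceEvent(SVType.INS, 1_100, 500)], rid=f"r{i}")
            for i in range(3)
        ]
        assert force_call(locus, reads) is False


class TestMultiSource:
    def test_two_programs_one_technology_count_once(self):
        locus = make_locus(
            callers=("BreakDancer", "Pindel"), sources=("Illumina HiSeq",),
            members=("a", "b"),
        )
        assert multi_source(locus) is False

    def test_two_technologies(self):
        locus = make_locus(
            sources=("Illumina HiSeq", "PacBio RS"), members=("a", "b")
        )
        assert multi_source(locus) is True

    def test_single_source(self):
        assert multi_source(make_locus()) is False


class TestScoreLoci:
    def test_aggregation_counts_supported_subset(self):
        loci = [make_locus(id=f"L{i}", start=i * 10_000, end=i * 10_000 + 500) for i in range(5)]
        contigs = [
            contig("L0", [EvidenceEvent(SVType.DEL, 500, 500)]),
            contig("L1", [EvidenceEvent(SVType.DEL, 10_500, 500)]),
        ]
        # L2 multi-source
        loci[2] = make_locus(
            id="L2", start=20_000, end=20_500,
            sources=("Illumina HiSeq", "PacBio RS"), members=("a", "b"),
        )
        results = score_loci(loci, contigs, [])
        assert [r.bitflag for r in results] == [4, 4, 2, 0, 0]
        assert sum(1 for r in results if r.bitflag > 0) == 3

    def test_force_call_excluded_for_force_source_only_loci(self):
        locus = make_locus(id="L1", sources=("PacBio RS",), svtype=SVType.DEL, size=500)
        hit = read("L1", [EvidenceEvent(SVType.DEL, 1_000, 500)])
        config = SupportConfig(force_call_source="PacBio RS")
        (result,) = score_loci([locus], [], [hit], config)
        assert result.force_called is False
        assert result.bitflag == 0
        # same locus discovered by another technology too: bit applies
        locus2 = make_locus(
            id="L1", sources=("PacBio RS", "Illumina HiSeq"), members=("a", "b"),
            svtype=SVType.DEL, size=500,
        )
        (result2,) = score_loci([locus2], [], [hit], config)
        assert result2.force_called is True
        assert result2.bitflag == 3  # multi + forced

    def test_unknown_locus_evidence_warned_and_skipped(self):
        with pytest.warns(UserWarning, match="unknown locus"):
            results = score_loci([make_locus(id="L1")], [contig("NOPE")], [])
        assert results[0].bitflag == 0

    def test_empty_locus_list(self):
        assert score_loci([], [], []) == []

    def test_monotonicity_adding_evidence_never_decreases_flag(self):
        locus = make_locus(id="L1", start=1_000, end=1_500, svtype=SVType.DEL, size=500)
        hit_contig = contig("L1", [EvidenceEvent(SVType.DEL, 1_000, 500)])
        hit_read = read("L1", [EvidenceEvent(SVType.DEL, 1_000, 500)])
        flags = [
            score_loci([locus], c, r)[0].bitflag
            for c, r in [([], []), ([hit_contig], []), ([hit_contig], [hit_read])]
        ]
        assert flags == sorted(flags)
        assert flags[0] <= flags[1] <= flags[2]

    def test_bitflag_consistency_enforced(self):
        with pytest.raises(ConsensvError):
            SupportResult("L1", assembly=True, multi_source=False, force_called=False, bitflag=2)

    def test_apply_support_writes_flags_onto_loci(self):
        loci = [make_locus(id="L1"), make_locus(id="L2", start=9_000, end=9_500)]
        results = [
            SupportResult("L1", True, True, False, 6),
            SupportResult("L2", False, False, False, 0),
        ]
        flagged = apply_support(loci, results)
        assert [l.bitflag for l in flagged] == [6, 0]


class TestEvidenceTsv:
    def test_round_trip_groups_events_by_record(self, tmp_path):
        records = [
            contig("L1", [EvidenceEvent(SVType.DEL, 100, 500), EvidenceEvent(SVType.INS, 900, 60)]),
            read("L1", [], rid="empty_read"),
            read("L2", [EvidenceEvent(SVType.DEL, 5_000, 300)], rid="r2"),
        ]
        path = tmp_path / "evidence.tsv"
        write_evidence_tsv(records, path)
        back = read_evidence_tsv(path)
        assert len(back) == 3
        by_kind = {(r.locus_id, r.kind, len(r.events)) for r in back}
        assert by_kind == {("L1", "CONTIG", 2), ("L1", "LONG_READ", 0), ("L2", "LONG_READ", 1)}
        (two_events,) = [r for r in back if len(r.events) == 2]
        assert two_events.events[0] == EvidenceEvent(SVType.DEL, 100, 500)

    def test_positions_one_based_on_disk(self, tmp_path):
        path = tmp_path / "evidence.tsv"
        write_evidence_tsv([contig("L1", [EvidenceEvent(SVType.DEL, 99, 10)])], path)
        row = path.read_text().splitlines()[1].split("\t")
        assert row[3] == "100"
        assert read_evidence_tsv(path)[0].events[0].position == 99


def test_sam_adapter_extracts_large_indels(tmp_path):
    sam = tmp_path / "reads.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr1\tLN:100000\n"
        # 500 bp deletion at ref 10100 (0-based), spans locus
        "readA\t0\tchr1\t10001\t60\t100M500D100M\t*\t0\t0\t"
        + "A" * 200 + "\t*\n"
        # only a small 10 bp deletion: below the 50 bp floor
        "readB\t0\tchr1\t10001\t60\t100M10D100M\t*\t0\t0\t"
        + "A" * 200 + "\t*\n"
    )
    from consensv.support import evidence_from_alignments

    locus = make_locus(id="L1", start=10_050, end=10_650, svtype=SVType.DEL, size=600)
    records = evidence_from_alignments(sam, [locus], kind="LONG_READ")
    by_read = {r.record_id: r for r in records}
    assert len(by_read["readA"].events) == 1
    assert by_read["readA"].events[0].op == SVType.DEL
    assert by_read["readA"].events[0].length == 500
    assert by_read["readA"].events[0].position == 10_100
    assert by_read["readB"].events == ()
    assert force_call(locus, records) is True
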