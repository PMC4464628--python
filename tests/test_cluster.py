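import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import n50_oracle, union_find_clusters
from unigene.cluster import (
    ClusterConfig,
    LocusCluster,
    assembly_stats,
    build_unigene_set,
    cluster_by_locus,
    collapse_unaligned,
    select_representative,
)
from unigene.io import TranscriptAlignment, TranscriptRecord


def aln(tid, start, end, scaffold="s1", strand="+", identity=99.0, coverage=100.0):
    return TranscriptAlignment(tid, scaffold, strand, ((start, end),), identity, coverage)


class TestClusterByLocus:
    def test_overlapping_spans_merge(self):
        clusters = cluster_by_locus([aln("a", 0, 100), aln("b", 50, 150)], True, 1)
        assert len(clusters) == 1
        assert clusters[0].footprint == (0, 150)
        assert clusters[0].member_ids == {"a", "b"}

    def test_disjoint_spans_stay_apart(self):
        clusters = cluster_by_locus([aln("a", 0, 100), aln("b", 200, 300)], True, 1)
        assert len(clusters) == 2

    def test_strand_aware_separates_antisense(self):
        alns = [aln("a", 0, 100, strand="+"), aln("b", 0, 100, strand="-")]
        assert len(cluster_by_locus(alns, True, 1)) == 2
        assert len(cluster_by_locus(alns, False, 1)) == 1

    def test_min_overlap_threshold(self):
        alns = [aln("a", 0, 100), aln("b", 95, 200)]
        assert len(cluster_by_locus(alns, True, 5)) == 1
        assert len(cluster_by_locus(alns, True, 6)) == 2

    def test_empty_input(self):
        assert cluster_by_locus([], True, 1) == []

    def test_multi_placement_assigned_to_best_identity(self):
        alns = [
            aln("t", 0, 100, scaffold="s1", identity=99.0),
            aln("t", 0, 100, scaffold="s2", identity=95.0),
            aln("u", 50, 150, scaffold="s2", identity=99.0),
        ]
        clusters = cluster_by_locus(alns, True, 1)
        by_scaffold = {c.scaffold: c for c in clusters}
        assert by_scaffold["s1"].member_ids == {"t"}
        assert by_scaffold["s2"].member_ids == {"u"}

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["s1", "s2"]),
                st.sampled_from(["+", "-"]),
                st.integers(0, 500),
                st.integers(1, 80),
            ),
            min_size=1,
            max_size=60,
        ),
        st.integers(1, 10),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_union_find_oracle(self, rows, min_overlap):
        alignments = [
            aln(f"t{i}", start, start + length, scaffold=scf, strand=strand)
            for i, (scf, strand, start, length) in enumerate(rows)
        ]
        got = {
            frozenset(c.member_ids) for c in cluster_by_locus(alignments, True, min_overlap)
        }
        intervals = [((a.scaffold, a.strand), a.span[0], a.span[1]) for a in alignments]
        expected = {
            frozenset(f"t{i}" for i in grp)
            for grp in union_find_clusters(intervals, min_overlap)
        }
        assert got == expected


class TestSelectRepresentative:
    def _records(self, lengths):
        return {tid: TranscriptRecord(id=tid, sequence="A" * n) for tid, n in lengths.items()}

    def test_max_length_wins(self):
        cluster = LocusCluster("s1", "+", (0, 10), {"t1", "t2"})
        recs = self._records({"t1": 500, "t2": 900})
        assert select_representative(cluster, recs) == "t2"
        assert cluster.representative_id == "t2"

    def test_tie_breaks_lexicographically(self):
        cluster = LocusCluster("s1", "+", (0, 10), {"b", "a"})
        assert select_representative(cluster, self._records({"a": 700, "b": 700})) == "a"

    def test_singleton(self):
        cluster = LocusCluster("s1", "+", (0, 10), {"only"})
        assert select_representative(cluster, self._records({"only": 10})) == "only"

    def test_unknown_member_raises(self):
        cluster = LocusCluster("s1", "+", (0, 10), {"ghost"})
        with pytest.raises(KeyError, match="ghost"):
            select_representative(cluster, {})


class TestCollapseUnaligned:
    def test_per_component_max(self):
        recs = [
            TranscriptRecord(id="X_c0_seq1", sequence="A" * 300),
            TranscriptRecord(id="X_c0_seq2", sequence="A" * 450),
            TranscriptRecord(id="Y_c1_seq1", sequence="A" * 200),
        ]
        assert set(collapse_unaligned(recs)) == {"X_c0_seq2", "Y_c1_seq1"}

    def test_unparseable_id_is_own_component(self):
        recs = [TranscriptRecord(id="oddball", sequence="ACGT")]
        assert collapse_unaligned(recs) == ["oddball"]

    def test_empty(self):
        assert collapse_unaligned([]) == []


class TestAssemblyStats:
    def test_worked_example(self):
        stats = assembly_stats([5, 4, 3, 2, 1])
        assert stats.n50 == 4  # cumulative 5, 9 >= 7.5
        assert stats.count == 5 and stats.max_len == 5 and stats.mean_len == 3

    def test_singleton(self):
        stats = assembly_stats([10])
        assert (stats.count, stats.max_len, stats.mean_len, stats.n50) == (1, 10, 10, 10)

    def test_uniform(self):
        assert assembly_stats([2, 2, 2, 2]).n50 == 2

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            assembly_stats([])

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=100))
    @settings(max_examples=300, deadline=None)
    def test_n50_matches_oracle(self, lengths):
        stats = assembly_stats(lengths)
        assert stats.n50 == n50_oracle(lengths)
        assert stats.max_len == max(lengths)
        assert stats.mean_len == round(sum(lengths) / len(lengths))
        assert stats.max_len >= stats.n50 >= 1


class TestBuildUnigeneSet:
    def test_fixture_recovery(self, fixture_inputs):
        truth = fixture_inputs["truth"]
        transcripts = [
            t for t in fixture_inputs["transcripts"] if t.id not in truth.decoys
        ]
        nr = build_unigene_set(transcripts, fixture_inputs["alignments"])
        assert {t.id for t in nr.representatives} == truth.expected_representatives
        # every representative is the longest member of its group
        by_id = {t.id: t for t in transcripts}
        groups: dict[str, list[str]] = {}
        for tid, locus in truth.locus_of_transcript.items():
            groups.setdefault(locus, []).append(tid)
        for locus, members in groups.items():
            longest = max(members, key=lambda tid: (by_id[tid].length, tid))
            assert longest in truth.expected_representatives

    def test_surjection_onto_representatives(self, fixture_inputs):
        truth = fixture_inputs["truth"]
        transcripts = [
            t for t in fixture_inputs["transcripts"] if t.id not in truth.decoys
        ]
        nr = build_unigene_set(transcripts, fixture_inputs["alignments"])
        assert len(nr.representatives) <= len(transcripts)
        assert set(nr.member_to_representative) == {t.id for t in transcripts}
        assert set(nr.member_to_representative.values()) == {
            t.id for t in nr.representatives
        }

    def test_all_unaligned_degenerates_to_collapse(self):
        recs = [
            TranscriptRecord(id="X_c0_seq1", sequence="A" * 100),
            TranscriptRecord(id="X_c0_seq2", sequence="A" * 200),
        ]
        nr = build_unigene_set(recs, [])
        assert [t.id for t in nr.representatives] == ["X_c0_seq2"]
        assert nr.source_of["X_c0_seq2"] == "unaligned_component"

    def test_single_transcript(self):
        recs = [TranscriptRecord(id="t", sequence="ACGT" * 30)]
        nr = build_unigene_set(recs, [aln("t", 0, 120)])
        assert len(nr.representatives) == 1
        assert nr.source_of["t"] == "aligned_locus"

    def test_stats_over_representative_lengths(self, fixture_inputs):
        truth = fixture_inputs["truth"]
        transcripts = [
            t for t in fixture_inputs["transcripts"] if t.id not in truth.decoys
        ]
        nr = build_unigene_set(transcripts, fixture_inputs["alignments"])
        expected = assembly_stats(sorted(truth.rep_lengths.values()))
        assert nr.stats == expected
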