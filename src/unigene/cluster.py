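"""Genome-anchored locus clustering and non-redundant representative selection.

Transcripts whose accepted genome placements overlap on the same scaffold
(and, by default, strand) are single-linkage clustered into gene loci; the
longest member of each locus becomes its representative.  Transcripts with no
accepted placement are collapsed per assembler component, again keeping the
longest.  The union of both representative sets is the non-redundant unigene
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import TranscriptAlignment, TranscriptRecord

__all__ = [
    "LocusCluster",
    "AssemblyStats",
    "NrUnigeneSet",
    "ClusterConfig",
    "cluster_by_locus",
    "select_representative",
    "collapse_unaligned",
    "build_unigene_set",
    "assembly_stats",
]


@dataclass
class LocusCluster:
    """A set of transcripts sharing an overlapping genomic footprint."""

    scaffold: str
    strand: str  # '+', '-' or 'merged'
    footprint: tuple[int, int]
    member_ids: set[str]
    representative_id: str | None = None

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("locus cluster must have at least one member")


@dataclass(frozen=True)
class AssemblyStats:
    count: int
    max_len: int
    mean_len: int
    n50: int


@dataclass
class NrUnigeneSet:
    representatives: list[TranscriptRecord]
    source_of: dict[str, str]  # id -> 'aligned_locus' | 'unaligned_component'
    stats: AssemblyStats
    clusters: list[LocusCluster] = field(default_factory=list)
    member_to_representative: dict[str, str] = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return sum(1 for s in self.source_of.values() if s == "aligned_locus")

    @property
    def n_unaligned_components(self) -> int:
        return sum(1 for s in self.source_of.values() if s == "unaligned_component")


@dataclass
class ClusterConfig:
    strand_aware: bool = True
    min_overlap_bp: int = 1
    min_identity: float = 95.0
    min_coverage: float = 90.0


def _best_placement_key(aln: TranscriptAlignment) -> tuple:
    # higher identity wins, then longer aligned span, then earliest coordinates
    return (-aln.identity_pct, -aln.span_length, aln.scaffold, aln.span[0], aln.span[1])


def cluster_by_locus(
    alignments: Sequence[TranscriptAlignment],
    strand_aware: bool = True,
    min_overlap_bp: int = 1,
) -> list[LocusCluster]:
    """Single-linkage cluster alignments into gene loci.

    Two placements on the same scaffold (and strand, if ``strand_aware``) are
    linked iff their spans overlap by at least ``min_overlap_bp``.  Clusters
    are the connected components.  A transcript placed in several clusters is
    assigned to the cluster holding its best placement (highest identity,
    then longest aligned span, then earliest coordinates); clusters emptied
    by this reassignment are dropped.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if not alignments:
        return []

    # group alignments by clustering key
    by_key: dict[tuple, list[TranscriptAlignment]] = {}
    for aln in alignments:
        key = (aln.scaffold, aln.strand) if strand_aware else (aln.scaffold,)
        by_key.setdefault(key, []).append(aln)

    # proto-clusters via a sorted sweep.  With starts ascending, an interval
    # of length >= min_overlap_bp links to the open component iff the
    # component's max end reaches start + min_overlap_bp; shorter intervals
    # can never link to anything and become immediate singletons without
    # closing the open component.
    proto: list[tuple[tuple, list[TranscriptAlignment]]] = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda a: a.span)
        current: list[TranscriptAlignment] = []
        max_end = -1
        for aln in group:
            start, end = aln.span
            if end - start < min_overlap_bp:
                proto.append((key, [aln]))
                continue
            if current and max_end >= start + min_overlap_bp:
                current.append(aln)
                max_end = max(max_end, end)
            else:
                if current:
                    proto.append((key, current))
                current = [aln]
                max_end = end
        if current:
            proto.append((key, current))

    # resolve multi-placement transcripts: best placement decides membership
    best_of: dict[str, TranscriptAlignment] = {}
    for aln in alignments:
        prev = best_of.get(aln.transcript_id)
        if prev is None or _best_placement_key(aln) < _best_placement_key(prev):
            best_of[aln.transcript_id] = aln

    clusters: list[LocusCluster] = []
    for key, members in proto:
        chosen = [a for a in members if best_of[a.transcript_id] is a]
        if not chosen:
            continue
        ids = {a.transcript_id for a in chosen}
        footprint = (min(a.span[0] for a in chosen), max(a.span[1] for a in chosen))
        strand = key[1] if len(key) == 2 else "merged"
        clusters.append(
            LocusCluster(scaffold=key[0], strand=strand, footprint=footprint, member_ids=ids)
        )
    return clusters


def select_representative(
    cluster: LocusCluster, transcripts: Mapping[str, TranscriptRecord]
) -> str:
    """Pick the longest member (tie: lexicographically smallest id) and record
    it on the cluster."""
    unknown = [tid for tid in cluster.member_ids if tid not in transcripts]
    if unknown:
        raise KeyError(f"cluster members not found among transcripts: {sorted(unknown)}")
    representative = min(cluster.member_ids, key=lambda tid: (-transcripts[tid].length, tid))
    cluster.representative_id = representative
    return representative


def collapse_unaligned(unaligned: Sequence[TranscriptRecord]) -> list[str]:
    """Collapse unaligned transcripts per assembler component, keeping the
    longest (tie: lexicographically smallest id) of each component."""
    by_component: dict[str, list[TranscriptRecord]] = {}
    for t in unaligned:
        by_component.setdefault(t.component_id, []).append(t)
    return [
        min(members, key=lambda t: (-t.length, t.id)).id
        for _, members in sorted(by_component.items())
    ]


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """Count, max, rounded mean and N50 of a length multiset.

    N50 is the largest member length L such that sequences of length >= L sum
    to at least half the total length (standard cumulative-half definition).
    """
    if not lengths:
        raise ValueError("assembly_stats requires at least one length")
    if any(x < 1 for x in lengths):
        raise ValueError("all lengths must be >= 1")
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    half = total / 2
    running = 0
    n50 = ordered[-1]
    for x in ordered:
        running += x
        if running >= half:
            n50 = x
            break
    return AssemblyStats(
        count=len(ordered),
        max_len=ordered[0],
        mean_len=round(total / len(ordered)),
        n50=n50,
    )


def build_unigene_set(
    filtered_transcripts: Sequence[TranscriptRecord],
    alignments: Sequence[TranscriptAlignment],
    config: ClusterConfig | None = None,
) -> NrUnigeneSet:
    """Construct the non-redundant unigene set from filtered transcripts and
    their accepted genome placements."""
    if config is None:
        config = ClusterConfig()
    by_id = {t.id: t for t in filtered_transcripts}
    relevant = [a for a in alignments if a.transcript_id in by_id]

    clusters = cluster_by_locus(relevant, config.strand_aware, config.min_overlap_bp)
    member_to_rep: dict[str, str] = {}
    source_of: dict[str, str] = {}
    rep_ids: list[str] = []
    for cl in clusters:
        rep = select_representative(cl, by_id)
        rep_ids.append(rep)
        source_of[rep] = "aligned_locus"
        for member in cl.member_ids:
            member_to_rep[member] = rep

    aligned_ids = {a.transcript_id for a in relevant}
    unaligned = [t for t in filtered_transcripts if t.id not in aligned_ids]
    by_component: dict[str, list[TranscriptRecord]] = {}
    for t in unaligned:
        by_component.setdefault(t.component_id, []).append(t)
    for rep in collapse_unaligned(unaligned):
        rep_ids.append(rep)
        source_of[rep] = "unaligned_component"
        for member in by_component[by_id[rep].component_id]:
            member_to_rep[member.id] = rep

    representatives = [by_id[r] for r in rep_ids]
    stats = assembly_stats([t.length for t in representatives])
    return NrUnigeneSet(
        representatives=representatives,
        source_of=source_of,
        stats=stats,
        clusters=clusters,
        member_to_representative=member_to_rep,
    )


def write_clusters_tsv(clusters: Iterable[LocusCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tscaffold\tstrand\tstart\tend\tmember_ids\trepresentative_id\n")
        for i, cl in enumerate(clusters, start=1):
            fh.write(
                "\t".join(
                    [
                        f"locus{i:05d}",
                        cl.scaffold,
                        cl.strand,
                        str(cl.footprint[0]),
                        str(cl.footprint[1]),
                        ",".join(sorted(cl.member_ids)),
                        cl.representative_id or "",
                    ]
                )
                + "\n"
            )


def write_stats_tsv(stats: AssemblyStats, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"count\t{stats.count}\n")
        fh.write(f"max_len\t{stats.max_len}\n")
        fh.write(f"mean_len\t{stats.mean_len}\n")
        fh.write(f"n50\t{stats.n50}\n")
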