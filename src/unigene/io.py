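"""Readers and writers for the file dialects consumed by the pipeline.

All genomic coordinates are 0-based half-open internally; GFF3 (1-based
inclusive) is converted at the boundary.  Sequence case is normalised to
uppercase on read.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptRecord",
    "TranscriptAlignment",
    "HitRecord",
    "CountMatrix",
    "parse_component_id",
    "read_fasta",
    "write_fasta",
    "read_alignments_gff3",
    "write_alignments_gff3",
    "read_hits_table",
    "read_count_matrix",
]

_NUCLEOTIDES = set("ACGTNRYSWKMBDHV")  # IUPAC nucleotide codes

_SEQ_SUFFIX = re.compile(r"^(?P<stem>.+)_seq(?P<k>[1-9]\d*)$")


def parse_component_id(transcript_id: str) -> tuple[str, int | None]:
    """Split an assembler-style transcript id into (component_id, isoform_index).

    Ids of the form ``<stem>_seq<k>`` with integer ``k >= 1`` are split into
    the component stem and the isoform index; anything else falls back to the
    whole id with no isoform index.  Total: never raises.

    >>> parse_component_id("Pg_Root111466_c0_seq17")
    ('Pg_Root111466_c0', 17)
    >>> parse_component_id("geneA")
    ('geneA', None)
    """
    if not transcript_id:
        raise ValueError("transcript id must be non-empty")
    m = _SEQ_SUFFIX.match(transcript_id)
    if m is None:
        return transcript_id, None
    return m.group("stem"), int(m.group("k"))


@dataclass(frozen=True)
class TranscriptRecord:
    """An assembled transcript with its parsed assembler component identity."""

    id: str
    sequence: str
    component_id: str = field(default="", compare=False)
    isoform_index: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.component_id:
            comp, iso = parse_component_id(self.id)
            object.__setattr__(self, "component_id", comp)
            object.__setattr__(self, "isoform_index", iso)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptAlignment:
    """One genome placement of a transcript.

    ``exon_blocks`` are 0-based half-open intervals on the scaffold, sorted
    ascending and non-overlapping.  ``span`` is (first block start, last block
    end).
    """

    transcript_id: str
    scaffold: str
    strand: str
    exon_blocks: tuple[tuple[int, int], ...]
    identity_pct: float
    coverage_pct: float

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exon_blocks:
            raise ValueError(f"alignment of {self.transcript_id} has no exons")
        blocks = tuple(tuple(b) for b in self.exon_blocks)
        prev_end = -1
        for start, end in blocks:
            if start >= end:
                raise ValueError(f"empty exon block ({start}, {end}) for {self.transcript_id}")
            if start < prev_end:
                raise ValueError(f"overlapping/unsorted exon blocks for {self.transcript_id}")
            prev_end = end
        object.__setattr__(self, "exon_blocks", blocks)
        if not (0.0 <= self.identity_pct <= 100.0 and 0.0 <= self.coverage_pct <= 100.0):
            raise ValueError("identity/coverage must be percentages in [0, 100]")

    @property
    def span(self) -> tuple[int, int]:
        return self.exon_blocks[0][0], self.exon_blocks[-1][1]

    @property
    def span_length(self) -> int:
        start, end = self.span
        return end - start


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular homology search output."""

    query_id: str
    subject_id: str
    identity_pct: float
    align_len: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")
        if self.align_len < 1:
            raise ValueError("alignment length must be >= 1")


class CountMatrix:
    """Per-transcript, per-sample fragment counts with replicate structure.

    Counts may be non-integer (expectation-based estimates are permitted) but
    never negative.  Every sample maps to exactly one group.
    """

    def __init__(
        self,
        transcript_ids: Sequence[str],
        sample_labels: Sequence[str],
        counts,
        group_of_sample: Mapping[str, str],
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (len(transcript_ids), len(sample_labels)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(transcript_ids)} transcripts x {len(sample_labels)} samples"
            )
        if (counts < 0).any():
            raise ValueError("count matrix contains negative entries")
        if len(set(transcript_ids)) != len(transcript_ids):
            raise ValueError("duplicate transcript ids in count matrix")
        missing = [s for s in sample_labels if s not in group_of_sample]
        if missing:
            raise ValueError(f"samples missing from group map: {missing}")
        self.transcript_ids = list(transcript_ids)
        self.sample_labels = list(sample_labels)
        self.counts = counts
        self.group_of_sample = {s: group_of_sample[s] for s in sample_labels}

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sample_labels:
            seen.setdefault(self.group_of_sample[s], None)
        return list(seen)

    def samples_of_group(self, group: str) -> list[str]:
        out = [s for s in self.sample_labels if self.group_of_sample[s] == group]
        if not out:
            raise KeyError(f"unknown group {group!r}")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.transcript_ids, columns=self.sample_labels)

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[TranscriptRecord]:
    """Read transcripts from FASTA; sequences uppercased, ids must be unique."""
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id in {path}: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r} in {path}")
        odd = set(seq) - _NUCLEOTIDES
        if odd:
            warnings.warn(
                f"transcript {rec.id!r} contains non-nucleotide symbols {sorted(odd)}; kept verbatim",
                stacklevel=2,
            )
        records.append(TranscriptRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[TranscriptRecord], path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# GFF3 alignment dialect (gene-structure output with identity/coverage
# attributes on the mRNA feature)

_ATTR = re.compile(r"(?P<key>[^;=]+)=(?P<value>[^;]*)")


def _parse_attributes(text: str) -> dict[str, str]:
    return {m.group("key").strip(): m.group("value").strip() for m in _ATTR.finditer(text)}


def read_alignments_gff3(
    path,
    min_identity: float = 95.0,
    min_coverage: float = 90.0,
) -> tuple[list[TranscriptAlignment], set[str]]:
    """Read transcript-to-genome alignments from a GFF3 file.

    mRNA features must carry ``identity`` and ``coverage`` attributes and a
    ``Name`` (or ``ID``) giving the transcript id; exon features reference
    their mRNA via ``Parent``.  Placements passing both thresholds are
    returned as :class:`TranscriptAlignment`; ``rejected_ids`` holds
    transcript ids whose every placement failed a threshold.  A transcript
    with several accepted placements yields several alignments.
    """
    mrnas: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attr_text = fields
            attrs = _parse_attributes(attr_text)
            if ftype == "mRNA":
                feature_id = attrs.get("ID") or attrs.get("Name")
                if feature_id is None:
                    raise ValueError(f"{path}:{lineno}: mRNA feature without ID/Name")
                name = attrs.get("Name", feature_id)
                try:
                    identity = float(attrs["identity"])
                    coverage = float(attrs["coverage"])
                except KeyError as exc:
                    raise ValueError(f"{path}:{lineno}: mRNA missing {exc} attribute") from None
                mrnas[feature_id] = {
                    "transcript_id": name,
                    "scaffold": seqid,
                    "strand": strand,
                    "identity": identity,
                    "coverage": coverage,
                    "exons": [],
                    "lineno": lineno,
                }
                order.append(feature_id)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None or parent not in mrnas:
                    raise ValueError(f"{path}:{lineno}: exon with no parent mRNA")
                # GFF3 1-based inclusive -> 0-based half-open
                mrnas[parent]["exons"].append((int(start) - 1, int(end)))

    accepted: list[TranscriptAlignment] = []
    rejected_ids: set[str] = set()
    accepted_ids: set[str] = set()
    for feature_id in order:
        rec = mrnas[feature_id]
        exons = rec["exons"]
        if not exons:
            raise ValueError(f"{path}: mRNA {feature_id!r} has no exon features")
        if exons != sorted(exons):
            warnings.warn(f"unsorted exons for {feature_id!r}; sorting", stacklevel=2)
            exons = sorted(exons)
        if rec["identity"] >= min_identity and rec["coverage"] >= min_coverage:
            accepted.append(
                TranscriptAlignment(
                    transcript_id=rec["transcript_id"],
                    scaffold=rec["scaffold"],
                    strand=rec["strand"],
                    exon_blocks=tuple(exons),
                    identity_pct=rec["identity"],
                    coverage_pct=rec["coverage"],
                )
            )
            accepted_ids.add(rec["transcript_id"])
        else:
            rejected_ids.add(rec["transcript_id"])
    return accepted, rejected_ids - accepted_ids


def write_alignments_gff3(alignments: Iterable[TranscriptAlignment], path) -> None:
    """Emit alignments in the GFF3 dialect read by :func:`read_alignments_gff3`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        counters: dict[str, int] = {}
        for aln in alignments:
            n = counters.get(aln.transcript_id, 0) + 1
            counters[aln.transcript_id] = n
            mrna_id = f"{aln.transcript_id}.path{n}"
            start, end = aln.span
            fh.write(
                "\t".join(
                    [
                        aln.scaffold,
                        "unigene",
                        "mRNA",
                        str(start + 1),
                        str(end),
                        ".",
                        aln.strand,
                        ".",
                        f"ID={mrna_id};Name={aln.transcript_id};"
                        f"identity={aln.identity_pct};coverage={aln.coverage_pct}",
                    ]
                )
                + "\n"
            )
            for i, (bstart, bend) in enumerate(aln.exon_blocks, start=1):
                fh.write(
                    "\t".join(
                        [
                            aln.scaffold,
                            "unigene",
                            "exon",
                            str(bstart + 1),
                            str(bend),
                            ".",
                            aln.strand,
                            ".",
                            f"ID={mrna_id}.exon{i};Parent={mrna_id}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Tabular hit files (12-column standard order)


def read_hits_table(path) -> list[HitRecord]:
    """Read a 12-column tabular homology search output (TSV)."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected >= 12 columns, got {len(fields)}")
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        identity_pct=float(fields[2]),
                        align_len=int(fields[3]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except (ValueError, IndexError) as exc:
                if isinstance(exc, ValueError) and "must be" in str(exc):
                    raise
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
    return hits


def write_hits_table(hits: Iterable[HitRecord], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_pct:.2f}",
                        str(h.align_len),
                        "0",
                        "0",
                        "1",
                        str(h.align_len),
                        "1",
                        str(h.align_len),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Count matrices


def read_count_matrix(path, sample_groups: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count table (header of sample labels, rows of counts)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in df.columns if s not in sample_groups]
    if missing:
        raise ValueError(f"samples in {path} missing from group map: {missing}")
    if (df.values < 0).any():
        raise ValueError(f"negative counts in {path}")
    return CountMatrix(
        transcript_ids=list(df.index.astype(str)),
        sample_labels=list(df.columns.astype(str)),
        counts=df.values,
        group_of_sample=sample_groups,
    )


def write_count_matrix(matrix: CountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="transcript_id")
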