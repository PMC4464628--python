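"""Post-assembly cleanup cascade: contaminant, rRNA and noncoding removal.

Stages run in a fixed order (contaminant -> rRNA -> lncRNA) and each removed
transcript is attributed to the first stage that removed it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import HitRecord, TranscriptRecord
from .orf import OrfAnnotation, annotate_orfs

__all__ = [
    "RrnaPrediction",
    "FilterConfig",
    "FilterReport",
    "filter_contaminants",
    "filter_rrna",
    "flag_noncoding",
    "run_filter_cascade",
    "read_rrna_gff",
    "write_rrna_gff",
]


@dataclass(frozen=True)
class RrnaPrediction:
    """A predicted rRNA segment on a transcript (0-based half-open)."""

    transcript_id: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid rRNA interval ({self.start}, {self.end})")


@dataclass
class FilterConfig:
    contaminant_max_evalue: float = 1e-10
    contaminant_min_identity: float = 90.0
    contaminant_min_covered_fraction: float = 0.5
    min_rrna_fraction: float = 0.5
    min_orf_aa: int = 100
    protein_max_evalue: float = 1e-5


@dataclass
class FilterReport:
    """Accounting of the cascade; each transcript counted once, at the first
    stage that removed it."""

    initial_count: int
    removed_contaminant: int
    removed_rrna: int
    removed_lncrna: int
    final_count: int = field(default=-1)

    def __post_init__(self) -> None:
        expected = self.initial_count - (
            self.removed_contaminant + self.removed_rrna + self.removed_lncrna
        )
        if self.final_count < 0:
            self.final_count = expected
        elif self.final_count != expected:
            raise ValueError("filter report counts are inconsistent")

    @property
    def removed_fraction(self) -> float:
        if self.initial_count == 0:
            return 0.0
        return 1.0 - self.final_count / self.initial_count

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"initial_count\t{self.initial_count}\n")
            fh.write(f"removed_contaminant\t{self.removed_contaminant}\n")
            fh.write(f"removed_rrna\t{self.removed_rrna}\n")
            fh.write(f"removed_lncrna\t{self.removed_lncrna}\n")
            fh.write(f"final_count\t{self.final_count}\n")
            fh.write(f"removed_fraction\t{self.removed_fraction:.6f}\n")


def filter_contaminants(
    transcripts: Sequence[TranscriptRecord],
    hits: Iterable[HitRecord],
    max_evalue: float = 1e-10,
    min_identity: float = 90.0,
    min_covered_fraction: float = 0.5,
) -> tuple[list[TranscriptRecord], set[str]]:
    """Remove transcripts with at least one sufficiently strong hit to a
    contaminant database.

    A hit removes its transcript iff ``evalue <= max_evalue`` and
    ``identity_pct >= min_identity`` and the aligned length covers at least
    ``min_covered_fraction`` of the transcript.
    """
    length_of = {t.id: t.length for t in transcripts}
    removed: set[str] = set()
    for hit in hits:
        tlen = length_of.get(hit.query_id)
        if tlen is None:
            warnings.warn(f"contaminant hit for unknown transcript {hit.query_id!r}; ignored", stacklevel=2)
            continue
        if (
            hit.evalue <= max_evalue
            and hit.identity_pct >= min_identity
            and hit.align_len / tlen >= min_covered_fraction
        ):
            removed.add(hit.query_id)
    kept = [t for t in transcripts if t.id not in removed]
    return kept, removed


def covered_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    merged = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                merged += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        merged += cur_end - cur_start
    return merged


def filter_rrna(
    transcripts: Sequence[TranscriptRecord],
    predictions: Iterable[RrnaPrediction],
    min_rrna_fraction: float = 0.5,
) -> tuple[list[TranscriptRecord], set[str]]:
    """Remove transcripts whose predicted rRNA segments (union length) cover
    at least ``min_rrna_fraction`` of the transcript."""
    length_of = {t.id: t.length for t in transcripts}
    by_transcript: dict[str, list[tuple[int, int]]] = {}
    for p in predictions:
        tlen = length_of.get(p.transcript_id)
        if tlen is None:
            continue
        if p.end > tlen:
            raise ValueError(
                f"rRNA prediction ({p.start}, {p.end}) out of bounds for "
                f"{p.transcript_id!r} of length {tlen}"
            )
        by_transcript.setdefault(p.transcript_id, []).append((p.start, p.end))
    removed = {
        tid
        for tid, ivs in by_transcript.items()
        if covered_length(ivs) / length_of[tid] >= min_rrna_fraction
    }
    kept = [t for t in transcripts if t.id not in removed]
    return kept, removed


def flag_noncoding(
    transcripts: Sequence[TranscriptRecord],
    orf_annotations: Mapping[str, OrfAnnotation],
    protein_hits: Iterable[HitRecord],
    min_orf_aa: int = 100,
    max_evalue: float = 1e-5,
) -> set[str]:
    """Flag transcripts with neither a long ORF nor protein homology.

    This is a stand-in coding-potential rule: a transcript is flagged as
    long-noncoding iff it has no ORF of >= ``min_orf_aa`` amino acids and no
    protein hit at ``evalue <= max_evalue``.
    """
    with_homology = {h.query_id for h in protein_hits if h.evalue <= max_evalue}
    flagged: set[str] = set()
    for t in transcripts:
        ann = orf_annotations.get(t.id)
        has_orf = ann is not None and ann.aa_length >= min_orf_aa
        if not has_orf and t.id not in with_homology:
            flagged.add(t.id)
    return flagged


def run_filter_cascade(
    transcripts: Sequence[TranscriptRecord],
    contaminant_hits: Sequence[HitRecord],
    rrna_predictions: Sequence[RrnaPrediction],
    protein_hits: Sequence[HitRecord],
    config: FilterConfig | None = None,
) -> tuple[list[TranscriptRecord], FilterReport]:
    """Apply contaminant -> rRNA -> lncRNA removal in order and report counts
    with first-stage attribution."""
    if config is None:
        config = FilterConfig()
    initial = len(transcripts)

    kept, removed_cont = filter_contaminants(
        transcripts,
        contaminant_hits,
        max_evalue=config.contaminant_max_evalue,
        min_identity=config.contaminant_min_identity,
        min_covered_fraction=config.contaminant_min_covered_fraction,
    )
    kept, removed_rrna = filter_rrna(kept, rrna_predictions, config.min_rrna_fraction)
    annotations = annotate_orfs(kept, min_orf_aa=config.min_orf_aa)
    flagged = flag_noncoding(
        kept,
        annotations,
        protein_hits,
        min_orf_aa=config.min_orf_aa,
        max_evalue=config.protein_max_evalue,
    )
    kept = [t for t in kept if t.id not in flagged]

    report = FilterReport(
        initial_count=initial,
        removed_contaminant=len(removed_cont),
        removed_rrna=len(removed_rrna),
        removed_lncrna=len(flagged),
        final_count=len(kept),
    )
    return kept, report


# ---------------------------------------------------------------------------
# RNAmmer-style GFF (transcript-space predictions)


def read_rrna_gff(path) -> list[RrnaPrediction]:
    """Read rRNA predictions from a GFF-like TSV (1-based inclusive coords)."""
    predictions: list[RrnaPrediction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns")
            try:
                score = float(fields[5]) if fields[5] != "." else 0.0
                predictions.append(
                    RrnaPrediction(
                        transcript_id=fields[0],
                        start=int(fields[3]) - 1,
                        end=int(fields[4]),
                        score=score,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
    return predictions


def write_rrna_gff(predictions: Iterable[RrnaPrediction], path) -> None:
    with open(path, "w") as fh:
        for p in predictions:
            fh.write(
                "\t".join(
                    [p.transcript_id, "rrna", "rRNA", str(p.start + 1), str(p.end), f"{p.score:.1f}", "+", ".", "-"]
                )
                + "\n"
            )
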