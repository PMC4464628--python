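"""Six-frame ORF discovery and completeness classification.

An ORF candidate in a frame is a maximal run between (a start codon or the
frame's sequence edge) and (a stop codon or the edge).  The best candidate is
the one with the most amino acids; ties break by frame order
``+1, +2, +3, -1, -2, -3`` and then by the 5'-most start within the frame.
Codons containing ``N`` (or any non-ACGT symbol) never match start or stop.
``aa_length`` excludes the stop codon.  Standard genetic code only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import HitRecord, TranscriptRecord

__all__ = [
    "OrfAnnotation",
    "find_best_orf",
    "annotate_orfs",
    "classify_orf_set",
    "FRAMES",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfAnnotation:
    """Best ORF of a transcript with completeness category.

    ``start``/``end`` are 0-based half-open on the *forward* transcript
    coordinate regardless of frame; ``end - start`` is a multiple of 3, plus
    3 when the stop codon is included.
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    aa_length: int
    has_start_codon: bool
    has_stop_codon: bool

    @property
    def category(self) -> str:
        if self.has_start_codon and self.has_stop_codon:
            return "complete"
        if self.has_stop_codon:
            return "five_prime_partial"
        if self.has_start_codon:
            return "three_prime_partial"
        return "internal"


def _frame_candidates(seq: str, offset: int):
    """Yield (start, aa_length, has_start, has_stop, end) candidates in one
    forward frame of ``seq``, coordinates in frame-local nucleotides.

    Candidates are maximal: per stop-delimited segment, the run from the
    segment's leading edge (if it touches the sequence start) and the run
    from the segment's first start codon.
    """
    n = len(seq)
    codon_starts = range(offset, n - 2, 3)
    seg_begin = offset  # first codon position of the current segment
    seg_first_atg = None
    at_edge = True  # does the current segment touch the frame's 5' edge?
    for pos in codon_starts:
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if at_edge and seg_begin < pos:
                # a run touching the edge counts as started iff its first
                # codon happens to be ATG
                yield seg_begin, (pos - seg_begin) // 3, seg_first_atg == seg_begin, True, pos + 3
            if seg_first_atg is not None and not (at_edge and seg_first_atg == seg_begin):
                yield seg_first_atg, (pos - seg_first_atg) // 3, True, True, pos + 3
            seg_begin = pos + 3
            seg_first_atg = None
            at_edge = False
        elif codon == START_CODON and seg_first_atg is None:
            seg_first_atg = pos
    # trailing segment runs to the frame edge (no stop)
    seg_end = offset + 3 * ((n - offset) // 3)
    if at_edge and seg_begin < seg_end:
        yield seg_begin, (seg_end - seg_begin) // 3, seg_first_atg == seg_begin, False, seg_end
    if (
        seg_first_atg is not None
        and seg_first_atg < seg_end
        and not (at_edge and seg_first_atg == seg_begin)
    ):
        yield seg_first_atg, (seg_end - seg_first_atg) // 3, True, False, seg_end


def find_best_orf(transcript: TranscriptRecord, min_orf_aa: int = 100) -> OrfAnnotation | None:
    """Scan all six frames and return the longest ORF of >= ``min_orf_aa``
    amino acids, or ``None`` if no candidate reaches the threshold."""
    seq = transcript.sequence
    rc = reverse_complement(seq)
    n = len(seq)
    best: tuple[int, int, int] | None = None  # (-aa, frame_rank, local_start)
    best_ann: OrfAnnotation | None = None
    for rank, frame in enumerate(FRAMES):
        working = seq if frame > 0 else rc
        offset = abs(frame) - 1
        for start, aa, has_start, has_stop, end in _frame_candidates(working, offset):
            if aa < min_orf_aa or aa == 0:
                continue
            key = (-aa, rank, start)
            if best is None or key < best:
                best = key
                if frame > 0:
                    fwd_start, fwd_end = start, end
                else:
                    fwd_start, fwd_end = n - end, n - start
                best_ann = OrfAnnotation(
                    transcript_id=transcript.id,
                    frame=frame,
                    start=fwd_start,
                    end=fwd_end,
                    aa_length=aa,
                    has_start_codon=has_start,
                    has_stop_codon=has_stop,
                )
    return best_ann


def annotate_orfs(
    transcripts: Iterable[TranscriptRecord],
    min_orf_aa: int = 100,
    rescue_hits: Sequence[HitRecord] | None = None,
    rescue_max_evalue: float = 1e-5,
    rescue_min_aa: int = 10,
) -> dict[str, OrfAnnotation]:
    """Annotate every transcript with its best ORF (if any).

    ``rescue_hits`` optionally provides homology evidence promoting
    sub-threshold ORFs: a transcript with no reported ORF but a hit at
    ``evalue <= rescue_max_evalue`` is re-scanned at ``rescue_min_aa``.
    """
    rescued: set[str] = set()
    if rescue_hits is not None:
        rescued = {h.query_id for h in rescue_hits if h.evalue <= rescue_max_evalue}
    annotations: dict[str, OrfAnnotation] = {}
    for t in transcripts:
        ann = find_best_orf(t, min_orf_aa)
        if ann is None and t.id in rescued:
            ann = find_best_orf(t, rescue_min_aa)
        if ann is not None:
            annotations[t.id] = ann
    return annotations


def classify_orf_set(
    transcripts: Sequence[TranscriptRecord],
    min_orf_aa: int = 100,
    annotations: Mapping[str, OrfAnnotation] | None = None,
) -> dict[str, float]:
    """Summarise ORF completeness over a transcript set.

    ``coding_fraction`` is relative to all transcripts; the four category
    fractions are relative to coding transcripts and sum to 1.
    """
    if not transcripts:
        raise ValueError("cannot classify an empty transcript set")
    if annotations is None:
        annotations = annotate_orfs(transcripts, min_orf_aa)
    n_total = len(transcripts)
    counts = {"complete": 0, "five_prime_partial": 0, "three_prime_partial": 0, "internal": 0}
    n_coding = 0
    for t in transcripts:
        ann = annotations.get(t.id)
        if ann is None:
            continue
        n_coding += 1
        counts[ann.category] += 1
    summary = {"coding_fraction": n_coding / n_total}
    for cat, short in [
        ("complete", "fraction_complete"),
        ("five_prime_partial", "fraction_5partial"),
        ("three_prime_partial", "fraction_3partial"),
        ("internal", "fraction_internal"),
    ]:
        summary[short] = counts[cat] / n_coding if n_coding else 0.0
    return summary


_CODON_TABLE = {}


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


def translate_orf(transcript: TranscriptRecord, ann: OrfAnnotation) -> str:
    """Translate an annotated ORF to its peptide (stop codon not included)."""
    global _CODON_TABLE
    if not _CODON_TABLE:
        _CODON_TABLE = _build_codon_table()
    sub = transcript.sequence[ann.start : ann.end]
    if ann.frame < 0:
        sub = reverse_complement(sub)
    peptide = []
    for i in range(0, len(sub) - 2, 3):
        codon = sub[i : i + 3]
        aa = _CODON_TABLE.get(codon, "X")
        if aa == "*":
            break
        peptide.append(aa)
    return "".join(peptide)
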