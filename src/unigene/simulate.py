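"""Deterministic synthetic fixture generator.

Builds a complete toy study — genome, multi-isoform transcripts, decoys,
alignments, count matrices with planted differential/specific/motif
structure — plus machine-readable truth tables, so every pipeline stage can
be tested without external data.  The same seed always yields a
byte-identical bundle.

Construction notes: isoforms of a locus are 3'-truncations of the locus
sequence, so locus clustering and longest-member representative selection
are unambiguous by construction.  Coding payloads are long enough
(>= 280 codons) that spurious open frames in shifted/reverse frames are
vanishingly unlikely to out-compete the planted ORF.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    CountMatrix,
    HitRecord,
    TranscriptAlignment,
    TranscriptRecord,
    write_alignments_gff3,
    write_count_matrix,
    write_fasta,
    write_hits_table,
)
from .filtering import RrnaPrediction, write_rrna_gff
from .orf import find_best_orf
from .pathway import load_pathway_definition
from .prosite import load_pattern, pattern_exemplar

__all__ = ["FixtureConfig", "TruthTable", "generate_fixture", "simulate_counts"]

_STOPS = ("TAA", "TAG", "TGA")
_ALL_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")
# codons that are neither stop nor start: safe filler for coding payloads
_SAFE_CODONS = tuple(c for c in _ALL_CODONS if c not in _STOPS and c != "ATG")

# amino acid -> synonymous codons (random choice keeps shifted frames
# stop-rich; a fixed codon per residue would create long spurious frames)
_AA_CODONS: dict[str, list[str]] = {}
for _codon in _ALL_CODONS:
    from Bio.Data.CodonTable import standard_dna_table as _tbl

    if _codon in _tbl.forward_table:
        _AA_CODONS.setdefault(_tbl.forward_table[_codon], []).append(_codon)

_CATEGORY_CYCLE = (
    "complete",
    "complete",
    "five_prime_partial",
    "complete",
    "three_prime_partial",
    "complete",
    "internal",
)


def default_pattern_path() -> Path:
    return Path(str(importlib.resources.files("unigene").joinpath("data/pspg.pattern")))


def default_pathway_path() -> Path:
    return Path(str(importlib.resources.files("unigene").joinpath("data/pathway.yaml")))


@dataclass
class FixtureConfig:
    seed: int = 42
    n_loci: int = 20
    isoforms_per_locus: tuple[int, int] = (2, 4)
    locus_gap_bp: int = 500
    n_unaligned_components: int = 5
    isoforms_per_unaligned: tuple[int, int] = (1, 3)
    n_contaminants: int = 3
    n_rrna: int = 2
    n_lncrna: int = 2
    groups: tuple[tuple[str, int], ...] = (
        ("whole_root", 3),
        ("main_body", 3),
        ("lateral_root", 3),
        ("rhizome", 3),
    )
    nb_dispersion: float = 0.1
    de_fraction: float = 0.2
    de_fold: float = 10.0
    specific_fraction: float = 0.12
    n_motif_positives: int = 3

    def validate(self) -> None:
        if self.locus_gap_bp <= 0:
            raise ValueError("locus_gap_bp must be > 0")
        if self.de_fold <= 1:
            raise ValueError("de_fold must be > 1")
        for name in ("n_loci", "n_unaligned_components", "n_contaminants", "n_rrna", "n_lncrna", "n_motif_positives"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.de_fraction <= 1 and 0 <= self.specific_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_motif_positives > self.n_loci:
            raise ValueError("n_motif_positives cannot exceed n_loci")
        for lo, hi in (self.isoforms_per_locus, self.isoforms_per_unaligned):
            if not (1 <= lo <= hi):
                raise ValueError("isoform ranges must satisfy 1 <= lo <= hi")


@dataclass
class TruthTable:
    locus_of_transcript: dict[str, str] = field(default_factory=dict)
    expected_representatives: set[str] = field(default_factory=set)
    planted_de: dict[str, str] = field(default_factory=dict)  # id -> direction
    planted_specific: dict[str, str] = field(default_factory=dict)  # id -> group
    planted_motif: set[str] = field(default_factory=set)
    planted_category: dict[str, str] = field(default_factory=dict)
    decoys: dict[str, str] = field(default_factory=dict)  # id -> stage
    ko_of_transcript: dict[str, str] = field(default_factory=dict)
    enzyme_of_ko: dict[str, str] = field(default_factory=dict)
    rep_lengths: dict[str, int] = field(default_factory=dict)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _safe_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(_SAFE_CODONS)[rng.integers(0, len(_SAFE_CODONS), n)])


def _encode_peptide(rng: np.random.Generator, peptide: str) -> str:
    return "".join(
        _AA_CODONS[aa][rng.integers(0, len(_AA_CODONS[aa]))] for aa in peptide
    )


def _coding_sequence(
    rng: np.random.Generator, category: str, payload_aa: int, motif: str | None = None
) -> str:
    """Build a transcript sequence whose best ORF has the requested
    completeness category (for the full, untruncated sequence)."""
    if motif is not None:
        n_rand = payload_aa - len(motif)
        insert_at = int(rng.integers(10, max(11, n_rand - 10)))
        aa_pool = np.array(list("ACDEFGHIKLNPQRSTVWY"))  # no M: keeps first ATG planted
        flank = "".join(aa_pool[rng.integers(0, len(aa_pool), n_rand)])
        peptide = flank[:insert_at] + motif + flank[insert_at:]
        payload = _encode_peptide(rng, peptide)
    else:
        payload = _safe_codons(rng, payload_aa)

    utr5 = _safe_codons(rng, 8) + "TAA"  # in-frame stop shields the planted start
    utr3 = _rand_seq(rng, 30)
    if category == "complete":
        return utr5 + "ATG" + payload + "TAA" + utr3
    if category == "five_prime_partial":
        return payload + "TAA" + utr3
    if category == "three_prime_partial":
        return utr5 + "ATG" + payload
    if category == "internal":
        return payload
    raise ValueError(f"unknown category {category!r}")


def _noncoding_sequence(rng: np.random.Generator, length: int, min_orf_aa: int = 100) -> str:
    """Random sequence with no ORF of >= min_orf_aa amino acids in any frame."""
    for _ in range(100):
        seq = _rand_seq(rng, length)
        if find_best_orf(TranscriptRecord(id="tmp", sequence=seq), min_orf_aa) is None:
            return seq
    raise RuntimeError("failed to draw a noncoding sequence")


def _isoform_lengths(rng: np.random.Generator, full_len: int, n: int, min_len: int) -> list[int]:
    """Distinct 3'-truncation lengths; index 0 is the full length."""
    lengths = [full_len]
    if n > 1:
        max_cut = max(1, full_len - min_len)
        step = max(30, max_cut // n)
        for k in range(1, n):
            lengths.append(max(min_len, full_len - k * step))
    # enforce distinctness (monotone decreasing by construction unless clipped)
    out = []
    prev = None
    for x in lengths:
        if prev is not None and x >= prev:
            x = prev - 1
        out.append(x)
        prev = x
    return out


def simulate_counts(
    truth: TruthTable,
    config: FixtureConfig,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Draw a replicate count matrix over the representative set.

    Baseline means are log-normal across transcripts; replicate counts are
    NB(mean, dispersion) draws.  Planted DE transcripts get ``de_fold`` times
    the baseline in the second group; planted specific transcripts are
    expressed only in their target group.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rep_ids = sorted(truth.expected_representatives)
    group_labels = [g for g, _ in config.groups]
    sample_labels: list[str] = []
    group_of_sample: dict[str, str] = {}
    for g, n_rep in config.groups:
        for r in range(1, n_rep + 1):
            label = f"{g}_rep{r}"
            sample_labels.append(label)
            group_of_sample[label] = g

    baseline = np.exp(rng.normal(np.log(80.0), 0.7, size=len(rep_ids)))
    mean_matrix = np.tile(baseline[:, None], (1, len(group_labels)))
    idx_of = {t: i for i, t in enumerate(rep_ids)}
    for tid, direction in truth.planted_de.items():
        gi = 1 if direction == "up" else 0
        mean_matrix[idx_of[tid], gi] *= config.de_fold
    for tid, group in truth.planted_specific.items():
        row = idx_of[tid]
        mean_matrix[row, :] = 0.0
        mean_matrix[row, group_labels.index(group)] = 300.0

    counts = np.zeros((len(rep_ids), len(sample_labels)))
    col = 0
    phi = config.nb_dispersion
    for gi, (_g, n_rep) in enumerate(config.groups):
        mu = mean_matrix[:, gi]
        for _ in range(n_rep):
            if phi > 0:
                r = 1.0 / phi
                p = r / (r + np.maximum(mu, 1e-12))
                draws = np.where(mu > 0, rng.negative_binomial(r, p), 0)
            else:
                draws = rng.poisson(mu)
            counts[:, col] = draws
            col += 1
    return CountMatrix(rep_ids, sample_labels, counts, group_of_sample)


def generate_fixture(config: FixtureConfig, outdir) -> tuple[dict[str, Path], TruthTable]:
    """Emit the complete fixture bundle into ``outdir`` and return its file
    paths plus the truth table."""
    config.validate()
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    pattern = load_pattern(default_pattern_path())
    motif = pattern_exemplar(pattern)
    truth = TruthTable()

    transcripts: list[TranscriptRecord] = []
    alignments: list[TranscriptAlignment] = []
    scaffold_parts: dict[str, list[str]] = {"scaffold1": [], "scaffold2": []}
    cursors = {"scaffold1": 0, "scaffold2": 0}

    # --- aligned loci -----------------------------------------------------
    for i in range(config.n_loci):
        category = _CATEGORY_CYCLE[i % len(_CATEGORY_CYCLE)]
        use_motif = i < config.n_motif_positives
        if use_motif:
            category = "complete"
        payload_aa = int(rng.integers(280, 420))
        locus_seq = _coding_sequence(rng, category, payload_aa, motif if use_motif else None)
        n_iso = int(rng.integers(config.isoforms_per_locus[0], config.isoforms_per_locus[1] + 1))
        # keep every truncation long enough to preserve a >= 120 aa ORF
        min_len = len(locus_seq) - 3 * max(0, payload_aa - 130)
        lengths = _isoform_lengths(rng, len(locus_seq), n_iso, min_len)

        scaffold = "scaffold1" if i % 2 == 0 else "scaffold2"
        strand = "+" if (i // 2) % 2 == 0 else "-"
        gap = config.locus_gap_bp + int(rng.integers(0, config.locus_gap_bp))
        locus_start = cursors[scaffold] + gap
        genome_insert = locus_seq if strand == "+" else _revcomp(locus_seq)
        scaffold_parts[scaffold].append(_rand_seq(rng, gap))
        scaffold_parts[scaffold].append(genome_insert)
        cursors[scaffold] = locus_start + len(locus_seq)

        locus_label = f"locus{i + 1:03d}"
        component = f"Pg_Root{100000 + i}_c0"
        rep_id = f"{component}_seq1"
        for k, tlen in enumerate(lengths, start=1):
            tid = f"{component}_seq{k}"
            seq = locus_seq[:tlen]
            transcripts.append(TranscriptRecord(id=tid, sequence=seq))
            if strand == "+":
                block = (locus_start, locus_start + tlen)
            else:
                block = (locus_start + len(locus_seq) - tlen, locus_start + len(locus_seq))
            alignments.append(
                TranscriptAlignment(
                    transcript_id=tid,
                    scaffold=scaffold,
                    strand=strand,
                    exon_blocks=(block,),
                    identity_pct=round(97.0 + 3.0 * rng.random(), 2),
                    coverage_pct=100.0,
                )
            )
            truth.locus_of_transcript[tid] = locus_label
        truth.expected_representatives.add(rep_id)
        truth.planted_category[rep_id] = category
        truth.rep_lengths[rep_id] = lengths[0]
        if use_motif:
            truth.planted_motif.add(rep_id)

    # --- unaligned components --------------------------------------------
    for i in range(config.n_unaligned_components):
        payload_aa = int(rng.integers(280, 420))
        seq = _coding_sequence(rng, "complete", payload_aa)
        n_iso = int(rng.integers(config.isoforms_per_unaligned[0], config.isoforms_per_unaligned[1] + 1))
        min_len = len(seq) - 3 * max(0, payload_aa - 130)
        lengths = _isoform_lengths(rng, len(seq), n_iso, min_len)
        component = f"Pg_Root{200000 + i}_c0"
        rep_id = f"{component}_seq1"
        for k, tlen in enumerate(lengths, start=1):
            tid = f"{component}_seq{k}"
            transcripts.append(TranscriptRecord(id=tid, sequence=seq[:tlen]))
            truth.locus_of_transcript[tid] = f"unaligned{i + 1:03d}"
        truth.expected_representatives.add(rep_id)
        truth.planted_category[rep_id] = "complete"
        truth.rep_lengths[rep_id] = lengths[0]

    # --- decoys -----------------------------------------------------------
    contaminant_hits: list[HitRecord] = []
    rrna_predictions: list[RrnaPrediction] = []
    for i in range(config.n_contaminants):
        tid = f"Pg_Root{300000 + i}_c0_seq1"
        seq = _rand_seq(rng, int(rng.integers(400, 800)))
        transcripts.append(TranscriptRecord(id=tid, sequence=seq))
        truth.decoys[tid] = "contaminant"
        contaminant_hits.append(
            HitRecord(tid, f"microbe{i + 1}", 99.0, int(0.9 * len(seq)), 1e-80, 500.0)
        )
    for i in range(config.n_rrna):
        tid = f"Pg_Root{400000 + i}_c0_seq1"
        seq = _rand_seq(rng, int(rng.integers(1000, 1600)))
        transcripts.append(TranscriptRecord(id=tid, sequence=seq))
        truth.decoys[tid] = "rrna"
        rrna_predictions.append(RrnaPrediction(tid, 0, int(0.9 * len(seq)), 1500.0))
    for i in range(config.n_lncrna):
        tid = f"Pg_Root{500000 + i}_c0_seq1"
        transcripts.append(TranscriptRecord(id=tid, sequence=_noncoding_sequence(rng, 600)))
        truth.decoys[tid] = "lncrna"

    # --- planted expression structure ------------------------------------
    rep_ids = sorted(truth.expected_representatives)
    group_labels = [g for g, _ in config.groups]
    n_spec = int(round(config.specific_fraction * len(rep_ids)))
    n_de = int(round(config.de_fraction * len(rep_ids)))
    shuffled = list(rep_ids)
    rng.shuffle(shuffled)
    for j, tid in enumerate(shuffled[:n_spec]):
        truth.planted_specific[tid] = group_labels[j % len(group_labels)]
    for tid in shuffled[n_spec : n_spec + n_de]:
        truth.planted_de[tid] = "up"

    counts = simulate_counts(truth, config, np.random.default_rng(config.seed + 1))

    # --- KO assignments ---------------------------------------------------
    definition = load_pathway_definition(default_pathway_path())
    labels = list(definition)
    copy_plan = [2] * 6 + [3] * 2 + [4] * 2 + [1] * max(0, len(labels) - 10)
    available = [t for t in rep_ids if t not in truth.planted_specific]
    pos = 0
    for label, n_copies in zip(labels, copy_plan):
        ko = definition[label][0]
        truth.enzyme_of_ko[ko] = label
        for _ in range(n_copies):
            if pos >= len(available):
                break
            truth.ko_of_transcript[available[pos]] = ko
            pos += 1

    # --- emit files -------------------------------------------------------
    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    genome_records = [
        TranscriptRecord(id=scf, sequence="".join(parts) + _rand_seq(rng, 200))
        for scf, parts in scaffold_parts.items()
        if parts
    ]
    write_fasta(genome_records, p("genome.fa"))
    write_fasta(transcripts, p("transcripts.fa"))
    write_alignments_gff3(alignments, p("alignments.gff3"))
    write_hits_table(contaminant_hits, p("contaminant_hits.tsv"))
    write_rrna_gff(rrna_predictions, p("rrna.gff"))
    write_hits_table([], p("protein_hits.tsv"))
    write_count_matrix(counts, p("counts.tsv"))
    with open(p("groups.tsv"), "w") as fh:
        fh.write("sample\tgroup\n")
        for s in counts.sample_labels:
            fh.write(f"{s}\t{counts.group_of_sample[s]}\n")
    with open(p("ko.tsv"), "w") as fh:
        fh.write("transcript_id\tko\tpathway\n")
        for tid in sorted(truth.ko_of_transcript):
            ko = truth.ko_of_transcript[tid]
            fh.write(f"{tid}\t{ko}\tginsenoside_backbone\n")
    with open(p("pspg.pattern"), "w") as fh:
        fh.write(pattern.raw + "\n")

    truth_dir = outdir / "truth"
    _write_map(truth_dir / "locus_of_transcript.tsv", "transcript_id\tlocus", truth.locus_of_transcript)
    _write_set(truth_dir / "representatives.tsv", "transcript_id", truth.expected_representatives)
    _write_map(truth_dir / "de.tsv", "transcript_id\tdirection", truth.planted_de)
    _write_map(truth_dir / "specific.tsv", "transcript_id\tgroup", truth.planted_specific)
    _write_set(truth_dir / "motif.tsv", "transcript_id", truth.planted_motif)
    _write_map(truth_dir / "category.tsv", "transcript_id\tcategory", truth.planted_category)
    _write_map(truth_dir / "decoys.tsv", "transcript_id\tstage", truth.decoys)
    paths["truth"] = truth_dir
    return paths, truth


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _write_map(path: Path, header: str, mapping: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for k in sorted(mapping):
            fh.write(f"{k}\t{mapping[k]}\n")


def _write_set(path: Path, header: str, items: set[str]) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for k in sorted(items):
            fh.write(f"{k}\n")
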