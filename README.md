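# unigene

A toolkit for building a non-redundant ("Nr") unigene set from a de novo
transcriptome assembly with the help of a draft genome, and for the standard
downstream root-transcriptome analyses:

- **Cleanup cascade** — removal of contaminant transcripts (from homology
  evidence tables), rRNA transcripts (from prediction tables) and
  long-noncoding transcripts (no long ORF and no protein homology), with a
  first-stage-attribution accounting report.
- **Locus collapsing** — single-linkage clustering of genome-aligned
  transcripts into gene loci (strand-aware by default), longest-member
  representative selection, component-based collapsing of unaligned
  transcripts, and assembly statistics (count / max / mean / N50).
- **ORF annotation** — six-frame ORF discovery with completeness
  classification (complete, 5′-partial, 3′-partial, internal) at a
  configurable minimum peptide length (default 100 aa).
- **Expression** — FPKM from fragment count matrices, a self-contained
  exact negative-binomial test with Benjamini–Hochberg FDR (DE rule:
  FDR ≤ 0.01 and fold change ≥ 2), tissue-specificity calling
  (group-mean FPKM > 3 in one group and < 1 in all others), top-abundance
  ranking and log-scale Pearson co-expression.
- **Motifs & pathways** — a PROSITE-syntax pattern engine for PSPG-motif
  UGT candidate discovery, and KO-table-driven pathway gene grouping with
  copy-number counts.
- **Synthetic fixtures** — a deterministic generator of a complete toy
  study (genome, multi-isoform transcripts, decoys, alignments, counts with
  planted DE/specific/motif structure) plus machine-readable truth tables.

## CLI

Every stage is a subcommand of `unigene`; all inputs and outputs are plain
text (FASTA, GFF3, TSV, YAML).

```bash
# generate a toy study with known truth
unigene simulate --seed 42 --outdir fixture/

# cleanup cascade
unigene filter --transcripts fixture/transcripts.fa \
    --contaminant-hits fixture/contaminant_hits.tsv \
    --rrna fixture/rrna.gff --protein-hits fixture/protein_hits.tsv \
    --out filtered.fa --report report.tsv

# non-redundant unigene set
unigene collapse --transcripts filtered.fa --alignments fixture/alignments.gff3 \
    --min-identity 95 --out nr.fa --clusters clusters.tsv --stats stats.tsv

# ORFs, quantification, DE, specificity
unigene orf --transcripts nr.fa --min-aa 100 --out orfs.tsv --peptides peps.fa
unigene quantify --counts fixture/counts.tsv --lengths nr.fa \
    --groups fixture/groups.tsv --out fpkm.tsv
unigene de --counts fixture/counts.tsv --lengths nr.fa --groups fixture/groups.tsv \
    --a whole_root --b rhizome --fdr 0.01 --fc 2 --out de.tsv
unigene specific --counts fixture/counts.tsv --lengths nr.fa \
    --groups fixture/groups.tsv --hi 3 --lo 1 --out specific.tsv

# UGT candidates and pathway grouping
unigene scan-ugt --transcripts nr.fa --pattern fixture/pspg.pattern --out ugt.tsv
unigene pathway --ko fixture/ko.tsv --out pathway_groups.tsv
```

The PSPG pattern (PROSITE entry PS00375) and the pathway enzyme→KO
definition ship as editable data files under `src/unigene/data/`; verify the
pattern against the current PROSITE release before production use.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes per-module unit tests, hypothesis property tests, and
`tests/test_acceptance.py`, which checks each operation against an
independent brute-force oracle (pairwise union-find for locus clustering,
exhaustive six-frame enumeration for ORFs, literal step-up for BH, a regex
translation for PROSITE scanning, …) and verifies planted-truth recovery on
synthetic fixtures (100% of planted specific/motif transcripts, ≥ 90%
power on planted 10-fold expression changes at FDR ≤ 0.01 with three
replicates, exact representative recovery for 20 planted loci plus 5
unaligned components).

## Notes on scope and simplifications

- Running external tools (assembler, aligner, rRNA predictor, homology
  search, abundance estimator) is out of scope; their outputs are consumed
  as tabular/GFF3 evidence files.
- The DE engine is an exact conditional negative-binomial test with a
  method-of-moments common dispersion, not the empirical-Bayes machinery of
  the usual Bioconductor tooling. Library sizes are equalised by scaling to
  the geometric-mean total count; this plain total-count scaling is subject
  to composition bias when a large fraction of transcripts change.
- The noncoding filter is a stated stand-in rule (no ORF ≥ 100 aa and no
  protein hit at e ≤ 1e-5), not a re-implementation of any published
  coding-potential classifier.
- FPKM uses transcript length as effective length (no fragment-length
  correction).
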