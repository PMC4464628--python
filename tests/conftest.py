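from __future__ import annotations

import numpy as np
import pytest

from unigene.io import CountMatrix, read_alignments_gff3, read_fasta, read_hits_table
from unigene.filtering import read_rrna_gff
from unigene.simulate import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Default synthetic study bundle (paths, truth, config)."""
    outdir = tmp_path_factory.mktemp("fixture")
    config = FixtureConfig(seed=20150612)
    paths, truth = generate_fixture(config, outdir)
    return paths, truth, config


@pytest.fixture(scope="session")
def fixture_inputs(fixture_bundle):
    """Parsed fixture inputs ready for the pipeline."""
    paths, truth, config = fixture_bundle
    return {
        "transcripts": read_fasta(paths["transcripts.fa"]),
        "alignments": read_alignments_gff3(paths["alignments.gff3"], 95.0, 90.0)[0],
        "contaminant_hits": read_hits_table(paths["contaminant_hits.tsv"]),
        "rrna_predictions": read_rrna_gff(paths["rrna.gff"]),
        "protein_hits": read_hits_table(paths["protein_hits.tsv"]),
        "truth": truth,
        "config": config,
        "paths": paths,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_count_matrix(counts, groups_per_sample=None, prefix="t"):
    """Small helper constructing a CountMatrix from a dense array."""
    counts = np.asarray(counts, dtype=float)
    n_t, n_s = counts.shape
    ids = [f"{prefix}{i + 1}" for i in range(n_t)]
    samples = [f"s{j + 1}" for j in range(n_s)]
    if groups_per_sample is None:
        groups_per_sample = ["g1"] * n_s
    groups = dict(zip(samples, groups_per_sample))
    return CountMatrix(ids, samples, counts, groups)
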