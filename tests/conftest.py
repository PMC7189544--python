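"""Shared fixtures: one small synthetic study reused across test modules."""

import pytest

from eremap.eremap_validation import call_eremaps
from eremap.proteogenomics import (
    build_ere_proteome,
    build_personalized_proteome,
    concat_proteomes,
    filter_alignments,
    partition_reads,
)
from eremap.synthetic_data import make_blcl_readset, make_genome, make_tissue_panel


@pytest.fixture(scope="session")
def genome_bundle():
    return make_genome(seed=11)


@pytest.fixture(scope="session")
def readset(genome_bundle):
    """Small planted read set (4000 pairs) shared by validation tests."""
    return make_blcl_readset(genome_bundle, depth=4000, seed=11)


@pytest.fixture(scope="session")
def pipeline_run(readset):
    """Full cascade output on the shared read set."""
    b = readset
    part = partition_reads(
        filter_alignments(b.reads), b.genome.repeats, b.genome.genes
    )
    proteome = concat_proteomes(
        build_ere_proteome(part),
        build_personalized_proteome(
            b.transcripts, None, b.transcript_expression,
            sample=b.truth.sample, cds_start=b.cds_start,
        ),
    )
    records, audited = call_eremaps(
        b.candidates, part, proteome, b.genome.repeats,
        b.genome.genes, b.genome.sequences,
    )
    return {
        "bundle": b,
        "partition": part,
        "proteome": proteome,
        "records": records,
        "audited": audited,
    }


@pytest.fixture(scope="session")
def tissue_panel():
    return make_tissue_panel(seed=7)
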