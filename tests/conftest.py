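"""Shared fixtures: tiny in-memory alignment builders and synthetic corpora."""

from __future__ import annotations

import pytest

from svrec.formats import AlignmentRecord
from svrec.synthdata import CorpusConfig, simulate_corpus


def make_record(
    read_id: str = "r1",
    chrom: str = "chr1",
    pos: int = 1000,
    cigar: tuple[tuple[int, int], ...] = ((0, 1000),),
    mapq: int = 60,
) -> AlignmentRecord:
    """Build a mapped record whose read length follows from the CIGAR."""
    from svrec.formats import QUERY_OPS

    read_length = sum(n for op, n in cigar if op in QUERY_OPS)
    return AlignmentRecord(
        read_id=read_id,
        chrom=chrom,
        pos=pos,
        cigar=cigar,
        read_length=read_length,
        mapq=mapq,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A small noisy corpus for fast model tests."""
    return simulate_corpus(CorpusConfig(n_datasets=40, noise_sd=0.05, seed=7))


@pytest.fixture(scope="session")
def noiseless_corpus():
    """A perfectly separable corpus: meta-target equals the rule label."""
    return simulate_corpus(CorpusConfig(n_datasets=60, noise_sd=0.0, seed=11))
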