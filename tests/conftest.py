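import numpy as np
import pytest

from isochrom.io import GenomicInterval, TranscriptModel
from isochrom.simulate import SimulationConfig


def make_transcript(gene, tid, strand, exons, principal=False, chrom="chr1"):
    return TranscriptModel(
        gene_id=gene,
        transcript_id=tid,
        strand=strand,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        principal=principal,
    )


@pytest.fixture
def se_pair():
    """Cassette-exon pair: identical transcripts except one internal exon."""
    t1 = make_transcript("g1", "t1", "+", [(0, 150), (450, 600), (900, 1050)], True)
    t2 = make_transcript("g1", "t2", "+", [(0, 150), (900, 1050)])
    return [t1, t2]


@pytest.fixture
def small_config():
    return SimulationConfig(n_genes=50, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
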