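import numpy as np
import pytest

from dgrna.genome_io import GeneModel, GenomeAssembly, GenomicInterval, Transcript
from dgrna.fixtures import random_sequence


def make_gene(gene_id, chrom, strand, chains, tids=None):
    """Gene model from [[(start, end), ...], ...] CDS chains."""
    transcripts = []
    for i, chain in enumerate(chains):
        tid = tids[i] if tids else f"{gene_id}.t{i + 1}"
        segs = tuple(
            GenomicInterval(chrom, s, e, strand) for s, e in sorted(chain)
        )
        transcripts.append(Transcript(tid, segs))
    return GeneModel(gene_id, chrom, strand, tuple(transcripts))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_assembly(rng):
    return GenomeAssembly({"chrR": random_sequence(rng, 20000, 0.45)})
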