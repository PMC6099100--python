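import numpy as np
import pytest
from hypothesis import settings

from coreskew.genome_model import AnnotatedGenome, GeneFeature

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_genome(sequence, features=(), label="toy"):
    return AnnotatedGenome(organism_label=label, sequence=sequence, features=list(features))


def cds(gene_id, start, end, strand=+1, product="protein"):
    return GeneFeature(gene_id, start, end, strand, "CDS", product)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    """60 bp genome with 3 CDS (one reverse), 1 rRNA, 1 tRNA."""
    seq = "ATGAAATAA" + "T" * 3 + "TTACATCAT" + "C" * 3 + "ATGGCCTAA" + "ACGT" * 6 + "AAA"
    feats = [
        cds("g1", 0, 9, +1, "protein A"),
        cds("g2", 12, 21, -1, "protein B"),
        cds("g3", 24, 33, +1, "protein C"),
        GeneFeature("r1", 33, 45, +1, "rRNA", "16S ribosomal RNA"),
        GeneFeature("t1", 45, 57, +1, "tRNA", "tRNA-Ala"),
    ]
    return make_genome(seq, feats)
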