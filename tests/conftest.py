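import numpy as np
import pytest

from circverify.annotation import Exon, GeneAnnotation, GenomeSequence, Transcript
from circverify.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(123)
    seq = "".join(rng.choice(list("ACGT"), size=700))
    return GenomeSequence([("chr1", seq)])


@pytest.fixture(scope="session")
def toy_annotation():
    """One 3-exon transcript: exons [100,200), [300,400), [500,600)."""
    exons = [
        Exon("chr1", 100, 200, "+"),
        Exon("chr1", 300, 400, "+"),
        Exon("chr1", 500, 600, "+"),
    ]
    return GeneAnnotation([Transcript("tx1", "gene1", exons)])


MIXED_PROFILE = {
    "correct": 0.6,
    "exon_skip": 0.15,
    "truncation": 0.1,
    "intron_retention": 0.1,
    "false_bsj": 0.05,
}


@pytest.fixture(scope="session")
def mixed_fixture():
    """20 genes / 60 circRNAs / error-free reads / mixed corruption."""
    config = SimConfig(
        seed=7,
        n_genes=20,
        n_circ=60,
        n_reads=400,
        genome_length=250_000,
        corruption_profile=dict(MIXED_PROFILE),
    )
    return simulate_all(config)


@pytest.fixture(scope="session")
def truth_labels(mixed_fixture):
    return {c.candidate_id: c.truth_label for c in mixed_fixture.candidates}
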