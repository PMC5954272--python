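import dataclasses

import numpy as np
import pytest

import orcel


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic study: 200 genes, 50 miRNAs, 20 planted sponges at
    8x seed density, 10 planted loops, seed 42."""
    return orcel.simulate(orcel.SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return orcel.run_pipeline(default_bundle)


@pytest.fixture(scope="session")
def null_bundle():
    """Same study with nothing planted; decoy target edges only."""
    cfg = dataclasses.replace(
        orcel.SimConfig(seed=42), n_planted_sponges=0, n_planted_loops=0
    )
    return orcel.simulate(cfg)


@pytest.fixture(scope="session")
def null_result(null_bundle):
    return orcel.run_pipeline(null_bundle, score_all_isoforms=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_genome(length=2000, seed=7, chrom="chr1"):
    r = np.random.default_rng(seed)
    return {chrom: "".join(np.array(list("ACGT"))[r.integers(0, 4, size=length)])}


@pytest.fixture()
def toy_genome():
    return make_genome()


@pytest.fixture()
def five_exon_gene():
    """One '+' strand gene with five 100-nt exons at round coordinates."""
    tx = orcel.TranscriptModel(
        "TXA.1", "chr1", "+",
        ((100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)),
    )
    return orcel.GeneModel("GENEA", [tx])
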