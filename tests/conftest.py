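import numpy as np
import pytest

from mirbind.features.registry import FeatureRegistry, RegistryConfig
from mirbind.simulate import CorpusConfig, generate_corpus
from mirbind.types import MiRNA, TranscriptUTR


@pytest.fixture(scope="session")
def mirna():
    # seed (positions 2-8) is GGAAUGU; 6mer core revcomp ACAUUC + C
    return MiRNA("hsa-miR-x", "UGGAAUGUAAAGAAGUAUGUAU")


@pytest.fixture()
def utr_8mer():
    return TranscriptUTR("ENST00000000001", "GGACAUUCCAGG", gene_id="GENE1")


@pytest.fixture(scope="session")
def registry():
    return FeatureRegistry(RegistryConfig())


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(
        CorpusConfig(n_mirnas=3, n_transcripts=25, seed=7,
                     max_unaffected_per_mirna=15)
    )


def random_mirna(rng: np.random.Generator, length: int = 22) -> MiRNA:
    seq = "".join(rng.choice(list("ACGU"), size=length))
    return MiRNA(f"rand-miR-{rng.integers(1 << 30)}", seq)


def random_utr(rng: np.random.Generator, length: int) -> TranscriptUTR:
    seq = "".join(rng.choice(list("ACGU"), size=length))
    return TranscriptUTR(f"ENSTR{rng.integers(1 << 30)}", seq)
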