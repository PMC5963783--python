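import numpy as np
import pytest

from legoscreen import Config, Transcript


@pytest.fixture
def config() -> Config:
    return Config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_transcript(rng: np.random.Generator, length: int, tid: str = "t", gene: str = "g") -> Transcript:
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return Transcript(id=tid, gene_label=gene, seq=seq)
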