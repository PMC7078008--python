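import numpy as np
import pytest

from aminoscore.types import AA_ALPHABET, Chain, SequenceRecord


def random_record(rng: np.random.Generator, record_id: str = "rnd",
                  max_chains: int = 3, max_len: int = 30) -> SequenceRecord:
    """Uniformly random record: 1..max_chains chains of 1..max_len residues."""
    n_chains = int(rng.integers(1, max_chains + 1))
    chains = []
    for _ in range(n_chains):
        length = int(rng.integers(1, max_len + 1))
        seq = "".join(rng.choice(list(AA_ALPHABET), size=length))
        ss = "".join(rng.choice(list("HEC"), size=length))
        chains.append(Chain(seq, ss))
    return SequenceRecord(record_id, chains)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
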