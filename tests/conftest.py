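import numpy as np
import pytest

from guarmir.descriptors import load_mature_table
from guarmir.seqio import SequenceRecord


@pytest.fixture(scope="session")
def reference_matures() -> list[SequenceRecord]:
    """A dozen real mature miRNA references from the packaged table."""
    pairs = load_mature_table()[:12]
    return [
        SequenceRecord(id=p.homolog_id, seq=p.known_mature,
                       alphabet_hint="rna")
        for p in pairs
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_seq(rng: np.random.Generator, n: int,
               alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))
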