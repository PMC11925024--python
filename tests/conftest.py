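import numpy as np
import pytest

from kmerpop.counting import KmerCountTable


def make_table(counts: dict[str, int], k: int | None = None,
               canonical: bool = True) -> KmerCountTable:
    return KmerCountTable.from_dict(counts, k=k, canonical=canonical)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
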