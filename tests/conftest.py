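import numpy as np
import pytest

from teloend import ReadRecord


@pytest.fixture
def make_read():
    def _make(sequence, read_id="read", quality=40):
        return ReadRecord(read_id, sequence, [quality] * len(sequence))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), size=length)])
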