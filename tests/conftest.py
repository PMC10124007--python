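import numpy as np
import pytest

from gtdiscord.encoding import VALID_BYTES

CODE_ALPHABET = np.array(sorted(VALID_BYTES), dtype=np.uint8)  # NUL + 10 IUPAC


def random_genotype_string(rng: np.random.Generator, length: int, missing_rate: float) -> bytes:
    """Random byte string over the full genotype alphabet with the given
    missingness."""
    called = rng.choice(CODE_ALPHABET[1:], size=length)
    miss = rng.random(length) < missing_rate
    called[miss] = 0
    return called.tobytes()


@pytest.fixture
def rng():
    return np.random.default_rng(20230424)


@pytest.fixture(scope="session")
def session_rng():
    return np.random.default_rng(424242)
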