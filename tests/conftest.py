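import numpy as np
import pytest

from nucbind import synthetic_data as sd

BASE_P_42GC = [0.29, 0.21, 0.21, 0.29]  # A, C, G, T at 42% GC
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng, length, p=BASE_P_42GC) -> str:
    return BASES[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


@pytest.fixture(scope="session")
def default_truth():
    """One default-scale synthetic dataset shared across the session.

    ~20,000 planted split-8-mer occurrences with binding labels drawn from
    the known logistic model; regenerating it per test would dominate the
    suite's runtime.
    """
    return sd.make_fixture(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
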