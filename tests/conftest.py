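import pytest

from sdmm import compute_timeline
from sdmm.fixtures import (
    CaseSpec,
    generate_random_case,
    load_fixture_ba,
    load_fixture_record,
)


@pytest.fixture(scope="session")
def ba():
    return load_fixture_ba()


@pytest.fixture(scope="session")
def p1():
    return load_fixture_record("P1")


@pytest.fixture(scope="session")
def p2():
    return load_fixture_record("P2")


@pytest.fixture(scope="session")
def timeline_p1(ba, p1):
    return compute_timeline(ba, p1)


@pytest.fixture(scope="session")
def timeline_p2(ba, p2):
    return compute_timeline(ba, p2)


def random_cases(ba, n, n_surgeries=None, seed0=0):
    """Deterministic stream of generated records for property tests."""
    for seed in range(seed0, seed0 + n):
        k = n_surgeries if n_surgeries is not None else 1 + seed % 10
        yield generate_random_case(CaseSpec(seed=seed, n_surgeries=k), ba)
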