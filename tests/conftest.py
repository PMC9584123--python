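import pytest

import seedmap as sm


@pytest.fixture(scope="session")
def toy_refs() -> sm.ReferenceSet:
    """Two tiny handmade references."""
    return sm.ReferenceSet((
        ("chr1", "ACGTACGTACGTAGGCTTACGGATCCTAGGCA"),
        ("chr2", "TTTTGGGGCCCCAAAATTGACGTACGGTTACG"),
    ))


@pytest.fixture(scope="session")
def small_genome() -> sm.ReferenceSet:
    """A 10 kb random genome used across mapper tests."""
    return sm.simulate_genome(10_000, seed=1234)


@pytest.fixture(scope="session")
def small_index(small_genome) -> sm.SeedIndex:
    return sm.build_index(small_genome, 10)
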