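import numpy as np
import pytest

from lexinet import (
    CognateDatabase,
    CognateRecord,
    build_presence_absence,
    hamming_distance,
    worked_example_database,
)


@pytest.fixture
def tiny_db() -> CognateDatabase:
    """Three records, two cogsets, one character."""
    return CognateDatabase(
        [
            CognateRecord("L1", "meaning1", "c1", "foo"),
            CognateRecord("L2", "meaning1", "c1", "fu"),
            CognateRecord("L3", "meaning1", "c2", "bar"),
        ]
    )


@pytest.fixture(scope="session")
def worked_db() -> CognateDatabase:
    return worked_example_database()


@pytest.fixture(scope="session")
def worked_dm():
    return hamming_distance(build_presence_absence(worked_example_database()))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
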