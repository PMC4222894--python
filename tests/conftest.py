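import pytest

from hamdex import (
    DEFAULT_OFFSET,
    SampleSheet,
    build_quaternary_code,
    default_index_set,
    design_indices,
)


@pytest.fixture(scope="session")
def codebook():
    return build_quaternary_code()


@pytest.fixture(scope="session")
def index120(codebook):
    """The shipped design: offset W=(1,2,2,3,3,0,0,0), default map."""
    return design_indices(codebook, DEFAULT_OFFSET)


@pytest.fixture(scope="session")
def index96():
    return default_index_set(96)


@pytest.fixture(scope="session")
def small_sheet(index96):
    """Four samples on distinct (i7, i5) pairs from the working set."""
    idx = index96.indices
    return SampleSheet(
        samples=tuple(
            (f"sample_{k}", idx[k], idx[k + 4]) for k in range(4)
        )
    )
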