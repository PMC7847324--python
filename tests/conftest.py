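import pytest

from revsort import distance_table, packaged_fixture


@pytest.fixture(scope="session")
def tables():
    """Exact distance tables for small n, shared across the session."""
    cache = {}

    def get(n):
        if n not in cache:
            cache[n] = distance_table(n)
        return cache[n]

    return get


@pytest.fixture(scope="session")
def mouse_order():
    return packaged_fixture("mouse_193")


@pytest.fixture(scope="session")
def human_order():
    return packaged_fixture("human_193")

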