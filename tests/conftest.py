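import pytest

from semantic_units.fixtures import (
    FixtureSpec,
    apple_example,
    generate_store,
    publication_example,
)
from semantic_units.compound import compound_all


def unit_key(unit):
    """(class, data-graph triple set) — identity of a statement unit across
    independently built stores."""
    return (unit.unit_class, unit.data_graph.as_set())


@pytest.fixture(scope="session")
def apple():
    return apple_example()


@pytest.fixture(scope="session")
def publication():
    return publication_example()


@pytest.fixture(scope="session")
def small_random():
    store, truth, report = generate_store(FixtureSpec(seed=11))
    summary = compound_all(store)
    return store, truth, report, summary
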