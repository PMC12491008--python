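import pytest

import omega3diet as od


@pytest.fixture(scope="session")
def bundled():
    """All five bundled composition tables, loaded once."""
    return od.load_all_bundled()


@pytest.fixture(scope="session")
def all_records(bundled):
    return [r for t in bundled.values() for r in t]


@pytest.fixture(scope="session")
def scored_all(all_records):
    return od.score_table(all_records)


@pytest.fixture(scope="session")
def by_id(scored_all):
    return {c.food_id: c for c in scored_all}
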