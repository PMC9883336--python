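import pytest

import fufatag


@pytest.fixture(scope="session")
def blocks():
    return fufatag.default_building_blocks()


@pytest.fixture(scope="session")
def core_blocks():
    return fufatag.core_building_blocks()


@pytest.fixture(scope="session")
def screening_db(blocks):
    """Default annotation database: one- and two-FuFA TAGs over the full set."""
    return fufatag.enumerate_candidates(blocks, (1, 2))


@pytest.fixture(scope="session")
def mushroom_fixture():
    return fufatag.mushroom_fixture()
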