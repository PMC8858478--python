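import pytest

from triage_eval import load_fixture


@pytest.fixture(scope="session")
def table4():
    """Bundled 12-profile mortality table."""
    return load_fixture("table4")


@pytest.fixture(scope="session")
def mortality(table4):
    return list(table4.outcomes)
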