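import pytest

from barcodegap.simulate import fixture_library


@pytest.fixture(scope="session")
def fixtures():
    """The deterministic miniature data sets shared across suites."""
    return fixture_library()
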