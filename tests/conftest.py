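import pytest
from hypothesis import settings

from pdcba import load_bundled

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def korea():
    """Korea societal-perspective set, published inputs verbatim."""
    return load_bundled("korea")


@pytest.fixture(scope="session")
def korea_unrounded():
    """Korea set with precision-restored AI cost and specificity."""
    return load_bundled("korea_unrounded")


@pytest.fixture(scope="session")
def usa():
    """U.S. healthcare-system-perspective set (direct medical costs only)."""
    return load_bundled("usa")
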