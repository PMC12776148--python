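import pytest

from mwcheck.synthetic import FixtureSpec, generate_valid


@pytest.fixture(scope="session")
def ms_fixture():
    """A clean mass-spec analysis: (document, mwTab text, JSON text)."""
    return generate_valid(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def nm_fixture():
    """A clean NMR analysis."""
    return generate_valid(FixtureSpec(seed=2, analytical_mode="NM"))


@pytest.fixture(scope="session")
def ext_fixture():
    """A clean analysis carrying an EXTENDED data table."""
    return generate_valid(FixtureSpec(seed=3, include_extended=True))
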