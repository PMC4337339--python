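import pytest

from biofilmdge.synthetic import simulate_biofilm_scenario


@pytest.fixture(scope="session")
def scenario():
    """One staged-biofilm scenario shared by read-only tests."""
    return simulate_biofilm_scenario(seed=1)
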