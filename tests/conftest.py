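import pytest

from mirmark.simulate import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def panel():
    """One deterministic synthetic panel shared by read-only tests."""
    return simulate_panel(SimConfig(seed=11))
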