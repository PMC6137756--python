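import pytest

from gridprod import build_toy_network, toy_medium


@pytest.fixture
def toy():
    """Fresh copy of the 8-reaction toy network."""
    return build_toy_network()


@pytest.fixture
def toy_med():
    return toy_medium()
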