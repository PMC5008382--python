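import pytest

from isomirev.isomir import AlignPolicy
from isomirev.simulate import make_toy_reference


@pytest.fixture(scope="session")
def toy_ref():
    """The three panel-like fixture hairpins only (no decoys)."""
    return make_toy_reference(seed=1, n_mirnas=3)


@pytest.fixture(scope="session")
def policy():
    return AlignPolicy()
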