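import pytest

from sh3prm import synthetic


@pytest.fixture(scope="session")
def screen_fixture():
    """Planted 50-protein proteome with full screening inputs (seed 7)."""
    return synthetic.gen_screen_fixture(seed=7)


@pytest.fixture()
def ppii_register():
    """Register for the GAPAKPARGG demo peptide: P0 at index 3."""
    return {k: 3 + k for k in range(-2, 6)}
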