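import pytest

from h4screen import compute_descriptors
from h4screen.synthsets import fixtures


@pytest.fixture(scope="session")
def fixture_mols():
    """Hard-coded structure fixtures with descriptors computed once."""
    return {name: compute_descriptors(m) for name, m in fixtures().items()}
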