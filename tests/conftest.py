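import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from protondl.dataset import generate_case


@pytest.fixture(scope="session")
def tiny_case():
    """One synthetic case on the default grid, shared across tests."""
    rng = np.random.default_rng(42)
    return generate_case("prostate_like", "tiny_000", rng)
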