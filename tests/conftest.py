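import numpy as np
import pytest

from ringmea.core import CircuitLayout
from ringmea.io import default_layout


@pytest.fixture(scope="session")
def layout() -> CircuitLayout:
    """The packaged 60-electrode, 15-circuit layout."""
    return default_layout()


@pytest.fixture
def one_circuit() -> CircuitLayout:
    """A single ring: electrodes 1..4 at positions 1..4."""
    return CircuitLayout({1: {1: 1, 2: 2, 3: 3, 4: 4}})


def make_layout(n_circuits: int) -> CircuitLayout:
    """n ring circuits with consecutive electrode ids."""
    return CircuitLayout({
        c: {p: (c - 1) * 4 + p for p in (1, 2, 3, 4)} for c in range(1, n_circuits + 1)
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
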