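import numpy as np
import pytest

from metabdiff.protocol import DiffusionProtocol


@pytest.fixture(scope="session")
def protocol() -> DiffusionProtocol:
    return DiffusionProtocol()


@pytest.fixture(scope="session")
def b_values(protocol) -> np.ndarray:
    return protocol.b_array()
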