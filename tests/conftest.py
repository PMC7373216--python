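import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from circuniform import pigeon_sample


@pytest.fixture
def pigeon():
    return pigeon_sample()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
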