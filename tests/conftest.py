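import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from parabind import synthetic


@pytest.fixture(scope="session")
def f_promoter():
    """The default synthetic F-architecture promoter and its truth table."""
    arch = synthetic.default_f_architecture()
    seq, truth = synthetic.build_promoter_sequence(arch, seed=11)
    return arch, seq, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
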