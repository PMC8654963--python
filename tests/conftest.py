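import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, length, p_g=0.25):
    bases = np.array(list("ACGT"))
    p = np.array([(1 - p_g) / 3] * 4)
    p[2] = p_g
    p = p / p.sum()
    return "".join(rng.choice(bases, size=length, p=p))
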