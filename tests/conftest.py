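import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cistress import PromoterRegion


@pytest.fixture
def make_promoter():
    def _make(seq: str, gene_id: str = "g") -> PromoterRegion:
        return PromoterRegion.from_sequence(gene_id, seq)
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20221130)


def random_seq(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
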