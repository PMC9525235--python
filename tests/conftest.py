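import numpy as np
import pytest

from neuropep.masschem import Peptidoform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pep():
    def make(seq, **kw):
        return Peptidoform(sequence=seq, **kw)

    return make
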