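import numpy as np
import pytest

from songcircuit import song as sg
from songcircuit.synth.song import default_motif, synthesize_motif


@pytest.fixture(scope="session")
def motif_spec():
    return default_motif()


@pytest.fixture(scope="session")
def template(motif_spec):
    audio, _ = synthesize_motif(motif_spec, seed=0)
    return sg.MotifTemplate(audio=audio)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
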