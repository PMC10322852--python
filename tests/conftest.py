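import pytest

from cryoslice import OpticalParams

# parameter triples in the range practitioners report for cryo-imaging:
# dim quantum-dot-labelled stem cells and bright red / dimmer green microspheres
STEM = OpticalParams(cell_intensity=38, attenuation=314, threshold=10)
GREEN = OpticalParams(cell_intensity=87, attenuation=372, threshold=10)
RED = OpticalParams(cell_intensity=300, attenuation=332, threshold=10)


@pytest.fixture
def stem_params():
    return STEM


@pytest.fixture
def green_params():
    return GREEN


@pytest.fixture
def red_params():
    return RED
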