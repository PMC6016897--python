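import pytest

from valvegeom import make_cusp

# reference human pulmonary valve instance: width 20.211 mm, max height
# 14.20 mm, three symmetric cusps (each one third of the cylinder)
REF_WIDTH = 20.211
REF_HEIGHT = 14.20
REF_N_CUSPS = 3


@pytest.fixture
def reference_cusp():
    return make_cusp(REF_WIDTH, REF_HEIGHT, REF_N_CUSPS)
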