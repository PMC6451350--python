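import numpy as np
import pytest

import hoxtempo as ht
from hoxtempo.simulate import default_standard_curve


@pytest.fixture(scope="session")
def annotation():
    return ht.default_annotation()


@pytest.fixture(scope="session")
def hoxa(annotation):
    a = [g for g in annotation if g.cluster == "A"]
    return sorted(a, key=lambda g: g.position_index)


@pytest.fixture(scope="session")
def curve():
    return default_standard_curve()


@pytest.fixture(scope="session")
def sampling_grid():
    return np.asarray(ht.SAMPLING_HPF)
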