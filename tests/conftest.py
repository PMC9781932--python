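import numpy as np
import pytest
from hypothesis import settings

import cosolv as cv

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from cosolv.synth import (alkane_like_profile, amide_like_profile,
                          water_like_profile)


@pytest.fixture(scope="session")
def table1():
    return cv.load_table1()


@pytest.fixture(scope="session")
def solvent_meta():
    return cv.load_solvent_meta()


@pytest.fixture(scope="session")
def water():
    return water_like_profile()


@pytest.fixture(scope="session")
def alkane():
    return alkane_like_profile()


@pytest.fixture(scope="session")
def amide():
    return amide_like_profile()


@pytest.fixture(scope="session")
def ja_truth():
    """A Jouyban-Acree ground truth with fixed anchors."""
    a2 = cv.NeatAnchor.from_points([288.15, 318.15], [-1.2, -0.8])
    a3 = cv.NeatAnchor.from_points([288.15, 318.15], [-6.2, -5.6])
    return cv.JouybanAcreeParams(500.0, -200.0, 100.0, a2, a3)
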