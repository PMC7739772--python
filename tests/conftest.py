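import numpy as np
import pytest

from sprintcp import generate_cohort, ta_config

# Hinge toy with an exact change-point at x=4: y = 12 - 2*min(x, 4).
TOY_X = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
TOY_Y = np.array([10.0, 8.0, 6.0, 4.0, 4.0, 4.0])


@pytest.fixture
def toy_hinge():
    return TOY_X.copy(), TOY_Y.copy()


@pytest.fixture(scope="session")
def ta_cohort():
    """Study-calibrated TA-mode synthetic cohort (n=14), fixed seed."""
    return generate_cohort(ta_config(seed=7))
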