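import numpy as np
import pytest

import rifvar as rv


@pytest.fixture
def two_point_spectrum():
    """Symmetric two-atom single-track spectrum: z in {0.1, 0.3} Gy, equal mass."""
    return rv.SingleTrackSpectrum(np.array([0.1, 0.3]), np.array([0.5, 0.5]))


@pytest.fixture(scope="session")
def default_model():
    return rv.default_cobalt60_model()


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down four-dose study used by gating and pipeline tests."""
    groups = {0.0: (4000, 3), 0.5: (2000, 3), 1.0: (2000, 3), 2.0: (2000, 3)}
    return rv.simulate_study(dose_groups=groups, seed=7)
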