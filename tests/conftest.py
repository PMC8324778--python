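import numpy as np
import pytest

from thrombodyn import CohortSpec, PlasmaProfile, RateConstants, TGCurve
from thrombodyn.synthetic import generate_cohort


@pytest.fixture(scope="session")
def k():
    return RateConstants()


@pytest.fixture(scope="session")
def control_plasma():
    return PlasmaProfile(at_level=2400.0, a2m_level=3000.0, fibrinogen=3.3,
                         fviii=1.0, group="control")


@pytest.fixture(scope="session")
def clean_cohort():
    """Study-sized cohort without measurement noise (ground truth exact)."""
    return generate_cohort(CohortSpec(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_cohort():
    """Study-sized cohort at the default 2 nM assay noise."""
    return generate_cohort(CohortSpec(seed=11, noise_sd=2.0))


@pytest.fixture
def triangle_curve():
    """Linear rise 0->100 nM over 0-10 min, fall back to 0 at 20 min."""
    t = np.linspace(0.0, 20.0, 201)
    y = np.where(t <= 10.0, 10.0 * t, 100.0 - 10.0 * (t - 10.0))
    return TGCurve(t, y, label="triangle")
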