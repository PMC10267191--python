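import numpy as np
import pytest

from dcenms import (
    AcquisitionParams,
    AIFShapeParams,
    AIFTrace,
    PhantomSpec,
    make_phantom_study,
    make_population_aif,
)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def times(acq):
    return acq.times()


@pytest.fixture(scope="session")
def population_shape(acq, times):
    return make_population_aif(times, AIFShapeParams(arrival_time=acq.injection_time))


@pytest.fixture(scope="session")
def aif(times, population_shape):
    """A physiological-scale whole-blood trace on the study grid."""
    return AIFTrace(times=times, c_aif=12.0 * population_shape.values, hct=0.45)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free desk-scale phantom used by several module tests."""
    return make_phantom_study(PhantomSpec.small(snr=None), seed=3)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Desk-scale phantom at the default signal SNR of 20."""
    return make_phantom_study(PhantomSpec.small(snr=20.0), seed=4)
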