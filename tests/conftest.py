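import numpy as np
import pytest

from gcgwas.datatypes import WeightSeries
from gcgwas.growth_models import predict_weight

CATTLE_AGES = np.array([0.0, 6.0, 12.0, 15.0, 18.0, 24.0])


@pytest.fixture
def brody_series():
    """Noiseless Brody data at the cattle age grid."""
    params = np.array([500.0, 0.9, 0.07])
    w = predict_weight("brody", params, CATTLE_AGES)
    return WeightSeries("x1", CATTLE_AGES, w), params


@pytest.fixture
def flat_series():
    return WeightSeries("flat", CATTLE_AGES, np.full(6, 250.0))
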