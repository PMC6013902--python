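import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_by_two():
    """Exposed: 30 events / 100; unexposed: 10 events / 100.

    The saturated two-group log-binomial MLE equals the empirical log risk
    ratio log(0.30/0.10) = log 3, with closed-form SE
    sqrt((1-0.30)/30 + (1-0.10)/10).
    """
    y = np.concatenate([np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)])
    x = np.concatenate([np.ones(100), np.zeros(100)])
    X = np.column_stack([np.ones(200), x])
    return y, X
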