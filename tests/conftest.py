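import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pathdiffcorr.expression_io import ConditionDesign, ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 probes x 4 samples, one missing value in p3/s4."""
    data = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.0, 6.0, 8.0],
            [5.0, 5.5, 6.0, np.nan],
        ],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def two_condition_design() -> ConditionDesign:
    return ConditionDesign(
        {"s1": "nonrelapse", "s2": "nonrelapse", "s3": "relapse",
         "s4": "relapse"}
    )
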