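import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_matrix():
    """4 genes x 3 samples, hand-pickable values."""
    from sigeval import ExpressionMatrix

    values = np.array(
        [
            [1.0, 3.0, 5.0],
            [2.0, 2.0, 2.0],
            [0.0, 10.0, 5.0],
            [7.0, 1.0, 4.0],
        ]
    )
    return ExpressionMatrix(["A", "B", "C", "D"], ["s1", "s2", "s3"], values)
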