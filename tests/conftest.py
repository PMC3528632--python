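import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def brute_force_concordance(y, scores) -> float:
    """All-pairs enumeration oracle: 1 per concordant pair, 0.5 per tie."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    affected = scores[y == 1]
    unaffected = scores[y == 0]
    total = 0.0
    for sa in affected:
        for su in unaffected:
            if sa > su:
                total += 1.0
            elif sa == su:
                total += 0.5
    return total / (len(affected) * len(unaffected))


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
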