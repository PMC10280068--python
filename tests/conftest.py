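import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ighap.readqc import UniqueSequence, round_proportion

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def uniques_from_counts(pairs):
    """Build a ranked UniqueSequence list from (sequence, count) pairs."""
    total = sum(c for _, c in pairs)
    ordered = sorted(pairs, key=lambda p: (-p[1], p[0]))
    return [
        UniqueSequence(
            bases=seq, count=c, rank=i + 1, proportion=round_proportion(c, total)
        )
        for i, (seq, c) in enumerate(ordered)
    ]


@pytest.fixture
def make_uniques():
    return uniques_from_counts
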