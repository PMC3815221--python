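import numpy as np
import pytest

from aoalearn.models import LearningParams, LogisticParams, ModelKind


@pytest.fixture(scope="session")
def months():
    return np.arange(16, 31, dtype=float)


def random_learning_params(rng, log10_range=(-0.5, 1.0)):
    """Random valid accumulator parameters on moderate scales."""
    lo, hi = log10_range
    return LearningParams(
        accumulation=10.0 ** rng.uniform(lo, hi),
        rate_exponent=10.0 ** rng.uniform(-0.7, 0.7),
        base_rate=10.0 ** rng.uniform(-2.0, 1.0),
    )


def kind_params(kind, rng):
    """Random valid parameters compatible with a given kind."""
    kind = ModelKind(kind)
    if kind is ModelKind.LOGISTIC:
        return LogisticParams(slope=10.0 ** rng.uniform(-1, 0.5), intercept=rng.uniform(-5, 30))
    p = random_learning_params(rng)
    if kind is ModelKind.GAMMA:
        return LearningParams(p.accumulation, 1.0, p.base_rate)
    if kind is ModelKind.WEIBULL:
        return LearningParams(1.0, p.rate_exponent, p.base_rate)
    return p
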