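import numpy as np
import pytest

from synprom.motifs import Pwm
from synprom.simulate import random_library


def random_pwm(rng: np.random.Generator, width: int, ident: str = "RND") -> Pwm:
    """A random Dirichlet PWM (strictly positive columns)."""
    prob = rng.dirichlet([0.5] * 4, size=width)
    prob = np.clip(prob, 1e-3, None)
    prob /= prob.sum(axis=1, keepdims=True)
    return Pwm(id=ident, tf_name=ident, prob=prob)


@pytest.fixture(scope="session")
def library8():
    """Eight well-separated high-information synthetic motifs (width 10)."""
    return random_library(8, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
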