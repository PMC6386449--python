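import numpy as np
import pytest

from taexcite.bifurcation import with_stress_parameter
from taexcite.parameters import mazef_normalized, mazef_parameters


@pytest.fixture(scope="session")
def p_ref():
    """Reference dimensional parameter set (derived d_c preset)."""
    return mazef_parameters()


@pytest.fixture(scope="session")
def q_ref():
    """Reference normalized parameter set."""
    return mazef_normalized()


@pytest.fixture(scope="session")
def q_at(q_ref):
    """Factory: normalized set at a given antitoxin-degradation stress level."""
    def _at(delta_a=None, epsilon=None):
        q = q_ref
        if delta_a is not None:
            q = with_stress_parameter(q, "delta_a", delta_a)
        if epsilon is not None:
            q = with_stress_parameter(q, "epsilon", epsilon)
        return q
    return _at


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
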