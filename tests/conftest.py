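import numpy as np
import pytest

from propdiff.generators import BetaParams, BetaScenario, TwoSampleData, draw_beta_two_sample


@pytest.fixture
def small_data() -> TwoSampleData:
    """Tiny fixed dataset: two observations per group."""
    return TwoSampleData(
        y=np.array([0.2, 0.4, 0.5, 0.7]),
        x=np.array([0, 0, 1, 1]),
    )


@pytest.fixture
def six_obs_data() -> TwoSampleData:
    return TwoSampleData(
        y=np.array([0.11, 0.35, 0.52, 0.48, 0.63, 0.81]),
        x=np.array([0, 0, 0, 1, 1, 1]),
    )


@pytest.fixture
def beta_data_n50() -> TwoSampleData:
    scenario = BetaScenario(BetaParams(0.4, 8.0), BetaParams(0.55, 4.0), n0=50, n1=50)
    return draw_beta_two_sample(scenario, seed=2024)


def numerical_gradient(fn, theta, h=1e-6):
    """Central-difference gradient, independent of any analytic path."""
    theta = np.asarray(theta, dtype=float)
    grad = np.zeros_like(theta)
    for j in range(theta.size):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        grad[j] = (fn(tp) - fn(tm)) / (2.0 * h)
    return grad
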