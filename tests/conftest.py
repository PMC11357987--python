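import numpy as np
import pytest

from neurosysid.datatypes import Recording


@pytest.fixture
def chaotic_recording() -> Recording:
    """Deterministic scalar chaotic map y(t+1) = 1 - 2 y(t)^2."""
    y = np.empty(10_000)
    y[0] = 0.3
    for t in range(1, y.size):
        y[t] = 1.0 - 2.0 * y[t - 1] ** 2
    return Recording(y[None, :])


def simulate_innovation_form(A, C, K, T, seed=0):
    """Simulate x(t+1) = A x + K e(t), y(t) = C x + e(t) with iid N(0, I)
    innovations; returns (Y (n, T), innovations (T, n))."""
    rng = np.random.default_rng(seed)
    n_x = A.shape[0]
    n = C.shape[0]
    e = rng.standard_normal((T, n))
    x = np.zeros(n_x)
    Y = np.empty((n, T))
    for t in range(T):
        Y[:, t] = C @ x + e[t]
        x = A @ x + K @ e[t]
    return Y, e
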