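import numpy as np
import pytest

from celia import KineticParams


@pytest.fixture(scope="session")
def params() -> KineticParams:
    return KineticParams()


@pytest.fixture(scope="session")
def at_threshold_abs(params) -> float:
    """Fixed cross-well signal threshold: 20% of the theoretical rT_alpha
    plateau at the default 50 nM reporter (alpha -> alpha_max)."""
    plateau = params.s_F * 50.0 * params.alpha_max / (params.K_r + params.alpha_max)
    return 0.2 * plateau


def euler_integrate(rhs, y0, t_end, dt=1e-3, record_every=None):
    """Fixed-step explicit Euler oracle for hand-written ODE systems.

    ``rhs(y) -> dy/dt``; returns (times, states) sampled every
    ``record_every`` minutes (default: only the final state).
    """
    y = np.array(y0, dtype=float)
    n = int(round(t_end / dt))
    if record_every is None:
        for _ in range(n):
            y = y + dt * rhs(y)
        return np.array([t_end]), y[None, :]
    stride = int(round(record_every / dt))
    times = [0.0]
    states = [y.copy()]
    for i in range(1, n + 1):
        y = y + dt * rhs(y)
        if i % stride == 0:
            times.append(i * dt)
            states.append(y.copy())
    return np.array(times), np.array(states)
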