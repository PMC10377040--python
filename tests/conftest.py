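import numpy as np
import pytest

from abdyn import build_grid, build_kernel


@pytest.fixture(scope="session")
def grid():
    """Default 9-class decade ladder centered on the log10-Kd mean."""
    return build_grid()


@pytest.fixture(scope="session")
def kernel(grid):
    return build_kernel(grid)


def rk4(f, y0, t_end, n_steps):
    """Fixed-step classical Runge-Kutta integrator, independent of scipy's
    adaptive machinery; returns the state at t_end."""
    y = np.asarray(y0, dtype=float).copy()
    h = t_end / n_steps
    t = 0.0
    for _ in range(n_steps):
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        y = y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y
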