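"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's own code paths: the Lorenz system
is integrated with a local RK4 stepper, and the largest Lyapunov exponent
is measured by Benettin two-trajectory renormalisation — fully independent
of the Rosenstein nearest-neighbor estimator under test.
"""

import numpy as np

SIGMA, RHO, BETA = 10.0, 28.0, 8.0 / 3.0


def _lorenz_rhs(s):
    x, y, z = s
    return np.array([SIGMA * (y - x), x * (RHO - z) - y, x * y - BETA * z])


def _rk4_step(s, dt):
    k1 = _lorenz_rhs(s)
    k2 = _lorenz_rhs(s + dt / 2 * k1)
    k3 = _lorenz_rhs(s + dt / 2 * k2)
    k4 = _lorenz_rhs(s + dt * k3)
    return s + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def lorenz_x_series(n: int, dt: float = 0.01, discard: int = 1000) -> np.ndarray:
    """x-coordinate of the Lorenz attractor after a transient."""
    s = np.array([1.0, 1.0, 20.0])
    out = np.empty(n + discard)
    for i in range(n + discard):
        s = _rk4_step(s, dt)
        out[i] = s[0]
    return out[discard:]


def benettin_max_lyapunov(
    n_steps: int = 40000, dt: float = 0.01, d0: float = 1e-8, transient: int = 2000
) -> float:
    """Largest Lyapunov exponent by two-trajectory renormalisation."""
    a = np.array([1.0, 1.0, 20.0])
    for _ in range(transient):
        a = _rk4_step(a, dt)
    b = a + np.array([d0, 0.0, 0.0])
    total = 0.0
    for _ in range(n_steps):
        a, b = _rk4_step(a, dt), _rk4_step(b, dt)
        d = np.linalg.norm(b - a)
        total += np.log(d / d0)
        b = a + (b - a) * (d0 / d)
    return total / (n_steps * dt)
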