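"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: kinetics are
checked against brute-force Runge-Kutta integration, hypergeometric tails
against scipy's distribution machinery, and regressions against
scipy.stats.linregress.
"""

import numpy as np


def rk4_kinetics(u0, s0, alpha, beta, gamma, tau, n_steps=10_000):
    """Fourth-order Runge-Kutta integration of du/dt = a - b u, ds/dt = b u - g s.

    All parameters may be arrays (vectorized over parameter sets).
    """
    u = np.asarray(u0, dtype=float).copy()
    s = np.asarray(s0, dtype=float).copy()
    tau = np.asarray(tau, dtype=float)
    h = tau / n_steps

    def f(u, s):
        return alpha - beta * u, beta * u - gamma * s

    for _ in range(n_steps):
        k1u, k1s = f(u, s)
        k2u, k2s = f(u + h / 2 * k1u, s + h / 2 * k1s)
        k3u, k3s = f(u + h / 2 * k2u, s + h / 2 * k2s)
        k4u, k4s = f(u + h * k3u, s + h * k3s)
        u = u + h / 6 * (k1u + 2 * k2u + 2 * k3u + k4u)
        s = s + h / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
    return u, s


def rk4_piecewise(alpha_regimes, switch_times, beta, gamma, t, u0=0.0, s0=0.0,
                  n_steps_per_regime=20_000):
    """Integrate the piecewise-constant-alpha system from time 0 to t."""
    bounds = [0.0] + [sw for sw in switch_times if sw < t] + [t]
    alphas = list(alpha_regimes)
    u, s = float(u0), float(s0)
    for i in range(len(bounds) - 1):
        span = bounds[i + 1] - bounds[i]
        if span <= 0:
            continue
        u, s = rk4_kinetics(u, s, alphas[i], beta, gamma, span, n_steps_per_regime)
        u, s = float(u), float(s)
    return u, s
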