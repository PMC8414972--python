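"""Independent numerical oracles used by the test suite.

The spike-time oracle never touches the closed-form solver: it evaluates the
membrane potential directly as a sum of alpha kernels on a dense time grid,
detects the first threshold crossing, and refines it by bisection.
"""

from __future__ import annotations

import numpy as np


def potential(t, times, weights, tau):
    """Direct kernel-sum membrane potential; t scalar or array."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    times = np.asarray(times, dtype=float)
    weights = np.asarray(weights, dtype=float)
    fin = np.isfinite(times)
    times, weights = times[fin], weights[fin]
    dt = t[:, None] - times[None, :]
    act = dt >= 0
    v = np.where(act, weights * dt * np.exp(-tau * np.where(act, dt, 0.0)), 0.0).sum(axis=1)
    return v


def oracle_spike_time(times, weights, tau, theta, resolution=1e-4):
    """First threshold crossing by dense-grid search + bisection, or None.

    The search horizon uses the fact that, after the last input, the summed
    potential has at most one interior maximum at B/A + 1/tau (a property of
    exp(-tau t)(A t - B), independent of the Lambert-W solution).
    """
    times = np.asarray(times, dtype=float)
    weights = np.asarray(weights, dtype=float)
    fin = np.isfinite(times)
    if not np.any(fin):
        return None
    t_fin, w_fin = times[fin], weights[fin]
    t0 = t_fin.min()
    last = t_fin.max()
    a = np.sum(w_fin * np.exp(tau * t_fin))
    t_end = last + 2.0 / tau
    if a > 0:
        b_over_a = np.sum(w_fin * np.exp(tau * t_fin) * t_fin) / a
        t_end = max(t_end, b_over_a + 3.0 / tau)
    grid = np.arange(t0, t_end, resolution)
    v = potential(grid, t_fin, w_fin, tau)
    above = v >= theta
    if not np.any(above):
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(grid[0])
    lo, hi = grid[i - 1], grid[i]
    f = lambda t: potential(t, t_fin, w_fin, tau)[0] - theta
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return float(0.5 * (lo + hi))


def random_instance(rng):
    """Random single-neuron instance: 3-10 inputs, N(0,1) weights, U[0,1] times."""
    n = int(rng.integers(3, 11))
    times = rng.uniform(0.0, 1.0, size=n)
    weights = rng.normal(0.0, 1.0, size=n)
    tau = float(rng.uniform(0.3, 2.0))
    theta = float(rng.uniform(0.1, 1.5))
    return times, weights, tau, theta


def central_difference(f, x, step):
    return (f(x + step) - f(x - step)) / (2.0 * step)
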