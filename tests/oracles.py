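"""Independent numerical oracles used to cross-check the package.

These deliberately avoid the code paths they validate: the two-zone ODEs
are integrated with a fixed-step RK4 scheme instead of the analytic
eigen-solution, the peak of the chamber curve is located by brute-force
grid search, and the storage regression is solved via the normal
equations.
"""

from __future__ import annotations

import numpy as np


def two_zone_deriv(x, vn, vf, q, beta, g):
    """Right-hand side of the coupled near-field/far-field mass balances."""
    cn, cf = x[..., 0], x[..., 1]
    dcn = (g + beta * (cf - cn)) / vn
    dcf = (beta * (cn - cf) - q * cf) / vf
    return np.stack([dcn, dcf], axis=-1)


def rk4_two_zone(vn, vf, q, beta, g, t_grid, dt=0.001, c_n0=0.0, c_f0=0.0):
    """Fixed-step RK4 integration of the two-zone balances.

    Parameters may be scalars or equal-length arrays (one system per
    entry); ``t_grid`` must be increasing near-multiples of ``dt``.
    Returns an array of shape ``(len(t_grid), n_systems, 2)`` (the system
    axis is squeezed for scalar input).
    """
    vn, vf, q, beta, g = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, dtype=float)) for a in (vn, vf, q, beta, g))
    )
    n_sys = vn.shape[0]
    x = np.zeros((n_sys, 2))
    x[:, 0] = c_n0
    x[:, 1] = c_f0
    t_grid = np.asarray(t_grid, dtype=float)
    out = np.empty((t_grid.size, n_sys, 2))
    steps = np.rint(t_grid / dt).astype(int)
    if not np.allclose(steps * dt, t_grid, atol=dt * 1e-6):
        raise ValueError("t_grid entries must be multiples of dt")
    t_step = 0
    k = 0
    while k < t_grid.size and steps[k] == 0:
        out[k] = x
        k += 1
    for t_step in range(1, steps[-1] + 1):
        k1 = two_zone_deriv(x, vn, vf, q, beta, g)
        k2 = two_zone_deriv(x + 0.5 * dt * k1, vn, vf, q, beta, g)
        k3 = two_zone_deriv(x + 0.5 * dt * k2, vn, vf, q, beta, g)
        k4 = two_zone_deriv(x + dt * k3, vn, vf, q, beta, g)
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        while k < t_grid.size and steps[k] == t_step:
            out[k] = x
            k += 1
    return out.squeeze(axis=1) if n_sys == 1 else out


def brute_force_peak(curve, t_end, n=200_001):
    """Grid-search maximum of ``curve(t)`` over (0, t_end]."""
    ts = np.linspace(t_end / n, t_end, n)
    cs = curve(ts)
    i = int(np.argmax(cs))
    return float(cs[i]), float(ts[i])


def ols_normal_equations(x, y):
    """Slope/intercept by explicitly solving X'X b = X'y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    b = np.linalg.solve(X.T @ X, X.T @ y)
    return float(b[1]), float(b[0])


def log_space_summary(values):
    """GM/GSD by direct log-space arithmetic (n-1 denominator)."""
    logs = np.log(np.asarray(values, dtype=float))
    n = logs.size
    mean = logs.sum() / n
    var = ((logs - mean) ** 2).sum() / (n - 1)
    return float(np.exp(mean)), float(np.exp(np.sqrt(var)))


def max_pairwise_distance(points):
    """All-pairs caliper oracle for the maximum Feret diameter."""
    pts = np.asarray(points, dtype=float)
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            best = max(best, float(np.hypot(*(pts[i] - pts[j]))))
    return best
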