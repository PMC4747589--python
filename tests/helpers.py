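"""Independent numerical oracles used by the tests.

These deliberately avoid the package's propagation code paths: the ODE
oracle is a fixed-step RK4 integrator over the piecewise-constant drive.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except Exception:  # pragma: no cover
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (a and callable(a[0])) else a[0]


@njit(cache=True)
def _rk4_segments(grid, u, km, gm, kp, gp, m0, p0, h):
    """RK4 at fixed step h through each constant-drive segment; returns
    (m, p) at every grid point."""
    G = grid.shape[0]
    M = np.empty(G)
    P = np.empty(G)
    m, p = m0, p0
    M[0] = m
    P[0] = p
    for i in range(G - 1):
        dt = grid[i + 1] - grid[i]
        uu = u[i]
        n = max(int(round(dt / h)), 1)
        hh = dt / n
        for _ in range(n):
            k1m = km * uu - gm * m
            k1p = kp * m - gp * p
            m2 = m + 0.5 * hh * k1m
            p2 = p + 0.5 * hh * k1p
            k2m = km * uu - gm * m2
            k2p = kp * m2 - gp * p2
            m3 = m + 0.5 * hh * k2m
            p3 = p + 0.5 * hh * k2p
            k3m = km * uu - gm * m3
            k3p = kp * m3 - gp * p3
            m4 = m + hh * k3m
            p4 = p + hh * k3p
            k4m = km * uu - gm * m4
            k4p = kp * m4 - gp * p4
            m = m + hh * (k1m + 2 * k2m + 2 * k3m + k4m) / 6.0
            p = p + hh * (k1p + 2 * k2p + 2 * k3p + k4p) / 6.0
        M[i + 1] = m
        P[i + 1] = p
    return M, P


def rk4_reference(input_signal, params, times, init=(0.0, 0.0), h=0.001):
    """Reference trajectory at the requested times (which must include
    all drive breakpoints between them, as produced by the input grid)."""
    grid = np.asarray(times, dtype=float)
    u = input_signal.at(grid[:-1])
    M, P = _rk4_segments(grid, u, params.k_m, params.g_m, params.k_p, params.g_p,
                         float(init[0]), float(init[1]), h)
    return M, P
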