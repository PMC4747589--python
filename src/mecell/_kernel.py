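"""Low-level propagation kernels.

The gene-expression model is linear with a piecewise-constant drive, so
each grid step admits a closed-form solution.  The kernels below
propagate many cells at once over a shared grid; they are numba-compiled
when numba is importable and fall back to a pure-NumPy segment loop
otherwise (identical results, slower).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _propagate_numba(grid, u, start_idx, m0, p0, km, gm, kp, gp, M, P):
    n_cells = km.shape[0]
    n_grid = grid.shape[0]
    for c in range(n_cells):
        m = m0[c]
        p = p0[c]
        s = start_idx[c]
        for i in range(min(s + 1, n_grid)):
            M[c, i] = m
            P[c, i] = p
        for i in range(s, n_grid - 1):
            dt = grid[i + 1] - grid[i]
            uu = u[i]
            a = km[c] * uu / gm[c]
            em = math.exp(-gm[c] * dt)
            ep = math.exp(-gp[c] * dt)
            d = gp[c] - gm[c]
            if abs(d) * dt < 1e-12:
                r = ep * dt
            else:
                r = ep * math.expm1(d * dt) / d
            pa = kp[c] * a / gp[c]
            p = pa + (p - pa) * ep + kp[c] * (m - a) * r
            m = a + (m - a) * em
            M[c, i + 1] = m
            P[c, i + 1] = p


def _propagate_numpy(grid, u, start_idx, m0, p0, km, gm, kp, gp, M, P):
    n_grid = grid.shape[0]
    m = m0.copy()
    p = p0.copy()
    M[:, 0] = m
    P[:, 0] = p
    for i in range(n_grid - 1):
        dt = grid[i + 1] - grid[i]
        active = start_idx <= i
        a = km * u[i] / gm
        em = np.exp(-gm * dt)
        ep = np.exp(-gp * dt)
        d = gp - gm
        small = np.abs(d) * dt < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(small, ep * dt, ep * np.expm1(np.where(small, 0.0, d) * dt) /
                         np.where(small, 1.0, d))
        pa = kp * a / gp
        p_new = pa + (p - pa) * ep + kp * (m - a) * r
        m_new = a + (m - a) * em
        m = np.where(active, m_new, m)
        p = np.where(active, p_new, p)
        M[:, i + 1] = m
        P[:, i + 1] = p


def propagate(grid, u, start_idx, m0, p0, km, gm, kp, gp):
    """Propagate N cells' (mRNA, protein) state over a shared grid.

    Parameters
    ----------
    grid : (G,) strictly increasing times (min).
    u : (G-1,) drive value on each half-open grid interval.
    start_idx : (N,) int — a cell's state is held at ``(m0, p0)`` until
        ``grid[start_idx]``, from which integration begins (cells born
        mid-experiment).
    m0, p0, km, gm, kp, gp : (N,) float arrays.

    Returns
    -------
    M, P : (N, G) arrays of mRNA and protein levels at grid times.
    """
    grid = np.ascontiguousarray(grid, dtype=np.float64)
    u = np.ascontiguousarray(u, dtype=np.float64)
    start_idx = np.ascontiguousarray(start_idx, dtype=np.int64)
    n = km.shape[0]
    M = np.empty((n, grid.shape[0]))
    P = np.empty((n, grid.shape[0]))
    args = (grid, u, start_idx,
            np.ascontiguousarray(m0, dtype=np.float64),
            np.ascontiguousarray(p0, dtype=np.float64),
            np.ascontiguousarray(km, dtype=np.float64),
            np.ascontiguousarray(gm, dtype=np.float64),
            np.ascontiguousarray(kp, dtype=np.float64),
            np.ascontiguousarray(gp, dtype=np.float64),
            M, P)
    if HAVE_NUMBA:
        _propagate_numba(*args)
    else:  # pragma: no cover
        _propagate_numpy(*args)
    return M, P
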