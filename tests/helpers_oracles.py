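"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the median-effect
oracle is a zooming brute-force grid search over (slope, intercept) of the
linearized model; the response-surface oracle solves the normal equations
directly; the kinetics oracle is a two-point finite difference.
"""

import numpy as np


def grid_search_median_effect(doses, fa, n=41, iters=25):
    """Minimize sum((m*x + c - y)^2) by iteratively zoomed 2-D grid search.

    Returns (m, Dm) with Dm = 10**(-c/m).  Each iteration shrinks the search
    box around the grid optimum by a factor of (n-1)/4, converging well below
    1e-12 absolute.
    """
    x = np.log10(np.asarray(doses, dtype=float))
    y = np.log10(fa / (1.0 - fa))
    # search over (slope, centered intercept) so the SSE valley is
    # axis-aligned; score offsets relative to the current box center as
    # SSE(center+delta) - SSE(center) = |delta_pred|^2 - 2 r.delta_pred,
    # which stays resolvable at machine precision near the optimum
    xbar = x.mean()
    xc = x - xbar
    m0, c0 = 1.0, 0.0
    w_m, w_c = 20.0, 20.0
    for _ in range(iters):
        dms = np.linspace(-w_m, w_m, n)
        dcs = np.linspace(-w_c, w_c, n)
        r = y - (m0 * xc + c0)
        DM, DC = np.meshgrid(dms, dcs, indexing="ij")
        delta = DM[..., None] * xc + DC[..., None]
        score = (delta**2).sum(axis=-1) - 2.0 * (r * delta).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(score), score.shape)
        m0, c0 = m0 + dms[i], c0 + dcs[j]
        w_m *= 4.0 / (n - 1)
        w_c *= 4.0 / (n - 1)
    c = c0 - m0 * xbar
    return float(m0), float(10.0 ** (-c / m0))


def normal_equations_quadratic(x1, x2, y):
    """Quadratic-surface coefficients via the normal equations X'X b = X'y."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    X = np.column_stack([np.ones_like(x1), x1, x2, x1**2, x2**2, x1 * x2])
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))


def finite_difference_slope(times, values):
    """Two-point slope from the first and last time point of a linear series."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    return (v[-1] - v[0]) / (t[-1] - t[0])
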