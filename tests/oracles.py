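"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own linear-algebra paths:
the restricted likelihood is evaluated densely from V, grid searches probe
it directly, and the small arithmetic oracles recompute statistics from
their defining formulas.
"""

from __future__ import annotations

from math import log, pi

import numpy as np


def neg2_reml_dense(y, X, Zs, variances, resid_diag):
    """-2 restricted log-likelihood computed densely from V."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    V = np.diag(np.asarray(resid_diag, float)).copy()
    for Z, v in zip(Zs, variances):
        V += v * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    quad = float((y - X @ beta) @ Vi @ y)
    return (n - p) * log(2 * pi) + ldV + ldX + quad


def grid_reml_2d(y, X, Z, lo=1e-8, hi=100.0, points=25, stages=8):
    """Zooming 2-D grid maximizer of the restricted likelihood for the
    one-random-factor model (var_g, var_e)."""
    n = len(y)
    b_g = (np.log(lo), np.log(hi))
    b_e = (np.log(lo), np.log(hi))
    best = None
    for _ in range(stages):
        gs = np.linspace(*b_g, points)
        es = np.linspace(*b_e, points)
        vals = np.empty((points, points))
        for i, lg in enumerate(gs):
            for j, le in enumerate(es):
                vals[i, j] = neg2_reml_dense(
                    y, X, [Z], [np.exp(lg)], np.full(n, np.exp(le))
                )
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        best = (np.exp(gs[i]), np.exp(es[j]), vals[i, j])
        half_g = (b_g[1] - b_g[0]) / (points - 1) * 2
        half_e = (b_e[1] - b_e[0]) / (points - 1) * 2
        b_g = (gs[i] - half_g, gs[i] + half_g)
        b_e = (es[j] - half_e, es[j] + half_e)
    return best  # (var_g, var_e, neg2)


def coordinate_grid_reml(y, X, Zs, lo=1e-6, hi=500.0, points=33, sweeps=60):
    """Cyclic per-coordinate grid refinement of the restricted likelihood
    over m variance components plus the residual variance (last slot).

    Each sweep lays a grid of half-width h around the incumbent in every
    coordinate (log scale) and moves to the best point; h shrinks slowly so
    the search can track likelihood ridges.
    """
    m = len(Zs)
    logs = np.full(m + 1, np.log(max(np.var(y), 1e-8) / (m + 1)))
    lo_l, hi_l = np.log(lo), np.log(hi)
    h = (hi_l - lo_l) / 2.0

    def f(logv):
        v = np.exp(logv)
        return neg2_reml_dense(y, X, Zs, v[:m], np.full(len(y), v[m]))

    val = f(logs)
    for sweep in range(sweeps):
        for k in range(m + 1):
            grid = np.clip(np.linspace(logs[k] - h, logs[k] + h, points), lo_l, hi_l)
            cand = logs.copy()
            vals = []
            for g in grid:
                cand[k] = g
                vals.append(f(cand))
            j = int(np.argmin(vals))
            logs[k] = grid[j]
            val = vals[j]
        h *= 0.65
        if h < 1e-9:
            break
    v = np.exp(logs)
    return v[:m], v[m], val


def superiority_direct(row, maxima):
    """P_i straight from its definition."""
    d = np.asarray(row, float) - np.asarray(maxima, float)
    return float((d**2).sum() / (2 * len(d)))


def superiority_decomposed(row, maxima):
    """The two-term genetic + GEI decomposition of P_i."""
    row = np.asarray(row, float)
    maxima = np.asarray(maxima, float)
    n = len(row)
    xbar, mbar = row.mean(), maxima.mean()
    return float(
        (n * (xbar - mbar) ** 2 + ((row - maxima - xbar + mbar) ** 2).sum()) / (2 * n)
    )


def interaction_ss_direct(Y):
    """Interaction sum of squares by explicit double centering."""
    Y = np.asarray(Y, float)
    Z = Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) + Y.mean()
    return float((Z**2).sum())


def asv_direct(l1, l2, s1, s2):
    """ASV from the defining formula."""
    w = (l1**2) / (l2**2)
    return float(np.sqrt((w * s1) ** 2 + s2**2))
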