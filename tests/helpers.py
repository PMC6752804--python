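"""Independent oracles and generators shared across the test suite.

Everything here deliberately avoids the package's own signature algebra so
that dual-route checks stay meaningful: iterated integrals are computed by
numerical quadrature on a refined polyline, signed areas by the shoelace
formula, and penalised logistic fits by a general-purpose bound-constrained
optimiser.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def random_path(rng, n_points=6, dim=3, scale=5.0):
    """A random strictly-increasing-time path with values of magnitude ~scale."""
    times = np.sort(rng.uniform(0.0, 10.0, n_points))
    while np.any(np.diff(times) <= 1e-6):
        times = np.sort(rng.uniform(0.0, 10.0, n_points))
    values = rng.uniform(-scale, scale, (n_points, dim))
    return times, values


def refine_polyline(times, values, factor=200):
    """Linearly interpolate extra samples inside every segment."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    fine_t = [times[:1]]
    for a, b in zip(times[:-1], times[1:]):
        fine_t.append(np.linspace(a, b, factor + 1)[1:])
    fine_t = np.concatenate(fine_t)
    fine_v = np.column_stack(
        [np.interp(fine_t, times, values[:, j]) for j in range(values.shape[1])]
    )
    return fine_t, fine_v


def oracle_iterated_integrals(times, values, refine=200):
    """Level-1 and level-2 iterated integrals by quadrature on a refined grid.

    Uses the midpoint rule per fine segment: exact (up to rounding) for the
    piecewise-linear interpolant, but shares no code path with the tensor
    algebra under test.
    """
    _, v = refine_polyline(times, values, refine)
    d = v.shape[1]
    delta = np.diff(v, axis=0)
    rel = v - v[0]
    mid = (rel[:-1] + rel[1:]) / 2.0
    level1 = rel[-1].copy()
    level2 = np.empty((d, d))
    for i in range(d):
        for j in range(d):
            level2[i, j] = float(mid[:, i] @ delta[:, j])
    return level1, level2


def shoelace_levy_area(x, y):
    """Signed area between a polyline and its chord (shoelace on the loop).

    Equals (S^(x,y) - S^(y,x)) / 2 for the piecewise-linear path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xs = np.append(x, x[0])
    ys = np.append(y, y[0])
    return 0.5 * float(np.sum(xs[:-1] * ys[1:] - xs[1:] * ys[:-1]))


def l1_logistic_oracle(X, y, lam):
    """Penalised logistic fit by L-BFGS-B on a positive/negative split.

    Minimises mean log(1 + exp(-s * eta)) + lam * sum(u + v) with
    beta = u - v, u, v >= 0 and an unpenalised intercept, on internally
    standardised columns; returns (intercept, coefficients) on the original
    feature scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd
    n, p = Xs.shape
    s = 2.0 * y - 1.0

    def objective(theta):
        b0, u, v = theta[0], theta[1 : p + 1], theta[p + 1 :]
        eta = b0 + Xs @ (u - v)
        z = -s * eta
        # stable log(1 + exp(z))
        loss = np.mean(np.logaddexp(0.0, z))
        grad_eta = -s * (1.0 / (1.0 + np.exp(-z))) / n
        g0 = grad_eta.sum()
        gx = Xs.T @ grad_eta
        grad = np.concatenate(([g0], gx + lam, -gx + lam))
        return loss + lam * (u.sum() + v.sum()), grad

    theta0 = np.zeros(1 + 2 * p)
    bounds = [(None, None)] + [(0.0, None)] * (2 * p)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    beta_std = res.x[1 : p + 1] - res.x[p + 1 :]
    beta = beta_std / sd
    b0 = res.x[0] - float(beta @ mean)
    return b0, beta
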