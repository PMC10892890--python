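"""Independent oracles used by the test suite.

These deliberately avoid the package's fitting/metric code paths: the ML
oracles maximise the raw log-likelihoods by iteratively-zoomed dense grid
search, and the isolation oracle enumerates every raster cell in plain
Python loops.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit, gammaln


def nb2_loglik_direct(y, mu, theta):
    y = np.asarray(y, float)
    return np.sum(
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu)),
        axis=-1,
    )


def beta_loglik_direct(y, mu, phi):
    y = np.asarray(y, float)
    a = mu * phi
    b = (1.0 - mu) * phi
    return np.sum(
        gammaln(a + b) - gammaln(a) - gammaln(b)
        + (a - 1) * np.log(y) + (b - 1) * np.log(1 - y),
        axis=-1,
    )


def _zoom_grid_search(loglik_fn, centers, half_widths, n_points=13, n_rounds=45,
                      shrink=0.55):
    """Maximise loglik_fn(p0, p1, p2) by repeatedly zoomed dense grids.

    The box shrinks slowly (factor ``shrink`` per round, recentred on the
    incumbent) so the search can track the correlated intercept/slope ridge
    instead of collapsing onto it prematurely.
    """
    centers = np.asarray(centers, float)
    half_widths = np.asarray(half_widths, float)
    best = None
    for _ in range(n_rounds):
        axes = [np.linspace(c - h, c + h, n_points) for c, h in zip(centers, half_widths)]
        G0, G1, G2 = np.meshgrid(*axes, indexing="ij")
        flat = np.column_stack([G0.ravel(), G1.ravel(), G2.ravel()])
        ll = loglik_fn(flat[:, 0], flat[:, 1], flat[:, 2])
        i = int(np.argmax(ll))
        centers = flat[i]
        best = ll[i]
        half_widths = half_widths * shrink
    return centers, best


def nb_grid_search_ml(y, x):
    """Grid-search ML of (b0, b1, log theta) for NB2 with log mu = b0 + b1*x."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)

    def ll(b0, b1, log_th):
        mu = np.exp(b0[:, None] + b1[:, None] * x[None, :])
        th = np.exp(log_th)[:, None]
        return nb2_loglik_direct(y[None, :], mu, th)

    c0 = math.log(max(y.mean(), 0.5))
    centers, _ = _zoom_grid_search(ll, [c0, 0.0, 1.5], [3.0, 3.0 / max(x.std(), 1e-9), 5.0])
    b0, b1, log_th = centers
    return b0, b1, math.exp(log_th)


def beta_grid_search_ml(y, x):
    """Grid-search ML of (g0, g1, log phi) for Beta with logit mu = g0 + g1*x."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)

    def ll(g0, g1, log_phi):
        mu = expit(g0[:, None] + g1[:, None] * x[None, :])
        phi = np.exp(log_phi)[:, None]
        return beta_loglik_direct(y[None, :], mu, phi)

    from scipy.special import logit

    c0 = float(np.mean(logit(y)))
    centers, _ = _zoom_grid_search(ll, [c0, 0.0, 2.0], [3.0, 3.0 / max(x.std(), 1e-9), 5.0])
    g0, g1, log_phi = centers
    return g0, g1, math.exp(log_phi)


def isolation_brute_force(raster, radius_km):
    """Per-cell enumeration of the survey disc; plain Python loops."""
    nrows, ncols = raster.shape
    cr, cc = raster.center
    n_disc = 0
    n_neighbour_land = 0
    for i in range(nrows):
        for j in range(ncols):
            d = math.hypot(i - cr, j - cc) * raster.cell_size_km
            if d <= radius_km:
                n_disc += 1
                if raster.values[i, j] == 1 and not raster.focal_mask[i, j]:
                    n_neighbour_land += 1
    cell_area = raster.cell_size_km ** 2
    return 1.0 - (n_neighbour_land * cell_area) / (n_disc * cell_area)
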