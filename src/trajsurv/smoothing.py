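"""Local-linear kernel smoothers on a fixed grid.

Scatterplot data are first linearly binned onto the output grid; the
weighted-least-squares moment sums of the local-linear estimator are then
exact convolutions of the binned arrays with Gaussian kernel-moment arrays,
evaluated with FFTs.  This makes the two-dimensional covariance smoother
cheap enough to run inside cross-validation loops.

A Gaussian kernel is used throughout, so the moment matrices are strictly
positive definite everywhere (the kernel has unbounded support) and the
estimator is defined on the whole grid even far from data.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

_K0 = 1.0 / np.sqrt(2.0 * np.pi)  # Gaussian kernel at zero


def _gauss(u: np.ndarray) -> np.ndarray:
    return _K0 * np.exp(-0.5 * u * u)


def linear_bin_1d(x, y, grid, w=None):
    """Linearly bin weighted observations onto ``grid``.

    Returns (count_weights, value_sums): arrays of Σ w and Σ w·y per node,
    with each observation split between its two bracketing nodes.
    Observations outside the grid are clamped to the end nodes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if w is None:
        w = np.ones_like(x)
    dx = grid[1] - grid[0]
    pos = np.clip((x - grid[0]) / dx, 0.0, len(grid) - 1.0)
    lo = np.floor(pos).astype(int)
    lo = np.minimum(lo, len(grid) - 2)
    frac = pos - lo
    cw = np.zeros(len(grid))
    vs = np.zeros(len(grid))
    np.add.at(cw, lo, w * (1 - frac))
    np.add.at(cw, lo + 1, w * frac)
    np.add.at(vs, lo, w * y * (1 - frac))
    np.add.at(vs, lo + 1, w * y * frac)
    return cw, vs


def _kernel_moments_1d(n, dx, h, orders):
    d = np.arange(-(n - 1), n) * dx
    k = _gauss(d / h)
    # convolution index m corresponds to offset g_j - g_i = -m*dx
    return {p: k * (-d) ** p for p in orders}


def local_linear_1d(x, y, grid, h, w=None):
    """Local-linear Gaussian smoother of (x, y) evaluated on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    cw, vs = linear_bin_1d(x, y, grid, w)
    return _local_linear_1d_binned(cw, vs, grid, h)


def _local_linear_1d_binned(cw, vs, grid, h):
    dx = grid[1] - grid[0]
    n = len(grid)
    km = _kernel_moments_1d(n, dx, h, (0, 1, 2))
    conv = lambda a, k: fftconvolve(a, k, mode="same")
    s0, s1, s2 = conv(cw, km[0]), conv(cw, km[1]), conv(cw, km[2])
    t0, t1 = conv(vs, km[0]), conv(vs, km[1])
    det = s0 * s2 - s1 * s1
    det = np.where(det <= 0, np.finfo(float).tiny, det)
    fit = (s2 * t0 - s1 * t1) / det
    # fall back to local-constant where the design is numerically degenerate
    bad = ~np.isfinite(fit)
    if bad.any():
        fit[bad] = t0[bad] / np.maximum(s0[bad], np.finfo(float).tiny)
    return fit


def gcv_bandwidth_1d(x, y, grid, candidates=None, w=None):
    """Pick the local-linear bandwidth by generalized cross-validation.

    The effective degrees of freedom are approximated by K(0)·range/h,
    the standard binned-GCV shortcut.  Returns (best_h, gcv_scores).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    rng_len = grid[-1] - grid[0]
    if candidates is None:
        lo = max(3.0 * (grid[1] - grid[0]), _min_spacing(x))
        candidates = np.geomspace(lo, rng_len / 3.0, 8)
    n = len(x)
    scores = []
    for h in candidates:
        fit = local_linear_1d(x, y, grid, h, w)
        yhat = np.interp(x, grid, fit)
        rss = float(np.sum((y - yhat) ** 2))
        df = _K0 * rng_len / h
        denom = max(1.0 - df / n, 0.05)
        scores.append(rss / (n * denom * denom))
    best = candidates[int(np.argmin(scores))]
    return float(best), np.asarray(scores)


def _min_spacing(x):
    xs = np.unique(x)
    if len(xs) < 2:
        return np.inf
    return float(np.min(np.diff(xs)))


def linear_bin_2d(x1, x2, y, grid, w=None):
    """Linear binning of 2-D scatter (x1, x2, y) onto grid × grid."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    if w is None:
        w = np.ones_like(y)
    dx = grid[1] - grid[0]
    n = len(grid)
    cw = np.zeros((n, n))
    vs = np.zeros((n, n))
    p1 = np.clip((x1 - grid[0]) / dx, 0.0, n - 1.0)
    p2 = np.clip((x2 - grid[0]) / dx, 0.0, n - 1.0)
    l1 = np.minimum(np.floor(p1).astype(int), n - 2)
    l2 = np.minimum(np.floor(p2).astype(int), n - 2)
    f1 = p1 - l1
    f2 = p2 - l2
    for a, fa in ((l1, 1 - f1), (l1 + 1, f1)):
        for b, fb in ((l2, 1 - f2), (l2 + 1, f2)):
            ww = w * fa * fb
            np.add.at(cw, (a, b), ww)
            np.add.at(vs, (a, b), ww * y)
    return cw, vs


def local_linear_2d(cw, vs, grid, h, cross_term=True):
    """Binned 2-D local-linear Gaussian smoother.

    ``cw``/``vs`` are binned count-weights and value-sums (from
    :func:`linear_bin_2d`).  Returns the fitted surface on grid × grid.

    With ``cross_term`` the local basis is (1, dx, dy, dx·dy) rather than
    the plane (1, dx, dy).  Covariance surfaces of low-rank processes are
    locally close to bilinear, and a plane fit uniformly attenuates the
    product structure (it shows up as a multiplicative eigenvalue bias);
    the bilinear basis removes that attenuation at negligible extra cost.
    """
    grid = np.asarray(grid, dtype=float)
    dx = grid[1] - grid[0]
    n = len(grid)
    d = np.arange(-(n - 1), n) * dx
    k = _gauss(d / h)
    kd = {p: k * (-d) ** p for p in (0, 1, 2)}

    def conv(a, px, py):
        # separable kernel: convolve rows then columns
        tmp = fftconvolve(a, kd[px][:, None], mode="same", axes=0)
        return fftconvolve(tmp, kd[py][None, :], mode="same", axes=1)

    orders = [(0, 0), (1, 0), (0, 1)]
    if cross_term:
        orders.append((1, 1))
    q = len(orders)
    M = np.empty((n, n, q, q))
    T = np.empty((n, n, q))
    s_cache = {}

    def S(px, py):
        if (px, py) not in s_cache:
            s_cache[(px, py)] = conv(cw, px, py)
        return s_cache[(px, py)]

    for a in range(q):
        pa, qa = orders[a]
        T[..., a] = conv(vs, pa, qa)
        for b in range(a, q):
            pb, qb = orders[b]
            M[..., a, b] = M[..., b, a] = S(pa + pb, qa + qb)
    # tiny ridge keeps far-from-data systems solvable
    eps = 1e-10 * np.maximum(M[..., 0, 0], np.finfo(float).tiny)
    for j in range(q):
        M[..., j, j] += eps * (grid[-1] - grid[0]) ** (2 * sum(orders[j]))
    s00 = M[..., 0, 0]
    try:
        beta = np.linalg.solve(M, T[..., None])[..., 0, 0]
    except np.linalg.LinAlgError:
        beta = T[..., 0] / np.maximum(s00, np.finfo(float).tiny)
    bad = ~np.isfinite(beta)
    if bad.any():
        fallback = T[..., 0] / np.maximum(s00, np.finfo(float).tiny)
        beta = np.where(bad, fallback, beta)
    return beta


def gcv_bandwidth_2d(x1, x2, y, grid, candidates=None, w=None,
                     plateau_tol=1e-3):
    """GCV bandwidth for the 2-D smoother (shared bandwidth in both axes).

    Raw covariance cross-products are so noisy that the GCV profile is often
    flat to within a fraction of a percent; the argmin is then essentially
    arbitrary and tends to undersmooth.  Among candidates whose score is
    within ``plateau_tol`` (relative) of the minimum, the *largest*
    bandwidth is taken; when the profile has genuine curvature the rule
    reduces to the ordinary GCV minimizer.
    """
    grid = np.asarray(grid, dtype=float)
    rng_len = grid[-1] - grid[0]
    if candidates is None:
        candidates = np.geomspace(
            max(4.0 * (grid[1] - grid[0]), rng_len / 10.0), rng_len / 6.0, 5)
    cw, vs = linear_bin_2d(x1, x2, y, grid, w)
    n = len(np.asarray(y))
    scores = []
    fits = []
    for h in candidates:
        surf = local_linear_2d(cw, vs, grid, h)
        yhat = _interp2(grid, surf, x1, x2)
        rss = float(np.sum((np.asarray(y) - yhat) ** 2))
        df = (_K0 * rng_len / h) ** 2
        denom = max(1.0 - df / n, 0.05)
        scores.append(rss / (n * denom * denom))
        fits.append(surf)
    scores = np.asarray(scores)
    ok = np.flatnonzero(scores <= scores.min() * (1.0 + plateau_tol))
    i = int(ok[-1])
    return float(candidates[i]), fits[i], scores


def _interp2(grid, surf, x1, x2):
    """Bilinear interpolation of a grid surface at scattered points."""
    dx = grid[1] - grid[0]
    n = len(grid)
    p1 = np.clip((np.asarray(x1) - grid[0]) / dx, 0.0, n - 1.0)
    p2 = np.clip((np.asarray(x2) - grid[0]) / dx, 0.0, n - 1.0)
    l1 = np.minimum(np.floor(p1).astype(int), n - 2)
    l2 = np.minimum(np.floor(p2).astype(int), n - 2)
    f1 = p1 - l1
    f2 = p2 - l2
    return (
        surf[l1, l2] * (1 - f1) * (1 - f2)
        + surf[l1 + 1, l2] * f1 * (1 - f2)
        + surf[l1, l2 + 1] * (1 - f1) * f2
        + surf[l1 + 1, l2 + 1] * f1 * f2
    )
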