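"""Sparse functional principal component analysis by conditional expectation.

Each tumor marker's log-scale trajectory is modelled as a Gaussian process

    Y_ij = X_i(t_ij) + eps_ij = mu(t_ij) + sum_k xi_ik phi_k(t_ij) + eps_ij

observed at a handful of irregular times per patient.  The mean function is
estimated by pooled local-linear smoothing, the covariance surface by 2-D
local-linear smoothing of within-patient residual cross-products (diagonal
excluded, so the measurement-error variance does not contaminate it), the
eigenstructure by a weighted eigenproblem under a trapezoid quadrature rule,
and per-patient scores by the conditional expectation (BLUP) given that
patient's own observations — the PACE estimator for sparse designs.

The number of retained components K is chosen by AIC on the conditional
pseudo-Gaussian log-likelihood, ties broken toward the smaller K.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .smoothing import (
    gcv_bandwidth_1d,
    gcv_bandwidth_2d,
    linear_bin_2d,
    local_linear_1d,
    local_linear_2d,
)

DEFAULT_GRID_LO = -1.0
DEFAULT_GRID_HI = 12.0
DEFAULT_GRID_SIZE = 101


def make_grid(lo: float = DEFAULT_GRID_LO, hi: float = DEFAULT_GRID_HI,
              n: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Dense evaluation grid in months relative to surgery."""
    return np.linspace(lo, hi, n)


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Quadrature weights: positive, summing to the interval length."""
    w = np.empty_like(grid)
    d = np.diff(grid)
    w[0] = d[0] / 2
    w[-1] = d[-1] / 2
    w[1:-1] = (d[:-1] + d[1:]) / 2
    return w


@dataclass
class GridFunction:
    """A function represented by its values on a dense time grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same shape")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def quad_weights(self) -> np.ndarray:
        return trapezoid_weights(self.grid)

    def __call__(self, t):
        return np.interp(t, self.grid, self.values)


@dataclass
class FpcaModel:
    """Estimated Karhunen–Loève decomposition for one marker."""

    marker: str
    grid: np.ndarray
    mu: np.ndarray                # mean function on grid
    phi: np.ndarray               # (K, G) orthonormal eigenfunctions
    lam: np.ndarray               # (K,) descending eigenvalues
    sigma2: float                 # measurement-error variance
    bandwidth_mean: float
    bandwidth_cov: float
    n_subjects: int = 0
    aic_by_k: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.lam)

    @property
    def quad_weights(self) -> np.ndarray:
        return trapezoid_weights(self.grid)

    def mean_function(self) -> GridFunction:
        return GridFunction(self.grid, self.mu)

    def eigenfunction(self, k: int) -> GridFunction:
        return GridFunction(self.grid, self.phi[k])

    def phi_at(self, t: np.ndarray) -> np.ndarray:
        """Eigenfunction values at arbitrary times, (len(t), K)."""
        t = np.atleast_1d(t)
        return np.column_stack([np.interp(t, self.grid, p) for p in self.phi])

    def truncated(self, K: int) -> "FpcaModel":
        if K > self.K:
            raise ValueError(f"cannot truncate to K={K} > {self.K}")
        return FpcaModel(self.marker, self.grid, self.mu, self.phi[:K],
                         self.lam[:K], self.sigma2, self.bandwidth_mean,
                         self.bandwidth_cov, self.n_subjects, self.aic_by_k)

    def to_json(self) -> str:
        return json.dumps({
            "marker": self.marker,
            "grid": self.grid.tolist(),
            "mu": self.mu.tolist(),
            "phi": self.phi.tolist(),
            "lam": self.lam.tolist(),
            "sigma2": self.sigma2,
            "bandwidth_mean": self.bandwidth_mean,
            "bandwidth_cov": self.bandwidth_cov,
            "n_subjects": self.n_subjects,
        })

    @classmethod
    def from_json(cls, text: str) -> "FpcaModel":
        d = json.loads(text)
        return cls(d["marker"], np.asarray(d["grid"]), np.asarray(d["mu"]),
                   np.asarray(d["phi"]), np.asarray(d["lam"]), d["sigma2"],
                   d["bandwidth_mean"], d["bandwidth_cov"],
                   d.get("n_subjects", 0))


# ---------------------------------------------------------------------------
# estimation stages
# ---------------------------------------------------------------------------

def estimate_mean(series: list[tuple[np.ndarray, np.ndarray]],
                  grid: np.ndarray, bandwidth="auto") -> tuple[GridFunction, float]:
    """Pooled local-linear mean function; GCV bandwidth if "auto"."""
    if not series:
        raise ValueError("empty cohort: no series to smooth")
    t = np.concatenate([np.asarray(s[0], dtype=float) for s in series])
    y = np.concatenate([np.asarray(s[1], dtype=float) for s in series])
    if len(np.unique(t)) < 2:
        raise ValueError("mean estimation needs >= 2 distinct observation times")
    if bandwidth == "auto":
        bandwidth, _ = gcv_bandwidth_1d(t, y, grid)
    mu = local_linear_1d(t, y, grid, bandwidth)
    return GridFunction(grid, mu), float(bandwidth)


def estimate_covariance(series, mean: GridFunction, bandwidth="auto",
                        sigma2_floor: float = 0.0):
    """Smoothed covariance surface and measurement-error variance.

    Raw within-patient residual cross-products (j != l) are smoothed in 2-D
    with the diagonal pairs excluded; the error variance is the average gap,
    over the central half of the domain, between the smoothed raw variance
    (which includes the error) and the surface diagonal (which does not).
    The surface is symmetrized and projected to the nearest PSD matrix by
    truncating negative eigenvalues.
    """
    grid = mean.grid
    t1, t2, prod, td, res2 = [], [], [], [], []
    for t, y in series:
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        e = y - mean(t)
        if len(t) >= 1:
            td.append(t)
            res2.append(e * e)
        if len(t) < 2:
            continue
        ii, jj = np.meshgrid(np.arange(len(t)), np.arange(len(t)), indexing="ij")
        off = ii != jj
        t1.append(t[ii[off]])
        t2.append(t[jj[off]])
        prod.append(e[ii[off]] * e[jj[off]])
    if not t1:
        raise ValueError("covariance estimation needs a patient with >= 2 observations")
    t1 = np.concatenate(t1)
    t2 = np.concatenate(t2)
    prod = np.concatenate(prod)

    if bandwidth == "auto":
        bandwidth, surf, _ = gcv_bandwidth_2d(t1, t2, prod, grid)
    else:
        cw, vs = linear_bin_2d(t1, t2, prod, grid)
        surf = local_linear_2d(cw, vs, grid, bandwidth)
    surf = 0.5 * (surf + surf.T)

    # error variance from the diagonal gap on the central sub-interval;
    # the raw variance curve gets its own 1-D bandwidth
    td = np.concatenate(td)
    res2 = np.concatenate(res2)
    bw_diag, _ = gcv_bandwidth_1d(td, res2, grid)
    vhat = local_linear_1d(td, res2, grid, bw_diag)
    lo = grid[0] + (grid[-1] - grid[0]) / 4
    hi = grid[-1] - (grid[-1] - grid[0]) / 4
    central = (grid >= lo) & (grid <= hi)
    sigma2 = float(np.mean(vhat[central] - np.diag(surf)[central]))
    sigma2 = max(sigma2, sigma2_floor, 0.0)

    surf = _project_psd(surf, trapezoid_weights(grid))
    return surf, sigma2, float(bandwidth)


def _project_psd(surface, w):
    sw = np.sqrt(w)
    B = sw[:, None] * surface * sw[None, :]
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    vals = np.clip(vals, 0.0, None)
    B = (vecs * vals) @ vecs.T
    B = 0.5 * (B + B.T)          # exact symmetry survives the element-wise
    return B / np.outer(sw, sw)  # division by a symmetric weight matrix


def eigendecompose(surface: np.ndarray, grid: np.ndarray,
                   drop_ratio: float = 1e-10):
    """Orthonormal eigenpairs of a covariance surface under quadrature.

    Solves the weighted eigenproblem so that int phi_j phi_k = delta_jk under
    the trapezoid rule; eigenvalues descending; each eigenfunction's sign is
    fixed so its integral is non-negative; components with eigenvalue below
    ``drop_ratio`` times the leading one are dropped.
    """
    w = trapezoid_weights(grid)
    sw = np.sqrt(w)
    B = sw[:, None] * surface * sw[None, :]
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    keep = vals > max(drop_ratio * max(vals[0], 0.0), 0.0)
    vals = vals[keep]
    vecs = vecs[:, keep]
    phi = (vecs / sw[:, None]).T  # (K, G)
    # sign convention: non-negative integral
    signs = np.where(phi @ w >= 0, 1.0, -1.0)
    phi = phi * signs[:, None]
    return vals, phi


def estimate_scores(model: FpcaModel, t, y):
    """PACE conditional-expectation scores for one patient.

    Returns (xi_hat, posterior covariance).  xi_hat is the best linear
    unbiased predictor Lambda Phi' Sigma^{-1} (y - mu) with
    Sigma = Phi Lambda Phi' + sigma2 I built from the eigenfunctions
    interpolated at the patient's own observation times.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if len(t) == 0:
        raise ValueError("patient has no observations")
    Phi = model.phi_at(t)                      # (m, K)
    Lam = np.diag(model.lam)
    resid = y - np.interp(t, model.grid, model.mu)
    noise = model.sigma2 if model.sigma2 > 0 else 1e-8
    Sigma = Phi @ Lam @ Phi.T + noise * np.eye(len(t))
    sol = np.linalg.solve(Sigma, resid)
    xi = model.lam * (Phi.T @ sol)
    A = np.linalg.solve(Sigma, Phi)            # Sigma^{-1} Phi
    post = Lam - Lam @ Phi.T @ A @ Lam
    return xi, post


def estimate_scores_all(model: FpcaModel, series: dict):
    """Scores for every patient in ``series`` (id -> (t, y)).

    Returns (ids, score matrix (n, K), list of posterior covariances).
    """
    ids = list(series)
    xis = np.empty((len(ids), model.K))
    posts = []
    for i, pid in enumerate(ids):
        t, y = series[pid]
        xi, post = estimate_scores(model, t, y)
        xis[i] = xi
        posts.append(post)
    return ids, xis, posts


def fit_trajectory(model: FpcaModel, xi) -> GridFunction:
    """Reconstruct the latent trajectory mu + sum_k xi_k phi_k on the grid."""
    xi = np.asarray(xi, dtype=float)
    if xi.shape != (model.K,):
        raise ValueError(f"expected {model.K} scores, got shape {xi.shape}")
    return GridFunction(model.grid, model.mu + xi @ model.phi)


def _pseudo_loglik(model: FpcaModel, series) -> float:
    """Marginal pseudo-Gaussian log-likelihood of the observations.

    Each patient's observation vector is scored under
    N(mu_i, Phi_i Lambda Phi_i' + sigma2 I) with the estimated mean,
    eigenstructure and error variance plugged in.  The marginal form keeps
    the determinant term, so adding a spurious component pays a real price
    and the AIC is a proper model-order criterion; a conditional
    (plug-in-score) likelihood lacks that term and systematically
    over-selects at these sample sizes.
    """
    noise = model.sigma2 if model.sigma2 > 0 else 1e-8
    Lam = np.diag(model.lam)
    ll = 0.0
    for t, y in series:
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        Phi = model.phi_at(t)
        Sigma = Phi @ Lam @ Phi.T + noise * np.eye(len(t))
        r = y - np.interp(t, model.grid, model.mu)
        _, logdet = np.linalg.slogdet(Sigma)
        ll += -0.5 * (len(t) * np.log(2 * np.pi) + logdet
                      + r @ np.linalg.solve(Sigma, r))
    return float(ll)


def select_K(model: FpcaModel, series, candidates=None) -> int:
    """AIC choice of the number of components; ties toward smaller K."""
    if candidates is None:
        candidates = range(1, model.K + 1)
    candidates = sorted(set(int(k) for k in candidates))
    if not candidates:
        raise ValueError("empty candidate set for K")
    aics = {}
    for K in candidates:
        sub = model.truncated(min(K, model.K))
        aics[K] = -2.0 * _pseudo_loglik(sub, series) + 2.0 * K
    model.aic_by_k = aics
    best = min(candidates, key=lambda K: (aics[K], K))
    return int(best)


def fit_fpca(series, marker: str = "", grid=None, bandwidth_mean="auto",
             bandwidth_cov="auto", k_candidates=None, max_components: int = 10,
             select: bool = True):
    """Full sparse-FPCA fit for one marker.

    ``series``: list of (times, log-values) pairs, or dict id -> pair.
    Returns an :class:`FpcaModel` truncated at the AIC-selected K.
    """
    if isinstance(series, dict):
        series = list(series.values())
    if grid is None:
        grid = make_grid()
    mean, bw_mu = estimate_mean(series, grid, bandwidth_mean)
    surf, sigma2, bw_cov = estimate_covariance(series, mean, bandwidth_cov)
    lam, phi = eigendecompose(surf, grid)
    if len(lam) == 0:
        warnings.warn("degenerate covariance surface; keeping one flat component")
        lam = np.array([1e-12])
        phi = np.ones((1, len(grid))) / np.sqrt(grid[-1] - grid[0])
    lam = lam[:max_components]
    phi = phi[:max_components]
    model = FpcaModel(marker, np.asarray(grid, dtype=float), mean.values, phi,
                      lam, sigma2, bw_mu, bw_cov, n_subjects=len(series))
    if select:
        K = select_K(model, series, k_candidates)
        model = model.truncated(K)
    return model
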