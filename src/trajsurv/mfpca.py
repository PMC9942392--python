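"""Multivariate FPCA by eigendecomposition of stacked univariate scores.

Cross-marker correlation is modelled indirectly: each marker's univariate
FPC score vector is estimated first, the vectors are stacked patient-wise,
and the sample covariance of the stacked vector is eigendecomposed.  The
joint components mix trajectory features across markers; per-marker
multivariate eigenfunctions are the corresponding linear combinations of
the univariate eigenfunctions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fpca import FpcaModel, GridFunction


@dataclass
class MfpcaModel:
    """Joint eigenstructure over the stacked univariate score space."""

    markers: list                    # marker order
    block_sizes: dict                # marker -> K
    eigvecs: np.ndarray              # (D, M) orthonormal columns c_m
    eigvals: np.ndarray              # (M,) descending
    M: int
    standardize: bool = False
    scales: np.ndarray | None = None  # per-column SD when standardizing
    total_variance: float = 0.0      # trace of the stacked covariance

    def block_slice(self, marker: str) -> slice:
        start = 0
        for m in self.markers:
            if m == marker:
                return slice(start, start + self.block_sizes[m])
            start += self.block_sizes[m]
        raise KeyError(marker)

    @property
    def stacked_dim(self) -> int:
        return sum(self.block_sizes.values())

    def to_json(self) -> str:
        return json.dumps({
            "markers": self.markers,
            "block_sizes": self.block_sizes,
            "eigvecs": self.eigvecs.tolist(),
            "eigvals": self.eigvals.tolist(),
            "M": self.M,
            "standardize": self.standardize,
            "scales": None if self.scales is None else self.scales.tolist(),
            "total_variance": self.total_variance,
        })

    @classmethod
    def from_json(cls, text: str) -> "MfpcaModel":
        d = json.loads(text)
        return cls(d["markers"], d["block_sizes"], np.asarray(d["eigvecs"]),
                   np.asarray(d["eigvals"]), d["M"], d["standardize"],
                   None if d["scales"] is None else np.asarray(d["scales"]),
                   d["total_variance"])


def _stack(score_frames: dict, markers) -> tuple[pd.Index, np.ndarray]:
    idx = None
    for m in markers:
        fi = score_frames[m].index
        if idx is None:
            idx = fi
        elif not idx.equals(fi):
            if set(idx) != set(fi):
                raise ValueError("score matrices cover different patients")
            score_frames = {**score_frames, m: score_frames[m].loc[idx]}
    X = np.hstack([np.asarray(score_frames[m].loc[idx]) for m in markers])
    return idx, X


def fit_mfpca(score_frames: dict, M="auto", standardize: bool = False,
              var_threshold: float = 0.99):
    """Fit the joint eigenstructure of stacked univariate FPC scores.

    ``score_frames``: marker -> DataFrame (patients x K_marker), identical
    patient sets.  ``M="auto"`` keeps the smallest number of components
    explaining ``var_threshold`` of the stacked variance.  Returns
    (MfpcaModel, DataFrame of multivariate scores).
    """
    markers = list(score_frames)
    idx, X = _stack(score_frames, markers)
    n, D = X.shape
    scales = None
    if standardize:
        scales = X.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
        X = X / scales
    cov = np.cov(X.T, ddof=1) if n > 1 else np.zeros((D, D))
    cov = np.atleast_2d(cov)
    if n <= D:
        warnings.warn(f"only {n} patients for a {D}-dimensional score space; "
                      "ridge-regularizing the covariance")
        cov = cov + 1e-6 * max(np.trace(cov), 1.0) / D * np.eye(D)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    # sign convention: largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    if M == "auto":
        total = vals.sum()
        if total <= 0:
            M_sel = 1
        else:
            M_sel = int(np.searchsorted(np.cumsum(vals) / total,
                                        var_threshold) + 1)
        M_sel = min(M_sel, D)
    else:
        M_sel = int(M)
        if not 1 <= M_sel <= D:
            raise ValueError(f"M must be in [1, {D}]")
    model = MfpcaModel(markers=markers,
                       block_sizes={m: score_frames[m].shape[1]
                                    for m in markers},
                       eigvecs=vecs[:, :M_sel], eigvals=vals[:M_sel],
                       M=M_sel, standardize=standardize, scales=scales,
                       total_variance=float(np.trace(cov)))
    return model, transform(model, score_frames)


def transform(model: MfpcaModel, score_frames: dict) -> pd.DataFrame:
    """Project stacked univariate scores onto the joint components.

    A deterministic linear map rho_im = <stacked xi_i, c_m>; patients may be
    any subset/ordering, rows follow the input index.
    """
    idx, X = _stack(score_frames, model.markers)
    if X.shape[1] != model.stacked_dim:
        raise ValueError(f"expected stacked dimension {model.stacked_dim}, "
                         f"got {X.shape[1]}")
    if model.standardize:
        X = X / model.scales
    rho = X @ model.eigvecs
    return pd.DataFrame(rho, index=idx,
                        columns=[f"mfpc_{j + 1}" for j in range(model.M)])


def transform_one(model: MfpcaModel, scores_by_marker: dict) -> np.ndarray:
    """Joint scores for a single patient's univariate score vectors."""
    x = np.concatenate([np.asarray(scores_by_marker[m], dtype=float)
                        for m in model.markers])
    if len(x) != model.stacked_dim:
        raise ValueError("score vector length mismatch")
    if model.standardize:
        x = x / model.scales
    return x @ model.eigvecs


def marker_eigenfunctions(model: MfpcaModel,
                          fpca_models: dict) -> dict:
    """Per-marker multivariate eigenfunction blocks psi_m.

    psi_m for marker g is sum_k c_m[g,k] * phi_k^{(g)} — the joint
    eigenvector coefficients applied to that marker's univariate
    eigenfunctions.  Returns marker -> list of GridFunction (one per joint
    component).
    """
    out = {}
    for m in model.markers:
        fm: FpcaModel = fpca_models[m]
        sl = model.block_slice(m)
        coefs = model.eigvecs[sl, :]           # (K_m, M)
        if model.standardize:
            coefs = coefs / model.scales[sl][:, None]
        vals = coefs.T @ fm.phi                # (M, G)
        out[m] = [GridFunction(fm.grid, v) for v in vals]
    return out
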