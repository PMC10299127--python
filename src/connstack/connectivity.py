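"""Per-subject connectivity estimation: correlation, covariance, tangent embedding.

The tangent representation whitens each subject's covariance by the inverse
square root of a group reference point — the affine-invariant (Karcher)
geometric mean of the fitting covariances — and takes the matrix logarithm.
The reference is computed by the standard fixed-point iteration

    G  <-  G^{1/2} exp( mean_i log(G^{-1/2} C_i G^{-1/2}) ) G^{1/2}

iterated until the Frobenius norm of the mean-log term falls below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import LedoitWolf

__all__ = [
    "ConnectivityMatrix",
    "GroupTangentModel",
    "correlation_matrix",
    "covariance_matrix",
    "fit_tangent",
    "tangent_embed",
]

METHODS = ("correlation", "covariance", "tangent")

_SYM_TOL = 1e-10
_PSD_TOL = -1e-8


class ConnectivityError(ValueError):
    """Raised on invalid inputs to the connectivity estimators."""


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N connectivity estimate tagged with atlas and method."""

    subject_id: str
    atlas: str
    method: str
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.method not in METHODS:
            raise ConnectivityError(f"unknown method {self.method!r}")
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ConnectivityError(f"matrix must be square, got {self.M.shape}")
        if not np.all(np.isfinite(self.M)):
            raise ConnectivityError("matrix contains non-finite entries")
        asym = np.max(np.abs(self.M - self.M.T)) if self.M.size else 0.0
        if asym > _SYM_TOL:
            raise ConnectivityError(f"matrix asymmetric beyond tolerance ({asym:.2e})")
        if self.method == "correlation":
            if not np.allclose(np.diag(self.M), 1.0, atol=1e-12):
                raise ConnectivityError("correlation matrix must have unit diagonal")
            if np.max(np.abs(self.M)) > 1.0 + 1e-12:
                raise ConnectivityError("correlation entries must lie in [-1, 1]")
        elif self.method == "covariance":
            min_eig = float(np.linalg.eigvalsh(self.M).min())
            if min_eig < _PSD_TOL:
                raise ConnectivityError(
                    f"covariance matrix not positive semi-definite (min eig {min_eig:.3e})"
                )

    @property
    def n_rois(self) -> int:
        return self.M.shape[0]


@dataclass
class GroupTangentModel:
    """Group reference for tangent embedding: geometric mean G and whitener W = G^{-1/2}."""

    G: np.ndarray
    W: np.ndarray
    n_fit: int
    tol: float

    def __post_init__(self) -> None:
        if np.linalg.eigvalsh(self.G).min() <= 0:
            raise ConnectivityError("tangent reference G must be positive definite")
        resid = np.max(np.abs(self.W @ self.G @ self.W.T - np.eye(self.G.shape[0])))
        if resid > 1e-8:
            raise ConnectivityError(f"whitener inconsistent with G (residual {resid:.2e})")


def correlation_matrix(ts) -> ConnectivityMatrix:
    """Pearson correlation across time between every pair of ROI signals."""
    data = ts.data
    stds = data.std(axis=0, ddof=1)
    zero = np.flatnonzero(stds == 0)
    if zero.size:
        raise ConnectivityError(
            f"zero-variance ROI column(s) {zero.tolist()}: correlation undefined"
        )
    M = np.corrcoef(data, rowvar=False)
    M = np.clip((M + M.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(M, 1.0)
    return ConnectivityMatrix(ts.subject_id, ts.atlas, "correlation", M)


def covariance_matrix(ts, estimator: str = "shrunk") -> ConnectivityMatrix:
    """Sample covariance of the ROI signals.

    ``empirical`` is the unbiased estimator (denominator T-1); ``shrunk`` is
    Ledoit-Wolf shrinkage toward a scaled identity, strictly positive
    definite even when T < N.
    """
    data = ts.data
    if data.shape[0] < 2:
        raise ConnectivityError("covariance requires at least 2 timepoints")
    if estimator == "empirical":
        M = np.cov(data, rowvar=False, ddof=1)
    elif estimator == "shrunk":
        M = LedoitWolf(assume_centered=False).fit(data).covariance_
    else:
        raise ConnectivityError(f"unknown estimator {estimator!r}")
    M = (M + M.T) / 2.0
    return ConnectivityMatrix(ts.subject_id, ts.atlas, "covariance", M)


# ---------------------------------------------------------------------------
# symmetric matrix functions via eigendecomposition

def _eig_fun(S: np.ndarray, fun) -> np.ndarray:
    vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
    out = (vecs * fun(vals)) @ vecs.T
    return (out + out.T) / 2.0


def _logm_spd(S: np.ndarray) -> np.ndarray:
    vals = np.linalg.eigvalsh((S + S.T) / 2.0)
    if vals.min() <= 0:
        raise ConnectivityError(
            f"matrix is not positive definite (min eig {vals.min():.3e}); cannot take log"
        )
    return _eig_fun(S, np.log)


def _check_spd(M: np.ndarray, what: str) -> None:
    if np.linalg.eigvalsh((M + M.T) / 2.0).min() <= 0:
        raise ConnectivityError(f"{what} must be symmetric positive definite")


def fit_tangent(covs: list, tol: float = 1e-8, max_iter: int = 200) -> GroupTangentModel:
    """Fit the group geometric mean of SPD covariance matrices.

    Accepts ``ConnectivityMatrix`` instances or raw SPD arrays.
    """
    mats = [np.asarray(getattr(c, "M", c), dtype=float) for c in covs]
    if not mats:
        raise ConnectivityError("fit_tangent needs at least one matrix")
    n = mats[0].shape[0]
    for i, m in enumerate(mats):
        if m.shape != (n, n):
            raise ConnectivityError(f"matrix {i} has shape {m.shape}, expected {(n, n)}")
        _check_spd(m, f"fitting matrix {i}")

    G = sum(mats) / len(mats)  # arithmetic mean as starting point
    resid = np.inf
    for _ in range(max_iter):
        W = _eig_fun(G, lambda v: v ** -0.5)
        mean_log = sum(_logm_spd(W @ m @ W.T) for m in mats) / len(mats)
        resid = float(np.linalg.norm(mean_log, "fro"))
        if resid < tol:
            break
        G_half = _eig_fun(G, np.sqrt)
        G = G_half @ _eig_fun(mean_log, np.exp) @ G_half
        G = (G + G.T) / 2.0
    else:
        raise ConnectivityError(
            f"geometric mean did not converge in {max_iter} iterations "
            f"(final residual {resid:.3e} > tol {tol:.1e})"
        )
    W = _eig_fun(G, lambda v: v ** -0.5)
    return GroupTangentModel(G=G, W=W, n_fit=len(mats), tol=tol)


def tangent_embed(model: GroupTangentModel, cov) -> ConnectivityMatrix:
    """Project an SPD covariance into the tangent space at the group mean."""
    C = np.asarray(getattr(cov, "M", cov), dtype=float)
    if C.shape != model.G.shape:
        raise ConnectivityError(
            f"dimension mismatch: matrix {C.shape} vs model {model.G.shape}"
        )
    _check_spd(C, "input covariance")
    T = _logm_spd(model.W @ C @ model.W.T)
    sid = getattr(cov, "subject_id", "")
    atlas = getattr(cov, "atlas", "")
    return ConnectivityMatrix(sid, atlas, "tangent", T)
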