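"""Comparison predictors sharing the train-matrix-in / score-matrix-out
interface: per-side RLS averaging, raw Kronecker RLS, Laplacian-regularized
least squares, truncated KATZ walks on the heterogeneous graph, two-phase
network-based inference, and weighted-profile recommendation.
"""

from __future__ import annotations

import numpy as np

from .io import AssociationMatrix, PredictionMatrix
from .kronrls import _kernel_values, _label_values, _wrap, eigendecompose, solve_eigen

__all__ = ["rls_avg", "rls_kron", "netlaprls", "katz", "nbi", "wp", "heterogeneous_adjacency"]


def rls_avg(Kc, Kd, Y, sigma: float = 0.2):
    """Average of the two one-sided regularized least squares smoothers."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    kc, kd = _kernel_values(Kc), _kernel_values(Kd)
    V = _label_values(Y)
    nc, nd = kc.shape[0], kd.shape[0]
    row_part = kc @ np.linalg.solve(kc + sigma * np.eye(nc), V)
    col_part = (kd @ np.linalg.solve(kd + sigma * np.eye(nd), V.T)).T
    return _wrap(Y, (row_part + col_part) / 2.0)


def rls_kron(Kc, Kd, Y, sigma: float = 0.2):
    """Kronecker-kernel RLS on the raw binary matrix (no cold-start stage)."""
    ef = eigendecompose(Kc, Kd)
    return solve_eigen(ef, Y, sigma)


def _normalized_laplacian(W: np.ndarray) -> np.ndarray:
    d = W.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / np.sqrt(d), 0.0)
    return np.diag(d * dinv * dinv) - (dinv[:, None] * W * dinv[None, :])


def netlaprls(
    Kc,
    Kd,
    Y,
    gamma_c2: float = 0.01,
    gamma_d2: float = 0.01,
    beta_c: float = 0.3,
    beta_d: float = 0.3,
):
    """Graph-Laplacian regularized least squares on each side, averaged.

    Each side blends the supplied similarity with the profile-linkage matrix
    Y Y^T (weight gamma), then solves F = W (W + beta L)^-1 Y with L the
    normalized Laplacian of W. beta = 0 degenerates to returning Y when W is
    invertible (least-squares fallback otherwise).
    """
    kc, kd = _kernel_values(Kc), _kernel_values(Kd)
    V = _label_values(Y)

    def side(S: np.ndarray, gamma: float, beta: float, labels: np.ndarray) -> np.ndarray:
        W = (S + gamma * (labels @ labels.T)) / (1.0 + gamma)
        L = _normalized_laplacian(W)
        A = W + beta * L
        try:
            X = np.linalg.solve(A, labels)
        except np.linalg.LinAlgError:
            X = np.linalg.lstsq(A, labels, rcond=None)[0]
        return W @ X

    Fc = side(kc, gamma_c2, beta_c, V)
    Fd = side(kd, gamma_d2, beta_d, V.T).T
    return _wrap(Y, (Fc + Fd) / 2.0)


def heterogeneous_adjacency(Y, Kc=None, Kd=None) -> np.ndarray:
    """Symmetric block adjacency [[Sc, Y], [Y^T, Sd]] (zero diagonal blocks
    when similarities are not supplied); node order is rows then columns."""
    V = _label_values(Y)
    nc, nd = V.shape
    A = np.zeros((nc + nd, nc + nd))
    A[:nc, nc:] = V
    A[nc:, :nc] = V.T
    if Kc is not None:
        A[:nc, :nc] = _kernel_values(Kc)
    if Kd is not None:
        A[nc:, nc:] = _kernel_values(Kd)
    return A


def katz(
    Y,
    Kc=None,
    Kd=None,
    beta: float = 0.01,
    max_length: int | None = 4,
    augment: bool = True,
):
    """Walk-count scoring: sum over lengths l of beta^l A^l on the
    heterogeneous adjacency; the bipartite block is returned.

    ``max_length=None`` uses the closed form (I - beta A)^-1 - I, valid only
    when beta * spectral_radius(A) < 1.
    """
    V = _label_values(Y)
    nc, nd = V.shape
    A = heterogeneous_adjacency(Y, Kc if augment else None, Kd if augment else None)
    if max_length is None:
        rho = float(np.max(np.abs(np.linalg.eigvals(A))))
        if beta * rho >= 1.0:
            raise ValueError(
                f"KATZ closed form diverges: beta * spectral_radius = {beta * rho:.3f} >= 1"
            )
        S = np.linalg.inv(np.eye(nc + nd) - beta * A) - np.eye(nc + nd)
    else:
        S = np.zeros_like(A)
        P = np.eye(nc + nd)
        for _ in range(max_length):
            P = P @ (beta * A)
            S += P
    return _wrap(Y, S[:nc, nc:])


def nbi(Y):
    """Two-phase resource allocation on the bipartite graph alone:
    Yhat = Y W with W(j, v) = sum_i Y(i,j) Y(i,v) / (deg(d_j) deg(c_i));
    zero-degree terms contribute nothing."""
    V = _label_values(Y)
    kc = V.sum(axis=1)  # row degrees
    kd = V.sum(axis=0)  # column degrees
    with np.errstate(divide="ignore"):
        kc_inv = np.where(kc > 0, 1.0 / kc, 0.0)
        kd_inv = np.where(kd > 0, 1.0 / kd, 0.0)
    W = (kd_inv[:, None] * V.T) @ (kc_inv[:, None] * V)
    return _wrap(Y, V @ W)


def wp(Kc, Kd, Y):
    """Weighted-profile recommendation: each score is the mean of the two
    similarity-weighted label averages (self-weights excluded); a side with
    zero similarity mass contributes 0."""
    kc, kd = _kernel_values(Kc), _kernel_values(Kd)
    V = _label_values(Y)
    kc0 = kc - np.diag(np.diag(kc))
    kd0 = kd - np.diag(np.diag(kd))
    rmass = kc0.sum(axis=1)
    cmass = kd0.sum(axis=1)
    with np.errstate(divide="ignore"):
        rinv = np.where(rmass > 0, 1.0 / rmass, 0.0)
        cinv = np.where(cmass > 0, 1.0 / cmass, 0.0)
    row_part = rinv[:, None] * (kc0 @ V)
    col_part = (cinv[:, None] * (kd0 @ V.T)).T
    return _wrap(Y, (row_part + col_part) / 2.0)
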