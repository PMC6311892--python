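"""Kronecker-product-kernel regularized least squares.

Two routes solve the same linear system ``vec(Yhat^T) = K (K + sigma I)^-1
vec(Y^T)`` with ``K = Kc (x) Kd``:

* :func:`solve_naive` materializes the Kronecker product — an oracle for small
  instances only;
* :func:`solve_eigen` uses the per-side eigendecompositions and an elementwise
  spectral filter ``lambda / (lambda + sigma)``, never forming the
  ``N_c N_d x N_c N_d`` system.

The vec convention is column stacking, so ``vec(Y^T)`` enumerates Y row by
row and matches the ``(i, j)`` pair ordering of ``Kc (x) Kd``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coldstart import augment_matrix
from .io import AssociationMatrix, PredictionMatrix, RunConfig
from .similarity import KernelMatrix, gip_kernel, integrate_disease_similarity

__all__ = [
    "EigenFactorization",
    "NAIVE_PAIR_LIMIT",
    "solve_naive",
    "eigendecompose",
    "solve_eigen",
    "predict",
    "build_kernels",
]

NAIVE_PAIR_LIMIT = 4096


def _kernel_values(K: KernelMatrix | np.ndarray) -> np.ndarray:
    v = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("kernel must be a square matrix")
    return v


def _label_values(Y: AssociationMatrix | np.ndarray) -> np.ndarray:
    return Y.values if isinstance(Y, AssociationMatrix) else np.asarray(Y, dtype=float)


def _wrap(Y, scores: np.ndarray) -> PredictionMatrix | np.ndarray:
    if isinstance(Y, AssociationMatrix):
        return PredictionMatrix(Y.row_ids, Y.col_ids, scores)
    return scores


def solve_naive(Kc, Kd, Y, sigma: float):
    """Closed-form solution via the explicit Kronecker product (test oracle).

    Guarded to at most ``NAIVE_PAIR_LIMIT`` pairs; use :func:`solve_eigen` for
    anything larger.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    kc, kd = _kernel_values(Kc), _kernel_values(Kd)
    V = _label_values(Y)
    nc, nd = kc.shape[0], kd.shape[0]
    if V.shape != (nc, nd):
        raise ValueError("label matrix shape does not match kernels")
    if nc * nd > NAIVE_PAIR_LIMIT:
        raise ValueError(
            f"{nc * nd} pairs exceed the naive-solver guard ({NAIVE_PAIR_LIMIT}); use solve_eigen"
        )
    K = np.kron(kc, kd)
    rhs = V.reshape(-1)  # row-major flatten == column-stacked vec(Y^T)
    sol = K @ np.linalg.solve(K + sigma * np.eye(nc * nd), rhs)
    return _wrap(Y, sol.reshape(nc, nd))


@dataclass
class EigenFactorization:
    """Per-side eigendecompositions of the two (symmetrized) kernels."""

    eigvec_c: np.ndarray
    eigval_c: np.ndarray
    eigvec_d: np.ndarray
    eigval_d: np.ndarray

    def __post_init__(self) -> None:
        for V in (self.eigvec_c, self.eigvec_d):
            n = V.shape[0]
            if np.abs(V.T @ V - np.eye(n)).max() > 1e-8:
                raise ValueError("eigenvector matrix is not orthogonal within 1e-8")


def eigendecompose(Kc, Kd) -> EigenFactorization:
    """Symmetric eigendecomposition of both kernels, symmetrized as (K+K^T)/2.

    Reconstruction is verified to 1e-8 in the max norm.
    """
    kc, kd = _kernel_values(Kc), _kernel_values(Kd)
    kc = (kc + kc.T) / 2.0
    kd = (kd + kd.T) / 2.0
    lc, Vc = np.linalg.eigh(kc)
    ld, Vd = np.linalg.eigh(kd)
    for K, lam, V in ((kc, lc, Vc), (kd, ld, Vd)):
        resid = np.abs(K - (V * lam) @ V.T).max()
        if resid > 1e-8:
            raise ValueError(f"eigendecomposition reconstruction residual {resid:.2e} > 1e-8")
    return EigenFactorization(Vc, lc, Vd, ld)


def solve_eigen(ef: EigenFactorization, Y, sigma: float):
    """Spectral-filter solution: Yhat = Vc (F * (Vc^T Y Vd)) Vd^T with
    F_ij = (lc_i ld_j) / (lc_i ld_j + sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    V = _label_values(Y)
    lam = np.outer(ef.eigval_c, ef.eigval_d)
    denom = lam + sigma
    bad = np.abs(denom) < 1e-12
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"near-singular spectral filter: eigenvalue product at (c={i}, d={j}) is within 1e-12 of -sigma"
        )
    M = ef.eigvec_c.T @ V @ ef.eigvec_d
    scores = ef.eigvec_c @ ((lam / denom) * M) @ ef.eigvec_d.T
    return _wrap(Y, scores)


def build_kernels(
    Y: AssociationMatrix,
    config: RunConfig,
    semantic: KernelMatrix | None = None,
) -> tuple[KernelMatrix, KernelMatrix]:
    """GIP kernels from the binary training matrix; the disease side is
    integrated with an optional precomputed semantic kernel."""
    Sc = gip_kernel(Y, "rows")
    Gd = gip_kernel(Y, "cols")
    Sd = integrate_disease_similarity(Gd, semantic, config.disease_sim_mode)
    return Sc, Sd


def predict(
    Y: AssociationMatrix,
    Sc: KernelMatrix,
    Sd: KernelMatrix,
    config: RunConfig,
) -> PredictionMatrix:
    """Full pipeline step: cold-start augmentation then spectral-filter RLS."""
    Y_aug = augment_matrix(Y, Sc, Sd, config.epsilon)
    ef = eigendecompose(Sc, Sd)
    return solve_eigen(ef, Y_aug, config.sigma)
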