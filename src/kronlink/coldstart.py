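"""Cold-start initialization by decreasing-weight k-nearest-neighbor averaging.

Entities whose training profile is all zero ("new" rows/columns) receive
initial scores equal to the similarity-weighted mean of their neighbors'
labels, with the neighbor count k chosen from a similarity-ranked list by an
epsilon-controlled admission rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import AssociationMatrix
from .similarity import KernelMatrix

__all__ = ["NeighborList", "rank_neighbors", "select_k", "dwnn_score", "augment_matrix"]


@dataclass
class NeighborList:
    """Similarity-ranked neighbors of one entity (self excluded)."""

    entity_id: str
    ranked_neighbors: list[tuple[str, float]]
    k_selected: int = 0

    def __post_init__(self) -> None:
        sims = [s for _, s in self.ranked_neighbors]
        if any(a < b for a, b in zip(sims, sims[1:])):
            raise ValueError("ranked_neighbors similarities must be non-increasing")
        if not 0 <= self.k_selected <= len(self.ranked_neighbors):
            raise ValueError("k_selected out of range")


def rank_neighbors(kernel: KernelMatrix, index: int) -> NeighborList:
    """Neighbors of entity ``index`` ranked by similarity descending; ties
    broken by id order for determinism."""
    sims = kernel.values[index]
    order = sorted((i for i in range(kernel.n) if i != index), key=lambda i: (-sims[i], i))
    return NeighborList(kernel.ids[index], [(kernel.ids[i], float(sims[i])) for i in order])


def select_k(ranked_sims: Sequence[float], epsilon: float) -> int:
    """Largest k such that (1 - sim_l)/l <= epsilon**l for every rank l = 1..k.

    With epsilon = 1 the bound is 1 at every rank, so all neighbors pass.
    """
    if not 0.0 < epsilon <= 1.0:
        raise ValueError("epsilon must be in (0, 1]")
    sims = list(ranked_sims)
    if any(a < b for a, b in zip(sims, sims[1:])):
        raise ValueError("ranked similarities must be sorted non-increasing")
    k = 0
    for l, s in enumerate(sims, start=1):
        if (1.0 - s) / l <= epsilon**l:
            k = l
        else:
            break
    return k


def dwnn_score(
    neighbor_sims: Sequence[float], neighbor_labels: Sequence[float], k: int
) -> float:
    """Similarity-weighted mean of the top-k neighbors' labels."""
    sims = np.asarray(neighbor_sims, dtype=float)
    labels = np.asarray(neighbor_labels, dtype=float)
    if sims.shape != labels.shape:
        raise ValueError("neighbor similarity and label vectors are misaligned")
    if k > sims.size:
        raise ValueError("k exceeds neighbor count")
    mass = sims[:k].sum()
    if k == 0 or mass <= 0.0:
        warnings.warn("cold-start score undefined (no neighbor mass); returning 0", stacklevel=2)
        return 0.0
    return float(sims[:k] @ labels[:k] / mass)


def _estimates(Y: np.ndarray, kernel: np.ndarray, new_idx: np.ndarray, epsilon: float) -> np.ndarray:
    """Row-side score estimates for each new row (kernel over rows of Y)."""
    out = np.zeros((new_idx.size, Y.shape[1]))
    n = kernel.shape[0]
    for r, i in enumerate(new_idx):
        order = sorted((u for u in range(n) if u != i), key=lambda u: (-kernel[i, u], u))
        sims = kernel[i, order]
        k = select_k(sims, epsilon)
        mass = sims[:k].sum()
        if k == 0 or mass <= 0.0:
            continue
        out[r] = sims[:k] @ Y[order[:k], :] / mass
    return out


def augment_matrix(
    Y: AssociationMatrix, Sc: KernelMatrix, Sd: KernelMatrix, epsilon: float = 1.0
) -> AssociationMatrix:
    """Replace all-zero rows/columns of a binary matrix with cold-start scores.

    New rows use row-side similarities, new columns use column-side
    similarities, entries that are both-new take the mean of the two
    estimates. All other entries are bit-preserved.
    """
    if not Y.binary:
        raise ValueError("augmentation expects a binary association matrix")
    if Sc.ids != Y.row_ids or Sd.ids != Y.col_ids:
        raise ValueError("kernel labels do not match association matrix labels")
    V = Y.values
    new_rows = np.flatnonzero(V.sum(axis=1) == 0)
    new_cols = np.flatnonzero(V.sum(axis=0) == 0)
    if new_rows.size == 0 and new_cols.size == 0:
        return AssociationMatrix(Y.row_ids, Y.col_ids, V.copy(), binary=True)

    out = V.astype(float).copy()
    R = _estimates(V, Sc.values, new_rows, epsilon)
    C = _estimates(V.T, Sd.values, new_cols, epsilon).T  # shape (n_rows, n_new_cols)
    if new_rows.size:
        out[new_rows, :] = R
    if new_cols.size:
        out[:, new_cols] = C
    if new_rows.size and new_cols.size:
        out[np.ix_(new_rows, new_cols)] = (
            R[:, new_cols] + C[new_rows, :]
        ) / 2.0
    return AssociationMatrix(Y.row_ids, Y.col_ids, out, binary=False)
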