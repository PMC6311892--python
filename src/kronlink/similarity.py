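"""Similarity kernels: Gaussian interaction-profile (GIP) kernels for both
entity sets, DAG-based semantic similarity for diseases, and their integration.

GIP kernels are always computed from the *binary* training matrix. The GIP
bandwidth is the reciprocal of the mean squared profile norm, i.e. for binary
profiles the reciprocal of the average number of associations per entity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import AssociationMatrix, DiseaseDAG

__all__ = [
    "KernelMatrix",
    "SemanticProfile",
    "gip_bandwidth",
    "gip_kernel",
    "semantic_profile",
    "semantic_similarity",
    "disease_semantic_matrix",
    "integrate_disease_similarity",
]

KERNEL_KINDS = ("gip_circ", "gip_disease", "semantic", "integrated")


@dataclass
class KernelMatrix:
    """Symmetric labeled similarity matrix over one entity set.

    ``semantic`` kernels may contain NaN where a disease is unmapped; all
    defined entries lie in [0, 1].
    """

    ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kernel kind must be one of {KERNEL_KINDS}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kernel shape {self.values.shape} does not match {n} ids")
        defined = np.isfinite(self.values)
        if self.kind != "semantic" and not defined.all():
            raise ValueError("only semantic kernels may contain missing entries")
        if not (defined == defined.T).all() or np.nanmax(np.abs(self.values - self.values.T), initial=0.0) > 1e-12:
            raise ValueError("kernel matrix is not symmetric")
        vals = self.values[defined]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1.0 + 1e-12):
            raise ValueError("kernel entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class SemanticProfile:
    """Decayed ancestor contributions of one DAG term."""

    term: str
    sv: dict[str, float]
    sem_total: float


def _profiles(Y: AssociationMatrix, axis: str) -> np.ndarray:
    if axis == "rows":
        return Y.values
    if axis == "cols":
        return Y.values.T
    raise ValueError("axis must be 'rows' or 'cols'")


def gip_bandwidth(Y: AssociationMatrix, axis: str) -> float:
    """Kernel bandwidth: reciprocal of the mean squared profile norm.

    For a binary matrix this is the reciprocal of the average number of
    associations per row (axis='rows') or per column (axis='cols').
    """
    P = _profiles(Y, axis)
    mean_sq = float((P**2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError("no associations; bandwidth undefined")
    return 1.0 / mean_sq


def gip_kernel(Y: AssociationMatrix, axis: str) -> KernelMatrix:
    """Gaussian interaction-profile kernel K(i,j) = exp(-gamma * ||p_i - p_j||^2)."""
    gamma = gip_bandwidth(Y, axis)
    P = _profiles(Y, axis)
    if P.shape[0] > 1:
        sqdist = squareform(pdist(P, metric="sqeuclidean"))
    else:
        sqdist = np.zeros((1, 1))
    K = np.exp(-gamma * sqdist)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    ids = Y.row_ids if axis == "rows" else Y.col_ids
    kind = "gip_circ" if axis == "rows" else "gip_disease"
    return KernelMatrix(ids, K, kind)


def semantic_profile(dag: DiseaseDAG, term: str, delta: float) -> SemanticProfile:
    """Semantic value of each ancestor of ``term``: delta**w where w is the
    shortest child->parent path length, 1 for the term itself."""
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    depths = dag.ancestor_depths(term)
    sv = {t: delta**w for t, w in depths.items()}
    return SemanticProfile(term, sv, float(sum(sv.values())))


def semantic_similarity(dag: DiseaseDAG, a_term: str, b_term: str, delta: float) -> float:
    """Shared-ancestor similarity: sum of both terms' semantic values over
    common ancestors, normalized by the two total semantic values."""
    pa = semantic_profile(dag, a_term, delta)
    pb = semantic_profile(dag, b_term, delta)
    common = pa.sv.keys() & pb.sv.keys()
    num = sum(pa.sv[t] + pb.sv[t] for t in common)
    return num / (pa.sem_total + pb.sem_total)


def disease_semantic_matrix(
    dag: DiseaseDAG,
    col_ids: list[str],
    entity_to_terms: dict[str, tuple[str, ...]] | None = None,
    delta: float = 0.5,
) -> KernelMatrix:
    """Pairwise disease semantic similarity; multi-term diseases take the max
    over term pairs, unmapped diseases yield NaN entries."""
    mapping = entity_to_terms if entity_to_terms is not None else dag.entity_to_terms
    n = len(col_ids)
    M = np.full((n, n), np.nan)
    profiles: dict[str, SemanticProfile] = {}

    def prof(t: str) -> SemanticProfile:
        if t not in profiles:
            profiles[t] = semantic_profile(dag, t, delta)
        return profiles[t]

    terms = [tuple(mapping.get(c, ())) for c in col_ids]
    for i in range(n):
        if not terms[i]:
            continue
        M[i, i] = 1.0
        for j in range(i + 1, n):
            if not terms[j]:
                continue
            best = 0.0
            for ta in terms[i]:
                pa = prof(ta)
                for tb in terms[j]:
                    pb = prof(tb)
                    common = pa.sv.keys() & pb.sv.keys()
                    num = sum(pa.sv[t] + pb.sv[t] for t in common)
                    best = max(best, num / (pa.sem_total + pb.sem_total))
            M[i, j] = M[j, i] = best
    return KernelMatrix(col_ids, M, "semantic")


def integrate_disease_similarity(
    gip: KernelMatrix, sem: KernelMatrix | None, mode: str = "mean_gip_semantic"
) -> KernelMatrix:
    """Final disease similarity: elementwise mean of GIP and semantic where the
    semantic entry is defined, the GIP value elsewhere; or GIP alone."""
    if mode == "gip_only" or sem is None:
        return KernelMatrix(gip.ids, gip.values.copy(), "integrated")
    if mode != "mean_gip_semantic":
        raise ValueError(f"unknown disease similarity mode {mode!r}")
    if gip.ids != sem.ids:
        raise ValueError("GIP and semantic kernels have mismatched ids")
    out = gip.values.copy()
    defined = np.isfinite(sem.values)
    out[defined] = (gip.values[defined] + sem.values[defined]) / 2.0
    return KernelMatrix(gip.ids, out, "integrated")
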