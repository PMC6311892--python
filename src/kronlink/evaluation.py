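"""Cross-validation over known positive pairs and rank-based AUC.

Protocol: the known positives are partitioned into folds; each fold is masked
to zero in the training matrix, the predictor is run on the training matrix
only, and the held-out positives are ranked against *all* pairs that are zero
in the full matrix. One ROC/AUC is computed per repeat by pooling every
fold's test scores of that repeat; results aggregate as mean +/- sd across
repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .io import AssociationMatrix, PredictionMatrix, RunConfig

__all__ = ["CVPlan", "EvalResult", "Predictor", "make_cv_plan", "mask_fold", "run_fold", "auc", "evaluate"]

Predictor = Callable[[AssociationMatrix], PredictionMatrix]

_FOLD_COUNTS = {"5CV": 5, "10CV": 10}


@dataclass
class CVPlan:
    scheme: str
    folds: list[list[tuple[str, str]]]
    repeat_index: int
    seed: int

    def all_pairs(self) -> set[tuple[str, str]]:
        return {p for fold in self.folds for p in fold}


@dataclass
class EvalResult:
    scheme: str
    predictor_name: str
    auc_per_repeat: list[float]
    seeds: list[int] = field(default_factory=list)

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.auc_per_repeat))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.auc_per_repeat, ddof=1)) if len(self.auc_per_repeat) > 1 else 0.0


def make_cv_plan(
    Y: AssociationMatrix, scheme: str, n_repeats: int = 10, seed: int = 0
) -> list[CVPlan]:
    """Seeded fold assignments over the known positives.

    k-fold: positives are shuffled (repeat r uses seed+r) and dealt round-robin,
    so fold sizes differ by at most one. LOOCV is deterministic: a single plan
    with one positive per fold, in matrix order.
    """
    positives = Y.positives()
    if scheme == "LOOCV":
        return [CVPlan("LOOCV", [[p] for p in positives], 0, seed)]
    if scheme not in _FOLD_COUNTS:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    k = _FOLD_COUNTS[scheme]
    if len(positives) < k:
        raise ValueError(f"{len(positives)} positives is fewer than {k} folds")
    plans = []
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(len(positives))
        folds: list[list[tuple[str, str]]] = [[] for _ in range(k)]
        for pos, idx in enumerate(perm):
            folds[pos % k].append(positives[idx])
        plans.append(CVPlan(scheme, folds, r, seed + r))
    return plans


def mask_fold(Y: AssociationMatrix, pairs: Sequence[tuple[str, str]]) -> AssociationMatrix:
    """Training matrix for one fold: held-out entries forced to zero.

    The original values of the masked cells never reach the predictor, which
    is what the no-leakage property tests pin down.
    """
    return Y.masked(pairs)


def run_fold(
    Y: AssociationMatrix,
    plan: CVPlan,
    fold_index: int,
    predictor: Predictor,
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and 0/1 labels for one fold's evaluation pair set.

    Evaluation pairs = held-out positives (label 1) plus every pair that is 0
    in the full matrix (label 0); training positives are excluded from the
    ranking.
    """
    fold = plan.folds[fold_index]
    train = mask_fold(Y, fold)
    try:
        pm = predictor(train)
    except Exception as e:
        raise RuntimeError(
            f"predictor failed on {plan.scheme} repeat {plan.repeat_index} fold {fold_index}: {e}"
        ) from e
    if pm.row_ids != Y.row_ids or pm.col_ids != Y.col_ids:
        raise ValueError("predictor returned misaligned labels")
    ridx = {r: i for i, r in enumerate(Y.row_ids)}
    cidx = {c: j for j, c in enumerate(Y.col_ids)}
    neg_i, neg_j = np.nonzero(Y.values == 0)
    pos_i = np.array([ridx[r] for r, _ in fold], dtype=int)
    pos_j = np.array([cidx[c] for _, c in fold], dtype=int)
    scores = np.concatenate([pm.scores[pos_i, pos_j], pm.scores[neg_i, neg_j]])
    labels = np.concatenate([np.ones(len(fold)), np.zeros(neg_i.size)])
    return scores, labels


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC with mid-rank handling of ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks for ties
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(
    Y: AssociationMatrix,
    predictor: Predictor,
    scheme: str,
    config: RunConfig | None = None,
    n_repeats: int | None = None,
    predictor_name: str = "predictor",
) -> EvalResult:
    """Repeated cross-validation; AUC pooled across folds within each repeat."""
    config = config or RunConfig()
    n_repeats = n_repeats if n_repeats is not None else config.n_repeats
    plans = make_cv_plan(Y, scheme, n_repeats=n_repeats, seed=config.seed)
    aucs, seeds = [], []
    for plan in plans:
        scores_all, labels_all = [], []
        for f in range(len(plan.folds)):
            s, l = run_fold(Y, plan, f, predictor)
            scores_all.append(s)
            labels_all.append(l)
        aucs.append(auc(np.concatenate(scores_all), np.concatenate(labels_all)))
        seeds.append(plan.seed)
    return EvalResult(scheme, predictor_name, aucs, seeds)
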