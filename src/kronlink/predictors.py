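"""Named predictor factory: every method takes a binary training matrix and
returns an aligned score matrix, so the CV harness and CLI can treat them
uniformly. Kernels are rebuilt from each training matrix; the disease
semantic kernel (independent of the labels) is precomputed once and reused.
"""

from __future__ import annotations

from typing import Callable

from . import baselines, kronrls
from .io import AssociationMatrix, PredictionMatrix, RunConfig
from .similarity import KernelMatrix

__all__ = ["METHODS", "make_predictor"]

METHODS = ("wknn-kronrls", "rls-avg", "rls-kron", "netlaprls", "katz", "nbi", "wp")


def make_predictor(
    method: str,
    config: RunConfig | None = None,
    semantic: KernelMatrix | None = None,
    **kwargs,
) -> Callable[[AssociationMatrix], PredictionMatrix]:
    """Build a predictor closure for one of :data:`METHODS`.

    ``semantic`` is the optional precomputed disease semantic kernel used by
    the mean-integration mode; ``kwargs`` pass method-specific hyperparameters
    (e.g. ``beta``/``max_length`` for katz).
    """
    config = config or RunConfig()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")

    def predictor(train: AssociationMatrix) -> PredictionMatrix:
        if method == "nbi":
            return baselines.nbi(train)
        Sc, Sd = kronrls.build_kernels(train, config, semantic)
        if method == "wknn-kronrls":
            return kronrls.predict(train, Sc, Sd, config)
        if method == "rls-kron":
            return baselines.rls_kron(Sc, Sd, train, config.sigma)
        if method == "rls-avg":
            return baselines.rls_avg(Sc, Sd, train, config.sigma)
        if method == "netlaprls":
            return baselines.netlaprls(Sc, Sd, train, **kwargs)
        if method == "katz":
            return baselines.katz(train, Sc, Sd, **kwargs)
        if method == "wp":
            return baselines.wp(Sc, Sd, train)
        raise AssertionError("unreachable")

    predictor.__name__ = method
    return predictor
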