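"""Seeded synthetic benchmark generator: block-structured bipartite
associations plus a random rooted ontology DAG whose layout is correlated
with the planted blocks, so both the profile-kernel signal and the semantic
signal are learnable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix, DiseaseDAG

__all__ = ["SyntheticSpec", "generate_associations", "generate_dag", "generate_dataset"]


@dataclass
class SyntheticSpec:
    n_circ: int = 60
    n_disease: int = 40
    n_blocks: int = 3
    within_block_prob: float = 0.3
    between_block_prob: float = 0.02
    dag_branching: int = 2
    dag_depth: int = 3
    second_parent_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_circ < 1 or self.n_disease < 1:
            raise ValueError("entity counts must be positive")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        for p in (self.within_block_prob, self.between_block_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.within_block_prob <= self.between_block_prob:
            raise ValueError("within_block_prob must exceed between_block_prob (planted signal)")
        if self.dag_branching < 1 or self.dag_depth < 1:
            raise ValueError("dag_branching and dag_depth must be >= 1")
        if not 0.0 <= self.second_parent_frac <= 1.0:
            raise ValueError("second_parent_frac must lie in [0, 1]")


def _block_labels(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    # shared sub-stream so the association and DAG generators agree on blocks
    rng = np.random.default_rng([spec.seed, 0])
    circ = rng.integers(0, spec.n_blocks, size=spec.n_circ)
    disease = rng.integers(0, spec.n_blocks, size=spec.n_disease)
    return circ, disease


def generate_associations(spec: SyntheticSpec) -> tuple[AssociationMatrix, dict[str, np.ndarray]]:
    """Bernoulli block-model association matrix plus the latent block labels."""
    circ_blocks, dis_blocks = _block_labels(spec)
    row_ids = [f"c{i:04d}" for i in range(spec.n_circ)]
    col_ids = [f"d{j:04d}" for j in range(spec.n_disease)]
    same = circ_blocks[:, None] == dis_blocks[None, :]
    probs = np.where(same, spec.within_block_prob, spec.between_block_prob)
    for attempt in range(100):
        rng = np.random.default_rng([spec.seed, 1, attempt])
        values = (rng.random(probs.shape) < probs).astype(float)
        if values.sum() > 0:
            break
    else:
        raise ValueError("could not generate a nonzero association matrix; raise the probabilities")
    am = AssociationMatrix(row_ids, col_ids, values)
    return am, {"circ_blocks": circ_blocks, "disease_blocks": dis_blocks}


def generate_dag(spec: SyntheticSpec) -> tuple[DiseaseDAG, dict[str, tuple[str, ...]]]:
    """Rooted block-correlated DAG over generic terms plus a disease->term map.

    One anchor term per block hangs off the root; each anchor carries a
    complete ``dag_branching``-ary subtree of depth ``dag_depth - 1``. A
    fraction of non-anchor nodes receive a second parent from a strictly
    shallower layer (keeping the graph acyclic). Diseases map to a uniform
    term inside their block's subtree, so same-block diseases share a recent
    ancestor.
    """
    _, dis_blocks = _block_labels(spec)
    rng = np.random.default_rng([spec.seed, 2])
    root = "T_root"
    edges: set[tuple[str, str]] = set()
    depth_of: dict[str, int] = {root: 0}
    block_nodes: list[list[str]] = []
    for b in range(spec.n_blocks):
        anchor = f"T{b}"
        edges.add((anchor, root))
        depth_of[anchor] = 1
        nodes = [anchor]
        frontier = [anchor]
        for level in range(2, spec.dag_depth + 1):
            nxt = []
            for parent in frontier:
                for c in range(spec.dag_branching):
                    child = f"{parent}.{c}"
                    edges.add((child, parent))
                    depth_of[child] = level
                    nodes.append(child)
                    nxt.append(child)
            frontier = nxt
        block_nodes.append(nodes)

    all_nodes = [root] + [n for nodes in block_nodes for n in nodes]
    # second parents from strictly shallower layers preserve acyclicity
    candidates = [n for n in all_nodes if depth_of[n] >= 2]
    n_extra = int(round(spec.second_parent_frac * len(candidates)))
    if n_extra and candidates:
        chosen = rng.choice(len(candidates), size=n_extra, replace=False)
        for ci in chosen:
            child = candidates[ci]
            shallower = [n for n in all_nodes if depth_of[n] < depth_of[child] and (child, n) not in edges]
            if shallower:
                edges.add((child, shallower[rng.integers(len(shallower))]))

    mapping: dict[str, tuple[str, ...]] = {}
    for j, b in enumerate(dis_blocks):
        nodes = block_nodes[int(b)]
        mapping[f"d{j:04d}"] = (nodes[rng.integers(len(nodes))],)
    dag = DiseaseDAG(set(all_nodes), edges, mapping)
    return dag, mapping


def generate_dataset(spec: SyntheticSpec):
    """Convenience bundle: (AssociationMatrix, DiseaseDAG, mapping, block labels)."""
    am, labels = generate_associations(spec)
    dag, mapping = generate_dag(spec)
    return am, dag, mapping, labels
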