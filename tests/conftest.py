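import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from kronlink.io import AssociationMatrix, DiseaseDAG, RunConfig
from kronlink.similarity import disease_semantic_matrix
from kronlink.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def toy_Y():
    """3x2 worked example: row norms 1,1,2 -> gamma_rows=0.75; col norms 2,2 -> gamma_cols=0.5."""
    return AssociationMatrix(["c1", "c2", "c3"], ["d1", "d2"], [[1, 0], [0, 1], [1, 1]])


@pytest.fixture
def chain_dag():
    """B -> A (B child of root A)."""
    return DiseaseDAG({"A", "B"}, {("B", "A")})


@pytest.fixture
def sibling_dag():
    """A and B both children of root R."""
    return DiseaseDAG({"A", "B", "R"}, {("A", "R"), ("B", "R")})


@pytest.fixture
def diamond_dag():
    """X -> {P, Q} -> R: two paths of length 2 from X to R."""
    return DiseaseDAG(
        {"X", "P", "Q", "R"}, {("X", "P"), ("X", "Q"), ("P", "R"), ("Q", "R")}
    )


@pytest.fixture(scope="session")
def synth():
    """Small structured dataset shared across tests (60x40, 3 blocks)."""
    spec = SyntheticSpec(seed=0)
    Y, dag, mapping, labels = generate_dataset(spec)
    sem = disease_semantic_matrix(dag, Y.col_ids, mapping, 0.5)
    return {"spec": spec, "Y": Y, "dag": dag, "mapping": mapping, "labels": labels, "sem": sem}


@pytest.fixture
def default_config():
    return RunConfig()


def random_binary(rng, n, m, p=0.4, ensure_nonzero=True):
    V = (rng.random((n, m)) < p).astype(float)
    if ensure_nonzero and V.sum() == 0:
        V[rng.integers(n), rng.integers(m)] = 1.0
    return V


def random_association(rng, n, m, p=0.4):
    return AssociationMatrix(
        [f"r{i}" for i in range(n)], [f"s{j}" for j in range(m)], random_binary(rng, n, m, p)
    )
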