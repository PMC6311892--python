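"""Reading and writing of association tables, ontology DAGs, predictions and run configs.

All label/alignment invariants that downstream modules rely on are enforced
here: identifiers are opaque case-sensitive strings, kept in first-appearance
order, with no duplicates.
"""

from __future__ import annotations

import graphlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AssociationMatrix",
    "DiseaseDAG",
    "PredictionMatrix",
    "RunConfig",
    "read_associations",
    "write_associations_dense",
    "read_dag",
    "read_mapping",
    "write_predictions",
]

CV_SCHEMES = ("5CV", "10CV", "LOOCV")
DISEASE_SIM_MODES = ("gip_only", "mean_gip_semantic")


class ParseError(ValueError):
    """Raised on malformed input files; carries the offending line number."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise ValueError(f"duplicate {what} identifier: {x!r}")
            seen.add(x)


@dataclass
class AssociationMatrix:
    """Labeled bipartite association matrix.

    ``values`` is an ``(len(row_ids), len(col_ids))`` array; entries are
    strictly {0, 1} when ``binary`` is true, and in [0, 1] otherwise (after
    cold-start augmentation).
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    binary: bool = True

    def __post_init__(self) -> None:
        self.row_ids = list(self.row_ids)
        self.col_ids = list(self.col_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.row_ids)}, {len(self.col_ids)}) labels"
            )
        if self.binary:
            if not np.isin(self.values, (0.0, 1.0)).all():
                bad = self.values[~np.isin(self.values, (0.0, 1.0))].flat[0]
                raise ValueError(f"binary association matrix contains non-binary entry {bad!r}")
        else:
            if not np.isfinite(self.values).all():
                raise ValueError("association matrix contains non-finite entries")
            if (self.values < 0).any() or (self.values > 1).any():
                raise ValueError("augmented association entries must lie in [0, 1]")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.col_ids)

    def row_index(self, row_id: str) -> int:
        return self.row_ids.index(row_id)

    def col_index(self, col_id: str) -> int:
        return self.col_ids.index(col_id)

    def positives(self) -> list[tuple[str, str]]:
        """Known positive pairs in row-major matrix order."""
        ii, jj = np.nonzero(self.values)
        return [(self.row_ids[i], self.col_ids[j]) for i, j in zip(ii, jj)]

    def masked(self, pairs: Iterable[tuple[str, str]]) -> "AssociationMatrix":
        """Copy with the given (row_id, col_id) entries set to 0."""
        v = self.values.copy()
        ridx = {r: i for i, r in enumerate(self.row_ids)}
        cidx = {c: j for j, c in enumerate(self.col_ids)}
        for r, c in pairs:
            v[ridx[r], cidx[c]] = 0.0
        return AssociationMatrix(self.row_ids, self.col_ids, v, binary=self.binary)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.row_ids, self.col_ids, self.values.copy(), self.binary)


@dataclass
class DiseaseDAG:
    """Rooted ontology DAG given as child->parent edges, plus an optional
    mapping from disease column ids to one or more DAG terms."""

    nodes: set[str]
    parent_edges: set[tuple[str, str]]
    entity_to_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        self.parent_edges = set(self.parent_edges)
        for child, parent in self.parent_edges:
            if parent not in self.nodes or child not in self.nodes:
                raise ValueError(f"edge ({child!r}, {parent!r}) references unknown node")
        for entity, terms in self.entity_to_terms.items():
            for t in terms:
                if t not in self.nodes:
                    raise ValueError(f"entity {entity!r} maps to unknown term {t!r}")
        self._assert_acyclic()
        self._parents: dict[str, list[str]] = {n: [] for n in self.nodes}
        for child, parent in sorted(self.parent_edges):
            self._parents[child].append(parent)

    def _assert_acyclic(self) -> None:
        ts: graphlib.TopologicalSorter = graphlib.TopologicalSorter()
        for n in self.nodes:
            ts.add(n)
        for child, parent in self.parent_edges:
            ts.add(child, parent)
        try:
            ts.prepare()
        except graphlib.CycleError as e:
            cycle = e.args[1]
            raise ValueError(f"DAG contains a directed cycle through node {cycle[0]!r}") from None

    def parents_of(self, term: str) -> list[str]:
        return self._parents[term]

    def ancestor_depths(self, term: str) -> dict[str, int]:
        """Shortest child->parent path length (in edges) from ``term`` to each
        ancestor, including ``term`` itself at depth 0 (breadth-first)."""
        if term not in self.nodes:
            raise KeyError(f"unknown DAG term {term!r}")
        depths = {term: 0}
        frontier = [term]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for node in frontier:
                for p in self._parents[node]:
                    if p not in depths:
                        depths[p] = d
                        nxt.append(p)
            frontier = nxt
        return depths


@dataclass
class PredictionMatrix:
    """Real-valued score matrix aligned with the AssociationMatrix it came from."""

    row_ids: list[str]
    col_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.row_ids = list(self.row_ids)
        self.col_ids = list(self.col_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")
        if self.scores.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("scores shape does not match labels")
        if not np.isfinite(self.scores).all():
            raise ValueError("prediction matrix contains non-finite entries")


@dataclass
class RunConfig:
    """Pipeline parameters with their documented defaults."""

    epsilon: float = 1.0
    sigma: float = 0.2
    delta: float = 0.5
    cv_scheme: str = "10CV"
    n_repeats: int = 10
    seed: int = 0
    disease_sim_mode: str = "mean_gip_semantic"

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon <= 1.0:
            raise ValueError("epsilon must be in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0, 1)")
        if self.cv_scheme not in CV_SCHEMES:
            raise ValueError(f"cv_scheme must be one of {CV_SCHEMES}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be a positive integer")
        if self.disease_sim_mode not in DISEASE_SIM_MODES:
            raise ValueError(f"disease_sim_mode must be one of {DISEASE_SIM_MODES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError(f"config file {path} must contain a mapping")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers


def _read_edge_list(path: str | Path, header: bool | None) -> AssociationMatrix:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty association file")
    parsed: list[tuple[str, str]] = []
    for lineno, ln in enumerate(lines, start=1):
        fields = ln.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected >=2 tab-separated fields, got {len(fields)}")
        parsed.append((fields[0], fields[1]))
    if header is None:
        # heuristic: first token of line 1 never reappears in column 1
        header = len(parsed) > 1 and all(parsed[0][0] != r for r, _ in parsed[1:])
    if header:
        parsed = parsed[1:]
        if not parsed:
            raise ParseError(f"{path}: association file contains only a header")
    rows = parsed

    row_ids: list[str] = []
    col_ids: list[str] = []
    rseen: dict[str, int] = {}
    cseen: dict[str, int] = {}
    for r, c in rows:
        if r not in rseen:
            rseen[r] = len(row_ids)
            row_ids.append(r)
        if c not in cseen:
            cseen[c] = len(col_ids)
            col_ids.append(c)
    values = np.zeros((len(row_ids), len(col_ids)))
    for r, c in rows:
        values[rseen[r], cseen[c]] = 1.0  # duplicates collapse
    return AssociationMatrix(row_ids, col_ids, values)


def _read_dense(path: str | Path) -> AssociationMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty association file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: dense association file has no data")
    values = df.to_numpy(dtype=float)
    if not np.isin(values, (0.0, 1.0)).all():
        bad = values[~np.isin(values, (0.0, 1.0))].flat[0]
        raise ParseError(f"{path}: dense association matrix has non-binary entry {bad!r}")
    return AssociationMatrix([str(r) for r in df.index], [str(c) for c in df.columns], values)


def read_associations(
    path: str | Path, format: str = "edge_list", header: bool | None = None
) -> AssociationMatrix:
    """Read a binary association table.

    ``format='edge_list'``: one ``row_id<TAB>col_id`` pair per line, duplicates
    collapsed, identifiers ordered by first appearance. An optional header line
    is auto-detected (its first token must not reoccur in column 1) unless
    ``header`` is given explicitly.

    ``format='dense'``: TSV with a header row of column ids and a first column
    of row ids; entries must be 0/1.
    """
    if format == "edge_list":
        am = _read_edge_list(path, header)
    elif format == "dense":
        am = _read_dense(path)
    else:
        raise ValueError(f"unknown association format {format!r}")
    if am.values.sum() == 0:
        raise ParseError(f"{path}: association matrix has no nonzero entries")
    return am


def write_associations_dense(am: AssociationMatrix, path: str | Path) -> None:
    df = pd.DataFrame(am.values, index=am.row_ids, columns=am.col_ids)
    df.to_csv(path, sep="\t", index_label="")


def read_dag(path: str | Path, entity_to_terms: Mapping[str, Sequence[str]] | None = None) -> DiseaseDAG:
    """Read a child<TAB>parent edge list into a validated DAG."""
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected child<TAB>parent")
            child, parent = fields[0], fields[1]
            edges.add((child, parent))
            nodes.update((child, parent))
    mapping = {k: tuple(v) for k, v in (entity_to_terms or {}).items()}
    return DiseaseDAG(nodes, edges, mapping)


def read_mapping(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read an entity<TAB>term mapping file; repeated entity lines accumulate terms."""
    mapping: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected entity<TAB>term")
            mapping.setdefault(fields[0], []).append(fields[1])
    return {k: tuple(dict.fromkeys(v)) for k, v in mapping.items()}


def ranked_predictions(
    pm: PredictionMatrix,
    top_k: int | None = None,
    exclude: AssociationMatrix | None = None,
) -> pd.DataFrame:
    """Ranked (row_id, col_id, score, rank) table, score-descending with
    lexicographic (row_id, col_id) tie breaking. ``exclude`` drops training
    positives from the ranking."""
    mask = np.ones_like(pm.scores, dtype=bool)
    if exclude is not None:
        if exclude.row_ids != pm.row_ids or exclude.col_ids != pm.col_ids:
            raise ValueError("exclusion matrix labels do not match prediction labels")
        mask &= exclude.values == 0
    records = [
        (pm.row_ids[i], pm.col_ids[j], pm.scores[i, j])
        for i, j in zip(*np.nonzero(mask))
    ]
    records.sort(key=lambda rec: (-rec[2], rec[0], rec[1]))
    if top_k is not None:
        records = records[:top_k]
    df = pd.DataFrame(records, columns=["row_id", "col_id", "score"])
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def write_predictions(
    pm: PredictionMatrix,
    path: str | Path,
    top_k: int | None = None,
    exclude: AssociationMatrix | None = None,
) -> None:
    ranked_predictions(pm, top_k=top_k, exclude=exclude).to_csv(path, sep="\t", index=False)
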