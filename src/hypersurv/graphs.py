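"""Population-graph construction.

Two named hyperedge groups are supported and concatenated column-wise into a
single incidence matrix: (i) pairwise edges from the encoder's similarity
matrix (one 2-node hyperedge per pair above a threshold, weighted by the
similarity) and (ii) k-nearest-neighbour hyperedges in the standardized
radiomics space (one hyperedge per node: the node plus its k neighbours,
weight 1).  An unsupervised comparator network is also provided: Gower
mixed-type distance on the raw clinical table thresholded at an ε-radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial.distance import squareform, pdist

from .cohort import CATEGORY_LEVELS, MISSING
from .pae import SimilarityMatrix
from .radiomics import FeatureMatrix

__all__ = [
    "HyperedgeGroup",
    "Hypergraph",
    "GowerSpec",
    "pae_edge_group",
    "adjacency_edge_group",
    "knn_hyperedge_group",
    "assemble_hypergraph",
    "default_gower_spec",
    "gower_distance",
    "epsilon_radius_network",
    "epsilon_grid_search",
]


@dataclass
class HyperedgeGroup:
    """A named set of hyperedges (node-index tuples) with positive weights."""

    name: str
    members: list[tuple[int, ...]]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != len(self.weights):
            raise ValueError("members/weights length mismatch")
        for m in self.members:
            if len(set(m)) < 2:
                raise ValueError(f"hyperedge {m} has fewer than 2 distinct members")
        if np.any(self.weights <= 0):
            raise ValueError("hyperedge weights must be positive")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Hypergraph:
    """Incidence matrix H (nodes x hyperedges, 0/1), per-hyperedge weights W.

    Node degrees Dv(v) = sum_e W(e) H(v,e); hyperedge degrees De(e) =
    sum_v H(v,e).  Singleton (pure self-loop) columns, added only as a last
    resort for otherwise isolated nodes, are the one place De = 1 is
    tolerated.
    """

    H: sparse.csr_matrix
    W: np.ndarray
    group_slices: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.H = sparse.csr_matrix(self.H)
        self.W = np.asarray(self.W, dtype=float)
        if self.H.shape[1] != len(self.W):
            raise ValueError("weight per hyperedge required")
        if np.any(self.W <= 0):
            raise ValueError("hyperedge weights must be positive")

    @property
    def n_nodes(self) -> int:
        return self.H.shape[0]

    @property
    def n_edges(self) -> int:
        return self.H.shape[1]

    @property
    def node_degrees(self) -> np.ndarray:
        return np.asarray(self.H @ self.W).ravel()

    @property
    def edge_degrees(self) -> np.ndarray:
        return np.asarray(self.H.sum(axis=0)).ravel()

    def propagation_matrix(self) -> np.ndarray:
        """Dense Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2} (symmetric)."""
        dv = self.node_degrees
        if np.any(dv <= 0):
            raise ValueError("node with zero degree; assemble with self-edge augmentation")
        de = self.edge_degrees
        dv_isqrt = 1.0 / np.sqrt(dv)
        Hd = self.H.multiply(self.W / de)  # column-scaled H: H W De^{-1}
        G = (Hd @ self.H.T).toarray()
        return dv_isqrt[:, None] * G * dv_isqrt[None, :]


def pae_edge_group(
    sim: SimilarityMatrix | np.ndarray, threshold: float = 0.5, name: str = "pae"
) -> HyperedgeGroup:
    """One 2-node hyperedge per patient pair with similarity >= threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    S = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    if not np.allclose(S, S.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    ii, jj = np.where(np.triu(S >= threshold, k=1))
    members = [(int(i), int(j)) for i, j in zip(ii, jj)]
    return HyperedgeGroup(name, members, S[ii, jj] if len(ii) else np.empty(0))


def adjacency_edge_group(adj: np.ndarray, name: str = "adjacency") -> HyperedgeGroup:
    """2-node unit-weight hyperedges from a binary adjacency matrix."""
    adj = np.asarray(adj)
    ii, jj = np.where(np.triu(adj != 0, k=1))
    members = [(int(i), int(j)) for i, j in zip(ii, jj)]
    return HyperedgeGroup(name, members, np.ones(len(members)))


def knn_hyperedge_group(
    features: FeatureMatrix | np.ndarray, k: int, name: str = "radiomics_knn"
) -> HyperedgeGroup:
    """One hyperedge per node: itself plus its k nearest neighbours.

    Euclidean distance in the (standardized) feature space; ties broken by
    lower node index so the graph is deterministic.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of nodes ({n})")
    D = squareform(pdist(X))
    members = []
    idx = np.arange(n)
    for v in range(n):
        others = idx[idx != v]
        order = np.lexsort((others, D[v, others]))  # distance, then lower index
        neigh = others[order[:k]]
        members.append(tuple([v] + sorted(int(u) for u in neigh)))
    return HyperedgeGroup(name, members, np.ones(n))


def assemble_hypergraph(
    groups: list[HyperedgeGroup],
    n_nodes: int,
    add_self_edges: bool = True,
    sim: SimilarityMatrix | np.ndarray | None = None,
) -> Hypergraph:
    """Concatenate hyperedge groups column-wise into one incidence matrix.

    With ``add_self_edges``, any node belonging to no hyperedge is re-attached
    so it can take part in message passing: a weight-1 pair with its nearest
    neighbour under ``sim`` when available, otherwise a pure self-column
    (the only case where a hyperedge of degree 1 is allowed).
    """
    if not groups and not add_self_edges:
        raise ValueError("no hyperedge groups and self-edge augmentation disabled")
    rows: list[int] = []
    cols: list[int] = []
    weights: list[float] = []
    slices: dict[str, slice] = {}
    e = 0
    for g in groups:
        start = e
        for m, w in zip(g.members, g.weights):
            if max(m) >= n_nodes:
                raise ValueError(f"hyperedge {m} references node >= n_nodes={n_nodes}")
            for v in set(m):
                rows.append(v)
                cols.append(e)
            weights.append(float(w))
            e += 1
        slices[g.name] = slice(start, e)
    covered = np.zeros(n_nodes, dtype=bool)
    covered[rows] = True
    if add_self_edges:
        start = e
        S = sim.values if isinstance(sim, SimilarityMatrix) else sim
        for v in np.where(~covered)[0]:
            if S is not None and n_nodes > 1:
                s = np.array(S[v], dtype=float)
                s[v] = -np.inf
                partner = int(np.argmax(s))
                for u in (v, partner):
                    rows.append(u)
                    cols.append(e)
            else:
                rows.append(int(v))
                cols.append(e)
            weights.append(1.0)
            e += 1
        if e > start:
            slices["self"] = slice(start, e)
    if e == 0:
        raise ValueError("empty hypergraph: no hyperedges and no nodes needing augmentation")
    H = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_nodes, e)
    ).tocsr()
    hg = Hypergraph(H, np.asarray(weights), slices)
    if np.any(hg.node_degrees <= 0):
        raise ValueError("isolated node remains after assembly (add_self_edges=False?)")
    return hg


@dataclass
class GowerSpec:
    """Variable typing for the Gower mixed-type distance.

    ``types`` maps variable -> {continuous, ordinal, categorical}; ordinal
    variables carry an ordered level list and are rank-scaled to [0,1];
    continuous ranges default to the observed max-min.
    """

    types: dict[str, str]
    weights: dict[str, float] = field(default_factory=dict)
    ranges: dict[str, float] = field(default_factory=dict)
    ordinal_levels: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, t in self.types.items():
            if t not in ("continuous", "ordinal", "categorical"):
                raise ValueError(f"unknown type {t!r} for variable {v!r}")
        w = [self.weights.get(v, 1.0) for v in self.types]
        if any(x < 0 for x in w):
            raise ValueError("weights must be >= 0")
        if not any(x > 0 for x in w):
            raise ValueError("at least one positive weight required")
        for v, r in self.ranges.items():
            if r <= 0:
                raise ValueError(f"range for {v!r} must be positive")


def default_gower_spec() -> GowerSpec:
    """Typing of the nine baseline clinical variables."""
    types = {v: "categorical" for v in CATEGORY_LEVELS}
    types.update({"age": "continuous", "longest_diameter": "continuous", "dnlr": "continuous"})
    types["treatment_line"] = "ordinal"
    return GowerSpec(types=types, ordinal_levels={"treatment_line": [1.0, 2.0, 3.0]})


def gower_distance(clinical: pd.DataFrame, spec: GowerSpec | None = None) -> np.ndarray:
    """Pairwise Gower distance over a mixed-type clinical table.

    d(i,j) = sum_k w_k d_k(i,j) / sum_k w_k over variables observed in both
    patients; |x_i - x_j| / range for continuous, rank-scaled difference for
    ordinal, 0/1 mismatch for categorical.  A pair with every term missing is
    an error.
    """
    spec = spec or default_gower_spec()
    n = len(clinical)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for var, vtype in spec.types.items():
        w = spec.weights.get(var, 1.0)
        if w == 0:
            continue
        col = clinical[var]
        if vtype in ("continuous", "ordinal"):
            if vtype == "ordinal":
                levels = spec.ordinal_levels.get(var)
                if levels is not None and not pd.api.types.is_numeric_dtype(col):
                    rank = {lev: r for r, lev in enumerate(levels)}
                    x = col.map(rank).to_numpy(dtype=float)
                else:
                    x = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
                    x = x - np.nanmin(x) if np.isfinite(x).any() else x
            else:
                x = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            valid = np.isfinite(x)
            rng = spec.ranges.get(var)
            if rng is None:
                if valid.sum() < 2 or np.nanmax(x) == np.nanmin(x):
                    continue  # no spread: variable carries no distance information
                rng = float(np.nanmax(x) - np.nanmin(x))
            dk = np.abs(x[:, None] - x[None, :]) / rng
        else:
            vals = col.astype(str).to_numpy()
            valid = (vals != MISSING) & (vals != "nan")
            dk = (vals[:, None] != vals[None, :]).astype(float)
        both = valid[:, None] & valid[None, :]
        num += np.where(both, dk, 0.0) * w
        den += both * w
    off = ~np.eye(n, dtype=bool)
    dead = (den == 0) & off
    if dead.any():
        i, j = np.argwhere(dead)[0]
        raise ValueError(f"pair ({i}, {j}) has no jointly observed variable")
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def epsilon_radius_network(dist: np.ndarray, epsilon: float = 0.5) -> np.ndarray:
    """Binary adjacency: 1 iff d(i,j) <= epsilon (boundary inclusive), i != j."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    dist = np.asarray(dist, dtype=float)
    if not np.allclose(dist, dist.T, atol=1e-9) or np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    adj = (dist <= epsilon).astype(int)
    np.fill_diagonal(adj, 0)
    return adj


def epsilon_grid_search(
    dist: np.ndarray,
    score_fn,
    epsilons: np.ndarray | None = None,
) -> tuple[float, dict[float, float]]:
    """Pick the ε whose network maximizes a caller-supplied score.

    ``score_fn(adjacency) -> float``; ε values with an empty or complete
    network still participate.  Returns (best ε, per-ε scores); ties go to
    the smaller ε.
    """
    if epsilons is None:
        epsilons = np.round(np.arange(0.1, 1.0, 0.1), 10)
    scores: dict[float, float] = {}
    for eps in epsilons:
        adj = epsilon_radius_network(dist, float(eps))
        try:
            scores[float(eps)] = float(score_fn(adj))
        except Exception as exc:  # degenerate networks may defeat the scorer
            warnings.warn(f"epsilon={eps}: scorer failed ({exc}); skipped")
            scores[float(eps)] = -np.inf
    best = max(sorted(scores), key=lambda e: scores[e])
    return best, scores
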