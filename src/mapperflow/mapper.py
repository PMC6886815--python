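"""Mapper graph construction from scratch.

Covers the range of a filtration function with overlapping intervals,
clusters each interval's preimage with deterministic k-medoids (Gower
distance by default, so mixed-type tables cluster natively), prunes small
clusters, and connects clusters sharing samples.  Also: assignment of new
points to retained nodes, exact graph edit distance for small graphs, and
plain-text graph exports.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from mapperflow.core import ContractError, NotFittedError
from mapperflow.morphisms import (
    StandardizeParams,
    apply_standardize,
    fit_standardize,
    infer_column_spec,
    _principal_axes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MapperParams",
    "Cover",
    "MapperNode",
    "MapperGraph",
    "gower_distance",
    "gower_matrix",
    "compute_numeric_ranges",
    "PCAFiltration",
    "CallableFiltration",
    "build_cover",
    "k_medoids",
    "merge_touching_clusters",
    "build_mapper_graph",
    "assign_new_points",
    "graph_edit_distance",
    "to_networkx",
    "graph_to_edgelist_tsv",
    "graph_to_dot",
]


# ------------------------------------------------------------------ distance
def compute_numeric_ranges(X: pd.DataFrame, column_spec: list[dict]) -> dict[str, float]:
    """Training-data ranges for the numeric columns used by Gower distance.
    Zero-range columns are recorded as 0 and excluded at evaluation time."""
    ranges: dict[str, float] = {}
    for c in column_spec:
        if c["kind"] == "continuous":
            col = np.asarray(X[c["name"]], dtype=float)
            r = float(col.max() - col.min())
            if r == 0.0:
                warnings.warn(f"column {c['name']!r} has zero range; excluded")
            ranges[c["name"]] = r
    return ranges


def gower_matrix(
    A: pd.DataFrame,
    B: pd.DataFrame,
    column_spec: list[dict],
    numeric_ranges: dict[str, float],
) -> np.ndarray:
    """Pairwise Gower distances between the rows of two tables, in [0, 1]:
    the unweighted mean over columns of |Δ|/range (numeric, clipped at 1)
    and mismatch indicators (categorical)."""
    n, m = len(A), len(B)
    total = np.zeros((n, m))
    used = 0
    for c in column_spec:
        name = c["name"]
        if c["kind"] == "continuous":
            r = numeric_ranges.get(name, 0.0)
            if r == 0.0:
                continue
            a = np.asarray(A[name], dtype=float)[:, None]
            b = np.asarray(B[name], dtype=float)[None, :]
            total += np.minimum(np.abs(a - b) / r, 1.0)
        else:
            a = np.asarray(A[name], dtype=object)[:, None]
            b = np.asarray(B[name], dtype=object)[None, :]
            total += (a != b).astype(float)
        used += 1
    if used == 0:
        raise ContractError("no usable columns for Gower distance")
    return total / used


def gower_distance(
    x1: pd.Series | dict,
    x2: pd.Series | dict,
    column_spec: list[dict],
    numeric_ranges: dict[str, float],
) -> float:
    """Gower distance between two single records."""
    A = pd.DataFrame([dict(x1)])
    B = pd.DataFrame([dict(x2)])
    return float(gower_matrix(A, B, column_spec, numeric_ranges)[0, 0])


# ---------------------------------------------------------------- filtration
class PCAFiltration:
    """First-principal-component score of the standardized encoded matrix.

    The principal axis sign is fixed so that its largest-magnitude loading
    is positive, making filter values reproducible.  Applies to unseen
    points through the stored standardization and axis.
    """

    def __init__(self) -> None:
        self.standardize_: StandardizeParams | None = None
        self.axis_: np.ndarray | None = None
        self.top_eigenvalue_: float | None = None

    def fit(self, X_encoded: np.ndarray) -> "PCAFiltration":
        X = np.atleast_2d(np.asarray(X_encoded, dtype=float))
        if X.shape[0] < 2:
            raise ContractError("filtration needs at least 2 rows")
        if np.allclose(X, X[0]):
            raise ContractError("constant data has no principal axis")
        self.standardize_ = fit_standardize(X)
        Z = apply_standardize(X, self.standardize_)
        S = np.cov(Z, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])
        evals, evecs = _principal_axes(S)
        self.axis_ = evecs[:, 0]
        self.top_eigenvalue_ = float(evals[0])
        return self

    def apply(self, X_encoded: np.ndarray) -> np.ndarray:
        if self.axis_ is None:
            raise NotFittedError("filtration not fitted")
        X = np.atleast_2d(np.asarray(X_encoded, dtype=float))
        return apply_standardize(X, self.standardize_) @ self.axis_


class CallableFiltration:
    """Adapter wrapping an arbitrary ``X_encoded -> values`` function."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray]) -> None:
        self.fn = fn

    def fit(self, X_encoded: np.ndarray) -> "CallableFiltration":
        return self

    def apply(self, X_encoded: np.ndarray) -> np.ndarray:
        return np.asarray(self.fn(np.atleast_2d(np.asarray(X_encoded, dtype=float))))


def _make_filtration(spec: Any) -> Any:
    if spec == "pc1" or spec is None:
        return PCAFiltration()
    if callable(spec):
        return CallableFiltration(spec)
    if hasattr(spec, "fit") and hasattr(spec, "apply"):
        return spec
    raise ContractError(f"unknown filtration spec {spec!r}")


# --------------------------------------------------------------------- cover
@dataclass(frozen=True)
class Cover:
    """Ordered overlapping closed intervals spanning the filter range."""

    intervals: tuple[tuple[float, float], ...]

    def containing(self, value: float, clamp: bool = False) -> list[int]:
        """Indices of intervals containing ``value`` (boundary-inclusive).
        With ``clamp=True``, out-of-range values snap to the nearest end."""
        if clamp:
            lo0 = self.intervals[0][0]
            hi_last = self.intervals[-1][1]
            value = min(max(value, lo0), hi_last)
        return [
            j for j, (lo, hi) in enumerate(self.intervals) if lo <= value <= hi
        ]


def build_cover(filter_values: np.ndarray, k: int, o: float) -> Cover:
    """Uniform cover of ``[min, max]`` with k intervals of equal length
    ``L = range / (k − (k−1)·o)`` whose adjacent intersections have length
    ``o·L``.  All filter values equal yields one degenerate interval."""
    if k < 1:
        raise ContractError("k must be >= 1")
    if not (0.0 <= o < 1.0):
        raise ContractError("overlap o must lie in [0, 1)")
    v = np.asarray(filter_values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return Cover(intervals=((lo, hi),))
    span = hi - lo
    L = span / (k - (k - 1) * o)
    intervals = []
    for j in range(k):
        a = lo + j * (1.0 - o) * L
        b = a + L
        intervals.append((a, b))
    # pin the extremes exactly to avoid floating-point gaps at the boundary
    intervals[0] = (lo, intervals[0][1])
    intervals[-1] = (intervals[-1][0], hi)
    return Cover(intervals=tuple(intervals))


# ----------------------------------------------------------------- clustering
def k_medoids(D: np.ndarray, b: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic k-medoids on a precomputed distance matrix.

    Seeding is farthest-point starting from index 0; assignment and medoid
    updates break ties towards the lowest index, so results are reproducible
    without a random seed.  Returns integer cluster labels.
    """
    n = D.shape[0]
    b = min(b, n)
    medoids = [0]
    while len(medoids) < b:
        dmin = D[:, medoids].min(axis=1)
        nxt = int(np.argmax(dmin))
        if dmin[nxt] == 0.0:
            break  # duplicates only; fewer clusters than requested
        medoids.append(nxt)
    medoids = np.asarray(sorted(medoids))
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = []
        for c in range(len(medoids)):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                new_medoids.append(medoids[c])
                continue
            sub = D[np.ix_(members, members)]
            new_medoids.append(int(members[int(np.argmin(sub.sum(axis=1)))]))
        new_medoids = np.asarray(sorted(new_medoids))
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


def _mst_max_edge(D: np.ndarray) -> float:
    """Largest edge of the minimum spanning tree — the cluster's internal
    connectivity scale (0 for singletons)."""
    if D.shape[0] < 2:
        return 0.0
    from scipy.sparse.csgraph import minimum_spanning_tree

    mst = minimum_spanning_tree(D).toarray()
    return float(mst.max())


def merge_touching_clusters(
    D: np.ndarray, labels: np.ndarray, slack: float = 1.5
) -> np.ndarray:
    """Merge clusters whose single-linkage gap is within the clusters' own
    internal connectivity scale.

    A forced cluster count can split a connected preimage (e.g. the cap of a
    circle) into adjacent pieces; merging restores connectivity while leaving
    genuinely separated clusters alone.  ``b`` therefore acts as an upper
    bound on the cluster count.  Deterministic: the smallest qualifying gap
    merges first.
    """
    labels = np.asarray(labels).copy()
    while True:
        ids = np.unique(labels)
        if len(ids) < 2:
            return labels
        scale = {c: _mst_max_edge(D[np.ix_(labels == c, labels == c)]) for c in ids}
        best = None
        for a, b in itertools.combinations(ids, 2):
            gap = float(D[np.ix_(labels == a, labels == b)].min())
            if gap <= slack * max(scale[a], scale[b]):
                if best is None or gap < best[0]:
                    best = (gap, a, b)
        if best is None:
            return labels
        _, a, b = best
        labels[labels == b] = a


# --------------------------------------------------------------------- graph
@dataclass
class MapperParams:
    k: int = 10
    o: float = 0.4
    b: int = 10
    min_node_size: int = 40
    filtration: Any = "pc1"  # 'pc1' or a fit/apply object or callable
    distance: str = "gower"  # 'gower' | 'euclidean'

    def __post_init__(self) -> None:
        if self.k < 1 or self.b < 1:
            raise ContractError("k and b must be >= 1")
        if not (0.0 <= self.o < 1.0):
            raise ContractError("o must lie in [0, 1)")
        if self.distance not in ("gower", "euclidean"):
            raise ContractError(f"unknown distance {self.distance!r}")


@dataclass
class MapperNode:
    id: int
    interval_index: int
    members: np.ndarray  # global sample indices
    medoid: int  # global index of the cluster representative


@dataclass
class MapperGraph:
    nodes: list[MapperNode]
    edges: list[tuple[int, int, int]]  # (node_id i, node_id j, shared count)
    params: MapperParams
    cover: Cover
    column_spec: list[dict] | None = None
    numeric_ranges: dict[str, float] | None = None
    medoid_table: pd.DataFrame | None = None  # raw medoid rows (gower mode)
    medoid_encoded: np.ndarray | None = None  # encoded medoid rows

    @property
    def node_ids(self) -> list[int]:
        return [n.id for n in self.nodes]

    def node(self, node_id: int) -> MapperNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)


def build_mapper_graph(
    X_table: pd.DataFrame,
    X_encoded: np.ndarray,
    params: MapperParams,
    column_spec: list[dict] | None = None,
    filter_values: np.ndarray | None = None,
) -> tuple[MapperGraph, Any]:
    """Run the full Mapper construction; returns (graph, fitted filtration).

    Per interval of the cover, the preimage is clustered into at most ``b``
    k-medoids clusters under the configured distance; clusters smaller than
    ``min_node_size`` are dropped *before* edge construction, and every
    retained pair sharing at least one sample gets an edge.
    """
    n = len(X_table)
    X_encoded = np.atleast_2d(np.asarray(X_encoded, dtype=float))
    if n < params.min_node_size:
        raise ContractError("fewer samples than min_node_size")
    if column_spec is None:
        column_spec = infer_column_spec(X_table)

    filtration = _make_filtration(params.filtration)
    filtration.fit(X_encoded)
    fv = filtration.apply(X_encoded) if filter_values is None else np.asarray(filter_values)
    cover = build_cover(fv, params.k, params.o)

    if params.distance == "gower":
        ranges = compute_numeric_ranges(X_table, column_spec)
        D = gower_matrix(X_table, X_table, column_spec, ranges)
    else:
        ranges = None
        diff = X_encoded[:, None, :] - X_encoded[None, :, :]
        D = np.sqrt(np.sum(diff * diff, axis=2))

    candidates: list[MapperNode] = []
    for j, (lo, hi) in enumerate(cover.intervals):
        members = np.flatnonzero((fv >= lo) & (fv <= hi))
        if len(members) == 0:
            continue
        D_sub = D[np.ix_(members, members)]
        labels = k_medoids(D_sub, params.b)
        if params.b > 1:
            labels = merge_touching_clusters(D_sub, labels)
        for c in np.unique(labels):
            idx = members[labels == c]
            sub = D[np.ix_(idx, idx)]
            medoid = int(idx[int(np.argmin(sub.sum(axis=1)))])
            candidates.append(
                MapperNode(id=-1, interval_index=j, members=idx, medoid=medoid)
            )

    retained = [c for c in candidates if len(c.members) >= params.min_node_size]
    if not retained:
        raise ContractError("no retained nodes; lower min_node_size")
    for i, node in enumerate(retained):
        node.id = i

    edges: list[tuple[int, int, int]] = []
    member_sets = [set(node.members.tolist()) for node in retained]
    for i, j in itertools.combinations(range(len(retained)), 2):
        shared = len(member_sets[i] & member_sets[j])
        if shared >= 1:
            edges.append((retained[i].id, retained[j].id, shared))

    medoid_idx = [node.medoid for node in retained]
    graph = MapperGraph(
        nodes=retained,
        edges=edges,
        params=params,
        cover=cover,
        column_spec=column_spec,
        numeric_ranges=ranges,
        medoid_table=X_table.iloc[medoid_idx].reset_index(drop=True),
        medoid_encoded=X_encoded[medoid_idx],
    )
    return graph, filtration


def assign_new_points(
    graph: MapperGraph,
    filtration: Any,
    cover: Cover,
    X_new_table: pd.DataFrame,
    X_new_encoded: np.ndarray,
    max_nodes: int = 2,
) -> list[list[tuple[int, float]]]:
    """Assign each new point to up to ``max_nodes`` retained nodes.

    The filter value selects the containing intervals (out-of-range values
    clamp to the nearest interval); within each interval the retained node
    with the nearest representative wins; results are ordered by distance.
    Points whose containing intervals hold no retained node fall back to the
    globally nearest node.
    """
    if max_nodes not in (1, 2):
        raise ContractError("max_nodes must be 1 or 2")
    X_new_encoded = np.atleast_2d(np.asarray(X_new_encoded, dtype=float))
    fv = filtration.apply(X_new_encoded)
    if graph.params.distance == "gower":
        dist_to_medoids = gower_matrix(
            X_new_table, graph.medoid_table, graph.column_spec, graph.numeric_ranges
        )
    else:
        diff = X_new_encoded[:, None, :] - graph.medoid_encoded[None, :, :]
        dist_to_medoids = np.sqrt(np.sum(diff * diff, axis=2))

    by_interval: dict[int, list[int]] = {}
    for pos, node in enumerate(graph.nodes):
        by_interval.setdefault(node.interval_index, []).append(pos)

    out: list[list[tuple[int, float]]] = []
    for r in range(len(X_new_encoded)):
        picks: list[tuple[int, float]] = []
        for j in cover.containing(float(fv[r]), clamp=True):
            positions = by_interval.get(j, [])
            if not positions:
                continue
            dists = dist_to_medoids[r, positions]
            best = positions[int(np.argmin(dists))]
            picks.append((graph.nodes[best].id, float(dists.min())))
        if not picks:
            logger.warning("point %d: no retained node in its intervals; "
                           "falling back to globally nearest node", r)
            best = int(np.argmin(dist_to_medoids[r]))
            picks = [(graph.nodes[best].id, float(dist_to_medoids[r, best]))]
        picks.sort(key=lambda t: (t[1], t[0]))
        out.append(picks[:max_nodes])
    return out


# ------------------------------------------------------- graph edit distance
_DEFAULT_COSTS = {
    "node_insert": 1.0,
    "node_delete": 1.0,
    "node_substitute": 1.0,  # charged only for labelled nodes with differing labels
    "edge_insert": 1.0,
    "edge_delete": 1.0,
}


def _as_graph(g: Any) -> tuple[list[Any], set[frozenset]]:
    """Normalise MapperGraph / networkx.Graph / (nodes, edges) to
    (node list, set of undirected edges)."""
    if isinstance(g, MapperGraph):
        nodes = g.node_ids
        edges = {frozenset((i, j)) for i, j, _ in g.edges}
        return nodes, edges
    if hasattr(g, "nodes") and hasattr(g, "edges"):  # networkx
        return list(g.nodes), {frozenset((u, v)) for u, v in g.edges if u != v}
    nodes, edges = g
    return list(nodes), {frozenset((u, v)) for u, v in edges if u != v}


def graph_edit_distance(
    G1: Any,
    G2: Any,
    costs: dict[str, float] | None = None,
    labels1: dict | None = None,
    labels2: dict | None = None,
    max_exact_nodes: int = 8,
) -> float:
    """Exact graph edit distance by exhaustive search over node assignments.

    Minimum total cost over node insertions/deletions/substitutions and edge
    insertions/deletions transforming ``G1`` into ``G2``; unit costs by
    default.  Node substitution is charged only when both nodes are labelled
    and their labels differ.  Exact search is limited to graphs with at most
    ``max_exact_nodes`` nodes (8 by default); larger inputs raise an error.
    """
    c = dict(_DEFAULT_COSTS)
    if costs:
        c.update(costs)
    if any(v < 0 for v in c.values()):
        raise ContractError("costs must be nonnegative")
    nodes1, edges1 = _as_graph(G1)
    nodes2, edges2 = _as_graph(G2)
    n1, n2 = len(nodes1), len(nodes2)
    if n1 > max_exact_nodes or n2 > max_exact_nodes:
        raise ContractError(
            f"exact solver limited to {max_exact_nodes} nodes; "
            "coarsen the graphs or raise max_exact_nodes"
        )

    def sub_cost(u: Any, v: Any) -> float:
        if labels1 is None or labels2 is None:
            return 0.0
        return 0.0 if labels1.get(u) == labels2.get(v) else c["node_substitute"]

    best = np.inf
    idx2 = list(range(n2))
    for s in range(0, min(n1, n2) + 1):
        for keep1 in itertools.combinations(range(n1), s):
            for image in itertools.permutations(idx2, s):
                mapping = {nodes1[a]: nodes2[b] for a, b in zip(keep1, image)}
                cost = (n1 - s) * c["node_delete"] + (n2 - s) * c["node_insert"]
                for u, v in mapping.items():
                    cost += sub_cost(u, v)
                mapped_edges2 = set()
                for e in edges1:
                    u, v = tuple(e)
                    if u in mapping and v in mapping:
                        img = frozenset((mapping[u], mapping[v]))
                        if img in edges2:
                            mapped_edges2.add(img)
                        else:
                            cost += c["edge_delete"]
                    else:
                        cost += c["edge_delete"]
                cost += c["edge_insert"] * len(edges2 - mapped_edges2)
                if cost < best:
                    best = cost
    return float(best)


# ------------------------------------------------------------------- exports
def to_networkx(graph: MapperGraph):
    """Convert to a networkx.Graph with member counts as node attributes."""
    import networkx as nx

    g = nx.Graph()
    for node in graph.nodes:
        g.add_node(node.id, size=len(node.members), interval=node.interval_index)
    for i, j, w in graph.edges:
        g.add_edge(i, j, shared=w)
    return g


def graph_to_edgelist_tsv(graph: MapperGraph) -> str:
    """Edge list as TSV text: node_i, node_j, shared sample count."""
    lines = ["node_i\tnode_j\tshared"]
    for i, j, w in graph.edges:
        lines.append(f"{i}\t{j}\t{w}")
    return "\n".join(lines) + "\n"


def graph_to_dot(graph: MapperGraph, outcome: np.ndarray | None = None) -> str:
    """DOT text with node size proportional to member count and, when an
    outcome vector is given, fill color by outcome prevalence."""
    lines = ["graph mapper {", "  node [style=filled];"]
    sizes = np.array([len(n.members) for n in graph.nodes], dtype=float)
    wmax = sizes.max() if len(sizes) else 1.0
    for node in graph.nodes:
        w = 0.4 + 1.1 * len(node.members) / wmax
        if outcome is not None:
            prev = float(np.mean(np.asarray(outcome)[node.members]))
            shade = int(round(255 * (1.0 - prev)))
            color = f"#ff{shade:02x}{shade:02x}"
            label = f"{node.id} (n={len(node.members)}, {prev:.0%})"
        else:
            color = "#cccccc"
            label = f"{node.id} (n={len(node.members)})"
        lines.append(
            f'  {node.id} [label="{label}", width={w:.2f}, fillcolor="{color}"];'
        )
    for i, j, w in graph.edges:
        lines.append(f"  {i} -- {j} [label={w}];")
    lines.append("}")
    return "\n".join(lines) + "\n"
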