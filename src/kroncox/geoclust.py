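"""Spatial clustering of point-referenced units by spanning-tree pruning.

Units (e.g. counties represented by their centroids) carry an attribute
vector; a contiguity graph is built from geographic proximity, edges are
weighted by attribute dissimilarity, and the minimum spanning tree is
pruned greedily so that each removed edge maximizes the drop in the
within-cluster attribute sum of squared deviations (SSD). Clusters are
therefore both spatially contiguous (connected subtrees) and internally
homogeneous. Optional constraints keep clusters above a minimum total
population or within size bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


class DisconnectedGraphError(ValueError):
    """Raised when an operation requires a connected graph."""

    def __init__(self, components: list[list[int]]):
        self.components = components
        preview = "; ".join(str(c[:8]) for c in components[:4])
        super().__init__(
            f"graph has {len(components)} connected components "
            f"(need 1): {preview}"
        )


@dataclass(frozen=True)
class SpatialUnit:
    """One spatial unit: centroid coordinates, population and attributes."""

    unit_id: str
    centroid: tuple[float, float]  # (latitude deg, longitude deg)
    population: float
    attributes: np.ndarray

    def __post_init__(self):
        lat, lon = self.centroid
        if not (-90.0 <= lat <= 90.0):
            raise ValueError(f"latitude {lat} outside [-90, 90]")
        if not (-180.0 <= lon <= 180.0):
            raise ValueError(f"longitude {lon} outside [-180, 180]")
        if self.population < 0:
            raise ValueError("population must be nonnegative")
        object.__setattr__(
            self, "attributes", np.asarray(self.attributes, dtype=float)
        )


@dataclass
class AdjacencyGraph:
    units: list[SpatialUnit]
    adjacency: np.ndarray  # N x N binary, symmetric, zero diagonal
    edge_weights: dict[tuple[int, int], float]  # keyed by (i, j), i < j

    @property
    def n(self) -> int:
        return len(self.units)

    def edges(self) -> list[tuple[int, int, float]]:
        return [(i, j, w) for (i, j), w in sorted(self.edge_weights.items())]


@dataclass
class SpanningTree:
    nodes: list[int]
    edges: list[tuple[int, int, float]]  # (i, j, weight), i < j

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def neighbors(self) -> dict[int, set[int]]:
        nb: dict[int, set[int]] = {v: set() for v in self.nodes}
        for i, j, _ in self.edges:
            nb[i].add(j)
            nb[j].add(i)
        return nb


Constraint = (
    tuple[Literal["min_population"], float]
    | tuple[Literal["size_bounds"], int, int]
    | None
)


@dataclass
class Partition:
    """Assignment of units to contiguous clusters."""

    assignment: np.ndarray  # per-unit integer label in {0, ..., C-1}
    n_clusters: int
    constraint: Constraint = None
    objective: float = float("nan")  # total within-cluster SSD

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == c)

    def to_frame(self, unit_ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": list(unit_ids), "cluster": self.assignment + 1}
        )


def great_circle_distance(a, b) -> float:
    """Haversine distance in km between two (lat, lon) points in degrees."""
    lat1, lon1 = float(a[0]), float(a[1])
    lat2, lon2 = float(b[0]), float(b[1])
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"coordinate ({lat}, {lon}) out of range")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(min(1.0, h))))


def pairwise_great_circle(units: Sequence[SpatialUnit]) -> np.ndarray:
    coords = np.array([u.centroid for u in units], dtype=float)
    n = len(units)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = great_circle_distance(coords[i], coords[j])
    return D


def standardize_attributes(units: Sequence[SpatialUnit]) -> np.ndarray:
    """Z-score the unit attribute matrix column-wise (constant cols -> 0)."""
    X = np.array([u.attributes for u in units], dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _connected_components(n: int, adj: np.ndarray) -> list[list[int]]:
    seen = np.zeros(n, dtype=bool)
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in np.flatnonzero(adj[v]):
                if not seen[u]:
                    seen[u] = True
                    stack.append(int(u))
        comps.append(sorted(comp))
    return comps


def build_adjacency(
    units: Sequence[SpatialUnit],
    mode: Literal["distance_threshold", "knn"] = "distance_threshold",
    *,
    d_km: float | None = None,
    k: int | None = None,
    attribute_indices: Sequence[int] | None = None,
) -> AdjacencyGraph:
    """Contiguity graph from centroid proximity, weighted by attribute dissimilarity.

    ``distance_threshold`` links units within ``d_km`` great-circle km;
    ``knn`` links each unit to its ``k`` nearest units and symmetrizes the
    result. Edge weights are Euclidean distances between z-standardized
    attribute vectors, so the spanning tree and the clustering that prunes
    it are scale-invariant in the attributes.
    """
    units = list(units)
    n = len(units)
    if n < 2:
        raise ValueError("need at least 2 units")
    D = pairwise_great_circle(units)
    A = np.zeros((n, n), dtype=int)
    if mode == "distance_threshold":
        if d_km is None:
            raise ValueError("distance_threshold mode needs d_km")
        A = ((D <= d_km) & (D > 0)).astype(int)
        np.fill_diagonal(A, 0)
    elif mode == "knn":
        if k is None:
            raise ValueError("knn mode needs k")
        if k >= n:
            raise ValueError(f"k={k} must be < number of units {n}")
        for i in range(n):
            order = np.argsort(D[i])
            nearest = [j for j in order if j != i][:k]
            A[i, nearest] = 1
        A = np.maximum(A, A.T)  # symmetrize (union of neighborhoods)
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")

    comps = _connected_components(n, A)
    if len(comps) > 1:
        raise DisconnectedGraphError(comps)

    Z = standardize_attributes(units)
    if attribute_indices is not None:
        Z = Z[:, list(attribute_indices)]
    weights = {}
    ii, jj = np.nonzero(np.triu(A, 1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        weights[(i, j)] = float(np.linalg.norm(Z[i] - Z[j]))
    return AdjacencyGraph(units=units, adjacency=A, edge_weights=weights)


def connected_knn_adjacency(
    units: Sequence[SpatialUnit],
    k: int = 4,
    attribute_indices: Sequence[int] | None = None,
) -> AdjacencyGraph:
    """Symmetrized knn contiguity with k grown until the graph connects."""
    n = len(units)
    last_exc: Exception | None = None
    for kk in range(k, n):
        try:
            return build_adjacency(
                units, mode="knn", k=kk, attribute_indices=attribute_indices
            )
        except DisconnectedGraphError as exc:
            last_exc = exc
    raise last_exc if last_exc is not None else ValueError("no units")


def minimum_spanning_tree(graph: AdjacencyGraph) -> SpanningTree:
    """Prim's algorithm with deterministic lexicographic tie-breaking.

    Among candidate edges of equal weight the one with the smallest
    (i, j) pair wins, so reruns give bit-identical trees.
    """
    n = graph.n
    comps = _connected_components(n, graph.adjacency)
    if len(comps) > 1:
        raise DisconnectedGraphError(comps)
    w = graph.edge_weights

    def weight(i: int, j: int) -> float:
        return w[(min(i, j), max(i, j))]

    in_tree = {0}
    edges: list[tuple[int, int, float]] = []
    adj = graph.adjacency
    while len(in_tree) < n:
        best = None  # (weight, i, j) with i < j for tie-break
        for v in sorted(in_tree):
            for u in np.flatnonzero(adj[v]):
                u = int(u)
                if u in in_tree:
                    continue
                cand = (weight(v, u), min(v, u), max(v, u))
                if best is None or cand < best:
                    best = cand
        assert best is not None
        wt, i, j = best
        edges.append((i, j, wt))
        in_tree.add(j if i in in_tree else i)
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    return SpanningTree(nodes=list(range(n)), edges=edges)


def ssd(members: Sequence[int] | np.ndarray, attributes: np.ndarray) -> float:
    """Within-set sum of squared deviations from the attribute means.

    ``SSD = sum_j sum_i (x_ij - xbar_j)^2`` over member units i and
    attribute columns j.
    """
    members = np.asarray(list(members), dtype=int)
    if members.size == 0:
        raise ValueError("member set must be nonempty")
    X = attributes[members]
    return float(((X - X.mean(axis=0)) ** 2).sum())


def _subtree_nodes(
    edges: list[tuple[int, int, float]], nodes: set[int]
) -> list[set[int]]:
    """Connected components of the forest restricted to ``nodes``."""
    nb: dict[int, set[int]] = {v: set() for v in nodes}
    for i, j, _ in edges:
        if i in nodes and j in nodes:
            nb[i].add(j)
            nb[j].add(i)
    seen: set[int] = set()
    comps = []
    for s in sorted(nodes):
        if s in seen:
            continue
        stack, comp = [s], set()
        seen.add(s)
        while stack:
            v = stack.pop()
            comp.add(v)
            for u in nb[v]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        comps.append(comp)
    return comps


def _split_by_edge(
    tree_edges: list[tuple[int, int, float]], nodes: set[int], edge_idx: int
) -> tuple[set[int], set[int]]:
    kept = [e for k, e in enumerate(tree_edges) if k != edge_idx]
    parts = _subtree_nodes(kept, nodes)
    assert len(parts) == 2
    return parts[0], parts[1]


def _constraint_ok(
    part: set[int], constraint: Constraint, populations: np.ndarray
) -> bool:
    if constraint is None:
        return True
    if constraint[0] == "min_population":
        return populations[sorted(part)].sum() >= constraint[1]
    if constraint[0] == "size_bounds":
        lo, hi = constraint[1], constraint[2]
        return lo <= len(part) <= hi
    raise ValueError(f"unknown constraint {constraint!r}")


def skater(
    tree: SpanningTree,
    n_clusters: int,
    attributes: np.ndarray,
    constraint: Constraint = None,
    populations: np.ndarray | None = None,
) -> Partition:
    """Greedy spanning-tree pruning into contiguous homogeneous clusters.

    At each iteration every edge of every current subtree is evaluated;
    the removed edge maximizes ``SSD(T) - (SSD(Ta) + SSD(Tb))``, i.e. the
    decrease in the partition cost ``Q = sum_k SSD_k``. Splits violating
    the active constraint are excluded; if no feasible split exists the
    search stops early with a warning and fewer clusters. Ties break on
    the lowest edge id (position in the sorted tree edge list).
    """
    n = len(tree.nodes)
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds node count {n}")
    if constraint is not None and constraint[0] == "min_population":
        if populations is None:
            raise ValueError("min_population constraint needs populations")
    pops = populations if populations is not None else np.zeros(n)

    if constraint is not None and not _constraint_ok(
        set(tree.nodes), constraint, pops
    ):
        raise ValueError("constraint infeasible even for the full node set")

    tree_edges = list(tree.edges)
    clusters: list[set[int]] = [set(tree.nodes)]
    q = ssd(sorted(clusters[0]), attributes)

    while len(clusters) < n_clusters:
        best = None  # (gain, edge_id, cluster_idx, part_a, part_b)
        for ci, nodes in enumerate(clusters):
            if len(nodes) < 2:
                continue
            parent_ssd = ssd(sorted(nodes), attributes)
            for eid, (i, j, _) in enumerate(tree_edges):
                if i not in nodes or j not in nodes:
                    continue
                a, b = _split_by_edge(tree_edges, nodes, eid)
                if not (
                    _constraint_ok(a, constraint, pops)
                    and _constraint_ok(b, constraint, pops)
                ):
                    continue
                gain = parent_ssd - (
                    ssd(sorted(a), attributes) + ssd(sorted(b), attributes)
                )
                cand = (gain, -eid)
                if best is None or cand > (best[0], -best[1]):
                    best = (gain, eid, ci, a, b)
        if best is None:
            warnings.warn(
                f"no feasible split: stopping at {len(clusters)} clusters "
                f"instead of {n_clusters}",
                RuntimeWarning,
            )
            break
        gain, eid, ci, a, b = best
        clusters[ci : ci + 1] = [a, b]
        q -= gain

    assignment = np.empty(n, dtype=int)
    order = sorted(range(len(clusters)), key=lambda c: min(clusters[c]))
    for label, ci in enumerate(order):
        for v in clusters[ci]:
            assignment[v] = label
    q_final = sum(ssd(sorted(c), attributes) for c in clusters)
    return Partition(
        assignment=assignment,
        n_clusters=len(clusters),
        constraint=constraint,
        objective=float(q_final),
    )


def silhouette_widths(
    partition: Partition, attributes: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-unit silhouette widths on Euclidean attribute distances.

    ``s(i) = (b(i) - a(i)) / max(a(i), b(i))``, with the convention
    ``s(i) = 0`` for units in singleton clusters and whenever
    ``max(a, b) = 0`` (all-identical degenerate case).
    """
    labels = partition.assignment
    if partition.n_clusters < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    X = np.asarray(attributes, dtype=float)
    n = X.shape[0]
    D = np.sqrt(
        np.maximum(
            0.0,
            (X**2).sum(1)[:, None] + (X**2).sum(1)[None, :] - 2 * X @ X.T,
        )
    )
    s = np.zeros(n)
    for i in range(n):
        own = np.flatnonzero(labels == labels[i])
        if own.size == 1:
            s[i] = 0.0
            continue
        a = D[i, own[own != i]].mean()
        b = min(
            D[i, labels == c].mean()
            for c in range(partition.n_clusters)
            if c != labels[i]
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def choose_cluster_count(
    tree: SpanningTree,
    attributes: np.ndarray,
    candidates: Sequence[int],
    constraint: Constraint = None,
    populations: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean silhouette width per candidate cluster count (diagnostic table)."""
    rows = []
    for c in candidates:
        part = skater(tree, c, attributes, constraint, populations)
        _, mean_w = silhouette_widths(part, attributes)
        rows.append(
            {"n_clusters": c, "mean_silhouette": mean_w, "objective": part.objective}
        )
    return pd.DataFrame(rows)


def read_units_csv(path) -> list[SpatialUnit]:
    """Load units from CSV with columns unit_id, lat, lon, population, attr_*."""
    df = pd.read_csv(path)
    attr_cols = [c for c in df.columns if c.startswith("attr_")]
    return [
        SpatialUnit(
            unit_id=str(r["unit_id"]),
            centroid=(float(r["lat"]), float(r["lon"])),
            population=float(r["population"]),
            attributes=np.array([r[c] for c in attr_cols], dtype=float),
        )
        for _, r in df.iterrows()
    ]
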