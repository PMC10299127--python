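"""Spanning-tree enhancement of connectivity matrices and 3-channel stacking.

A connectivity matrix becomes a complete weighted graph on the ROIs.  Kruskal's
algorithm (own union-find, deterministic tie-break) extracts the minimum and
maximum spanning trees, which proxy the weakest and strongest connection
backbones.  The *enhanced* stack layers the original matrix with the MaxST and
MST layers; the *plain* stack splits the matrix into three row bands that sum
back to the original.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightedGraph",
    "SpanningTree",
    "Stack3D",
    "matrix_to_graph",
    "kruskal_spanning_tree",
    "tree_layer",
    "build_enhanced_stack",
    "build_plain_stack",
    "plain_band_sizes",
]

_SYM_TOL = 1e-8


class GraphError(ValueError):
    """Raised on invalid graph or stacking inputs."""


@dataclass
class WeightedGraph:
    """Undirected weighted graph; edges stored as (i, j, w) with i < j."""

    n_vertices: int
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        norm = []
        for i, j, w in self.edges:
            if i == j:
                raise GraphError(f"self-loop at vertex {i}")
            if not (0 <= i < self.n_vertices and 0 <= j < self.n_vertices):
                raise GraphError(f"edge ({i},{j}) out of range for {self.n_vertices} vertices")
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                raise GraphError(f"duplicate edge ({a},{b})")
            seen.add((a, b))
            norm.append((a, b, float(w)))
        self.edges = norm

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class SpanningTree:
    """Acyclic connected edge subset with extremal total weight."""

    variant: str  # "min" | "max"
    n_vertices: int
    edges: list[tuple[int, int, float]]
    total_weight: float

    def __post_init__(self) -> None:
        if self.variant not in ("min", "max"):
            raise GraphError(f"variant must be 'min' or 'max', got {self.variant!r}")
        if len(self.edges) != self.n_vertices - 1:
            raise GraphError(
                f"spanning tree on {self.n_vertices} vertices needs "
                f"{self.n_vertices - 1} edges, got {len(self.edges)}"
            )
        uf = _UnionFind(self.n_vertices)
        for i, j, _ in self.edges:
            if not uf.union(i, j):
                raise GraphError(f"cycle introduced by edge ({i},{j})")
        if uf.n_components != 1:
            raise GraphError("edge set does not span all vertices")
        if not np.isclose(self.total_weight, sum(w for _, _, w in self.edges)):
            raise GraphError("total_weight inconsistent with member edges")

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.edges}


@dataclass
class Stack3D:
    """N x N x 3 channel stack mimicking an RGB image."""

    subject_id: str
    atlas: str
    method: str
    strategy: str  # "plain" | "enhanced"
    channels: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.strategy not in ("plain", "enhanced"):
            raise GraphError(f"strategy must be 'plain' or 'enhanced', got {self.strategy!r}")
        s = self.channels.shape
        if len(s) != 3 or s[2] != 3 or s[0] != s[1]:
            raise GraphError(f"channels must be N x N x 3, got {s}")

    @property
    def n_rois(self) -> int:
        return self.channels.shape[0]


class _UnionFind:
    """Path-compressed union-find over 0..n-1."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n
        self.n_components = n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        self.n_components -= 1
        return True


def matrix_to_graph(cm, absolute: bool = False) -> WeightedGraph:
    """Complete weighted graph from a symmetric matrix; diagonal discarded.

    Signed entries are kept as-is unless ``absolute`` is set, in which case
    edge weights are the magnitudes.
    """
    M = np.asarray(getattr(cm, "M", cm), dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise GraphError(f"matrix must be square, got {M.shape}")
    asym = np.max(np.abs(M - M.T))
    if asym > _SYM_TOL:
        raise GraphError(f"matrix asymmetric beyond tolerance ({asym:.2e})")
    n = M.shape[0]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            w = abs(M[i, j]) if absolute else M[i, j]
            edges.append((i, j, float(w)))
    return WeightedGraph(n_vertices=n, edges=edges)


def kruskal_spanning_tree(g: WeightedGraph, variant: str = "min") -> SpanningTree:
    """Kruskal's greedy spanning tree via union-find.

    Edges are scanned in ascending (min) or descending (max) weight order,
    ties broken by lexicographic (i, j) so extraction is reproducible.
    """
    if variant not in ("min", "max"):
        raise GraphError(f"variant must be 'min' or 'max', got {variant!r}")
    if variant == "min":
        order = sorted(g.edges, key=lambda e: (e[2], e[0], e[1]))
    else:
        order = sorted(g.edges, key=lambda e: (-e[2], e[0], e[1]))
    uf = _UnionFind(g.n_vertices)
    chosen: list[tuple[int, int, float]] = []
    for i, j, w in order:
        if uf.union(i, j):
            chosen.append((i, j, w))
            if len(chosen) == g.n_vertices - 1:
                break
    if len(chosen) != g.n_vertices - 1:
        comp = sorted(v for v in range(g.n_vertices) if uf.find(v) == uf.find(0))
        raise GraphError(
            f"graph is disconnected; component containing vertex 0: {comp}"
        )
    return SpanningTree(
        variant=variant,
        n_vertices=g.n_vertices,
        edges=chosen,
        total_weight=float(sum(w for _, _, w in chosen)),
    )


def tree_layer(tree: SpanningTree, cm) -> np.ndarray:
    """Symmetric N x N matrix holding the source weights on the tree edges."""
    M = np.asarray(getattr(cm, "M", cm), dtype=float)
    n = M.shape[0]
    if tree.n_vertices != n:
        raise GraphError(
            f"tree on {tree.n_vertices} vertices does not match {n} x {n} matrix"
        )
    layer = np.zeros((n, n))
    for i, j, _ in tree.edges:
        layer[i, j] = layer[j, i] = M[i, j]
    return layer


def build_enhanced_stack(cm, absolute: bool = False) -> Stack3D:
    """Layer the original matrix with its MaxST (channel 1) and MST (channel 2).

    Tree layers carry the original signed weights even when trees are
    extracted on magnitudes (``absolute``).
    """
    M = np.asarray(cm.M, dtype=float)
    g = matrix_to_graph(cm, absolute=absolute)
    max_tree = kruskal_spanning_tree(g, "max")
    min_tree = kruskal_spanning_tree(g, "min")
    channels = np.stack(
        [M, tree_layer(max_tree, cm), tree_layer(min_tree, cm)], axis=2
    )
    return Stack3D(
        subject_id=cm.subject_id,
        atlas=cm.atlas,
        method=cm.method,
        strategy="enhanced",
        channels=channels,
    )


def plain_band_sizes(n: int) -> tuple[int, int, int]:
    """Contiguous row-band sizes for the thirds split; earlier bands take the
    extra rows when n is not divisible by 3 (e.g. 116 -> 39, 39, 38)."""
    if n < 3:
        raise GraphError(f"plain stack needs at least 3 ROIs, got {n}")
    b1 = -(-n // 3)
    b2 = -(-(n - b1) // 2)
    return b1, b2, n - b1 - b2


def build_plain_stack(cm) -> Stack3D:
    """Split the matrix into three contiguous row bands, one per channel.

    The channels sum elementwise back to the source matrix and no entry is
    nonzero in more than one channel.
    """
    M = np.asarray(cm.M, dtype=float)
    n = M.shape[0]
    b1, b2, b3 = plain_band_sizes(n)
    bounds = [(0, b1), (b1, b1 + b2), (b1 + b2, n)]
    channels = np.zeros((n, n, 3))
    for k, (lo, hi) in enumerate(bounds):
        channels[lo:hi, :, k] = M[lo:hi, :]
    return Stack3D(
        subject_id=cm.subject_id,
        atlas=cm.atlas,
        method=cm.method,
        strategy="plain",
        channels=channels,
    )
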