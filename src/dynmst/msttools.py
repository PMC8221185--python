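"""Maximum spanning tree extraction and tree topology measures.

PLI is a similarity (larger = stronger coupling), so the network backbone
is the *maximum* spanning tree: Kruskal's algorithm over edges sorted by
descending weight, with lexicographic (i, j) tie-breaking for exact
reproducibility. The tree on N nodes has m = N - 1 links.

Topology is summarised between the two extremes of tree shape:

* line (path): raw max degree 2, raw leaf count 2, raw diameter N - 1 —
  chained, locally clustered processing;
* star: raw max degree N - 1, raw leaf count N - 1, raw diameter 2 —
  hub-mediated integration with short paths.

Reported measures are normalized so they are comparable across tree
sizes: degree, leaf fraction, diameter and eccentricity are divided by
the link count m; betweenness centrality (BC) by the undirected pair
count (N - 1)(N - 2)/2; tree hierarchy Th = L / (2 m MaxBC) balances
leaf-mediated integration against hub overload. The mean edge weight
(mean PLI over the m tree links) tracks overall coupling strength; all
other measures are purely topological and unchanged by binarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpanningTree:
    """Acyclic connected backbone: N nodes, N-1 weighted edges."""

    n_nodes: int
    edges: list[tuple[int, int, float]]
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError("a spanning tree on N nodes has exactly N-1 edges")
        if not self.node_labels:
            self.node_labels = [str(i) for i in range(self.n_nodes)]
        # connectivity check via union-find (also rejects cycles)
        parent = list(range(self.n_nodes))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j, _ in self.edges:
            ri, rj = find(i), find(j)
            if ri == rj:
                raise ValueError("edge list contains a cycle")
            parent[ri] = rj

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def adjacency_lists(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j, _ in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class MSTMeasureSet:
    """Normalized global tree measures plus per-node vectors.

    Raw (unnormalized) counterparts are kept alongside because the
    line/star extreme structures are naturally stated in raw units.
    """

    n_nodes: int
    diameter: float
    leaf_fraction: float
    eccentricity: np.ndarray
    max_bc: float
    max_degree: float
    tree_hierarchy: float
    mst_pli: float
    node_bc: np.ndarray
    node_degree: np.ndarray
    raw_diameter: int
    raw_leaf_count: int
    raw_max_degree: int
    node_labels: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        """Global measures only, keyed by their conventional short names."""
        return {"D": self.diameter, "Lf": self.leaf_fraction,
                "MaxBC": self.max_bc, "MaxK": self.max_degree,
                "Th": self.tree_hierarchy, "MST_PLI": self.mst_pli}


def max_spanning_tree(adjacency: np.ndarray,
                      node_labels: list[str] | None = None) -> SpanningTree:
    """Kruskal maximum spanning tree of a symmetric nonnegative matrix.

    Edges are taken in order of descending weight; exact weight ties are
    broken by ascending (i, j), so the result is deterministic. Zero
    entries are admitted as (weightless) edges so the tree always exists.
    """
    adjacency = np.asarray(adjacency, dtype=float)
    n = adjacency.shape[0]
    if adjacency.ndim != 2 or adjacency.shape[1] != n:
        raise ValueError("adjacency must be square")
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not np.allclose(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    if adjacency.min() < 0:
        raise ValueError("weights must be nonnegative")

    iu, ju = np.triu_indices(n, k=1)
    weights = adjacency[iu, ju]
    order = np.lexsort((ju, iu, -weights))

    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: list[tuple[int, int, float]] = []
    for k in order:
        i, j, w = int(iu[k]), int(ju[k]), float(weights[k])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j, w))
            if len(edges) == n - 1:
                break
    return SpanningTree(n_nodes=n, edges=edges,
                        node_labels=list(node_labels or []))


def _bfs_hops(nbrs: list[list[int]], source: int) -> np.ndarray:
    n = len(nbrs)
    dist = np.full(n, -1, dtype=int)
    dist[source] = 0
    queue = [source]
    while queue:
        u = queue.pop(0)
        for v in nbrs[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _tree_betweenness(tree: SpanningTree) -> np.ndarray:
    """Normalized betweenness for a tree, exactly.

    Paths in a tree are unique, so BC(v) equals the number of node pairs
    separated by v: C(N-1, 2) minus the pairs that stay within a single
    branch hanging off v. Normalization is the undirected pair count
    C(N-1, 2).
    """
    n = tree.n_nodes
    nbrs = tree.adjacency_lists()
    total = (n - 1) * (n - 2) / 2.0
    bc = np.zeros(n)
    if total == 0:
        return bc
    for v in range(n):
        within = 0.0
        seen = {v}
        for start in nbrs[v]:
            if start in seen:
                continue
            # size of the branch rooted at `start` when v is removed
            stack, size = [start], 0
            seen.add(start)
            while stack:
                u = stack.pop()
                size += 1
                for w in nbrs[u]:
                    if w not in seen and w != v:
                        seen.add(w)
                        stack.append(w)
            within += size * (size - 1) / 2.0
        bc[v] = (total - within) / total
    return bc


def mst_measures(tree: SpanningTree) -> MSTMeasureSet:
    """Compute the full measure suite for one spanning tree."""
    n = tree.n_nodes
    m = n - 1
    deg = tree.degrees()
    leaves = int(np.sum(deg == 1))
    nbrs = tree.adjacency_lists()

    hops = np.stack([_bfs_hops(nbrs, s) for s in range(n)])
    ecc_raw = hops.max(axis=1)
    diameter_raw = int(ecc_raw.max())

    bc = _tree_betweenness(tree)
    max_bc = float(bc.max())
    weights = np.array([w for _, _, w in tree.edges], dtype=float)

    th = leaves / (2.0 * m * max_bc) if max_bc > 0 else np.nan
    return MSTMeasureSet(
        n_nodes=n,
        diameter=diameter_raw / m,
        leaf_fraction=leaves / m,
        eccentricity=ecc_raw / m,
        max_bc=max_bc,
        max_degree=int(deg.max()) / m,
        tree_hierarchy=th,
        mst_pli=float(weights.mean()),
        node_bc=bc,
        node_degree=deg / m,
        raw_diameter=diameter_raw,
        raw_leaf_count=leaves,
        raw_max_degree=int(deg.max()),
        node_labels=list(tree.node_labels),
    )


def binarize(tree: SpanningTree) -> SpanningTree:
    """Same topology with unit edge weights.

    All topological measures are invariant; the mean-edge-PLI measure is
    defined on the pre-binarization weights.
    """
    return SpanningTree(n_nodes=tree.n_nodes,
                        edges=[(i, j, 1.0) for i, j, _ in tree.edges],
                        node_labels=list(tree.node_labels))
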