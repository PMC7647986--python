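"""Gyral 3-hinge identification on triangulated cortical surfaces.

The pipeline has four stages, run in order by :func:`detect_hinges`:

1. **Gyral altitude mapping** — signed displacement of each vertex from the
   mid-surface obtained by heavy Laplacian smoothing; positive on the
   outward-normal (gyral) side.
2. **Gyral crest segmentation** — a watershed flood of the altitude map:
   vertices below a threshold level flood into sulcal basins grown from
   local minima, while the above-level region plus flooding-collision
   ridges form the gyral crest mask.
3. **Tree construction** — a geodesic distance transform of the crest
   region to its border, then tree marching from each crest component's
   maximum-distance centre outward along descending distance.
4. **Crest-line extraction** — iterative pruning of leaf branches shorter
   than a length threshold; remaining trunks are the gyral crest lines and
   vertices of trunk degree >= 3 are gyral hinges.  Hinges with exactly
   three arms are the 3-hinges of interest.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .surface import SurfaceMesh

__all__ = [
    "BasinSegmentation", "CrestGraph", "compute_gyral_altitude",
    "watershed_segment", "distance_transform_crest", "build_crest_trees",
    "prune_and_extract", "detect_hinges",
]

CREST = -1  # basin_id value on crest vertices


@dataclass
class BasinSegmentation:
    """Watershed segmentation of the altitude map.

    ``basin_id[v] == -1`` marks crest vertices; basins are labelled
    ``0..n_basins-1`` and are each edge-connected.
    """

    basin_id: np.ndarray
    crest_mask: np.ndarray
    level: float

    @property
    def n_basins(self) -> int:
        ids = self.basin_id[self.basin_id >= 0]
        return int(ids.max()) + 1 if ids.size else 0


@dataclass
class CrestGraph:
    """Pruned gyral crest-line skeleton.

    ``hinges`` lists ``(vertex_index, arm_count)`` for vertices whose degree
    in the pruned trunk graph is at least 3; ``arm_count == 3`` identifies
    3-hinges.
    """

    nodes: np.ndarray                       # crest-line vertex indices
    edges: np.ndarray                       # (k, 2) vertex index pairs
    hinges: list[tuple[int, int]]
    distance: dict[int, float] = field(default_factory=dict)

    @property
    def three_hinges(self) -> list[int]:
        return [v for v, a in self.hinges if a == 3]

    def degree(self) -> dict[int, int]:
        deg = {int(v): 0 for v in self.nodes}
        for a, b in self.edges:
            deg[int(a)] += 1
            deg[int(b)] += 1
        return deg


def compute_gyral_altitude(mesh: SurfaceMesh,
                           smoothing_iters: int = 200) -> np.ndarray:
    """Signed mm distance from each vertex to the smoothed mid-surface.

    The mid-surface is obtained by ``smoothing_iters`` rounds of uniform
    Laplacian smoothing (lambda = 0.5).  The sign is positive on the side of
    the outward vertex normal, so gyral crowns get positive altitude and
    sulcal fundi negative.
    """
    if smoothing_iters < 1:
        raise ValueError("smoothing_iters must be >= 1")
    if np.any(mesh.face_areas <= 0):
        raise ValueError("degenerate mesh: zero-area faces")

    n = mesh.n_vertices
    g = mesh.edge_graph().copy()
    g.data[:] = 1.0
    deg = np.asarray(g.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    avg = sparse.diags(1.0 / deg) @ g

    smooth = mesh.vertices.copy()
    for _ in range(smoothing_iters):
        smooth = 0.5 * smooth + 0.5 * (avg @ smooth)

    disp = mesh.vertices - smooth
    normals = mesh.vertex_normals()
    altitude = np.einsum("ij,ij->i", disp, normals)
    return altitude


def watershed_segment(mesh: SurfaceMesh, altitude: np.ndarray,
                      level: float = 0.0) -> BasinSegmentation:
    """Watershed flood of the altitude map below ``level``.

    Below-level vertices are processed in ascending altitude order (ties by
    vertex index, which also resolves plateaus to the first-arriving basin).
    A vertex with no flooded neighbour seeds a new basin at a local minimum;
    one touching a single basin joins it; one touching several basins is a
    flooding-collision ridge and joins the crest.  The crest mask is the
    union of the at/above-level region and the collision ridges: the
    watershed line separating shallow sulcal water sources.
    """
    altitude = np.asarray(altitude, dtype=float)
    if altitude.shape != (mesh.n_vertices,):
        raise ValueError("altitude must be per-vertex")
    if np.ptp(altitude) == 0:
        raise ValueError("constant altitude field: no basins to segment")

    n = mesh.n_vertices
    basin_id = np.full(n, CREST, dtype=np.int64)
    below = altitude < level
    neighbors = mesh.vertex_neighbors()

    # regional minima: connected equal-altitude plateaus of below-level
    # vertices with no strictly lower neighbour anywhere on the plateau
    e = mesh.edges()
    plateau = below[e[:, 0]] & below[e[:, 1]] \
        & (altitude[e[:, 0]] == altitude[e[:, 1]])
    pe = e[plateau]
    plat_graph = sparse.csr_matrix(
        (np.ones(len(pe)), (pe[:, 0], pe[:, 1])), shape=(n, n))
    _, comp = csgraph.connected_components(plat_graph + plat_graph.T,
                                           directed=False)
    has_lower = np.zeros(n, dtype=bool)
    for v in np.flatnonzero(below):
        if any(altitude[u] < altitude[v] for u in neighbors[v]):
            has_lower[v] = True
    comp_has_lower = np.zeros(comp.max() + 1, dtype=bool)
    np.add.at(comp_has_lower, comp[below], has_lower[below])
    is_min = below & ~comp_has_lower[comp]

    # label each regional-minimum plateau as one basin seed
    min_comps = np.unique(comp[is_min])
    remap = {c: i for i, c in enumerate(min_comps)}
    heap: list[tuple[float, int]] = []
    for v in np.flatnonzero(is_min):
        basin_id[v] = remap[comp[v]]
    for v in np.flatnonzero(is_min):
        for u in neighbors[v]:
            if below[u] and basin_id[u] == CREST:
                heapq.heappush(heap, (altitude[u], int(u)))

    # simultaneous flooding in ascending altitude (ties: vertex index)
    done = is_min.copy()
    while heap:
        _, v = heapq.heappop(heap)
        if done[v]:
            continue
        done[v] = True
        labels = {basin_id[u] for u in neighbors[v]
                  if below[u] and basin_id[u] >= 0}
        if len(labels) == 1:
            basin_id[v] = labels.pop()
        else:
            basin_id[v] = CREST  # flooding-collision ridge
        for u in neighbors[v]:
            if below[u] and not done[u]:
                heapq.heappush(heap, (altitude[u], int(u)))

    crest_mask = basin_id == CREST
    return BasinSegmentation(basin_id=basin_id, crest_mask=crest_mask,
                             level=float(level))


def distance_transform_crest(mesh: SurfaceMesh,
                             seg: BasinSegmentation) -> np.ndarray:
    """Geodesic distance of each crest vertex to the crest border, mm.

    The border is the set of crest vertices adjacent to at least one basin
    vertex; border vertices get distance 0 and interior crest vertices the
    shortest-path distance along mesh edges restricted to the crest.
    Non-crest vertices get NaN.
    """
    crest = seg.crest_mask
    if not crest.any():
        raise ValueError("empty crest mask")

    neighbors = mesh.vertex_neighbors()
    border = np.zeros(mesh.n_vertices, dtype=bool)
    for v in np.flatnonzero(crest):
        if any(not crest[u] for u in neighbors[v]):
            border[v] = True
    if not border.any():
        raise ValueError("crest has no border: whole surface is crest")

    g = mesh.edge_graph().tocoo()
    keep = crest[g.row] & crest[g.col]
    sub = sparse.csr_matrix((g.data[keep], (g.row[keep], g.col[keep])),
                            shape=g.shape)
    d = csgraph.dijkstra(sub, directed=False,
                         indices=np.flatnonzero(border), min_only=True)
    dist = np.full(mesh.n_vertices, np.nan)
    dist[crest] = d[crest]
    if np.any(~np.isfinite(dist[crest])):
        raise ValueError("crest component with no reachable border")
    return dist


def build_crest_trees(mesh: SurfaceMesh, seg: BasinSegmentation,
                      distance: np.ndarray) -> np.ndarray:
    """Tree-march each crest component from its distance maximum outward.

    Returns per-vertex parent pointers (-2 for non-crest vertices, -1 for
    roots).  Each connected crest component yields one tree rooted at its
    maximum-distance vertex (ties broken by lowest index); every other
    crest vertex attaches to its already-claimed neighbour of largest
    distance, so tree paths follow descending distance gradients from the
    crest centre to the border.
    """
    n = mesh.n_vertices
    crest = seg.crest_mask
    neighbors = mesh.vertex_neighbors()
    parent = np.full(n, -2, dtype=np.int64)
    claimed = np.zeros(n, dtype=bool)

    crest_idx = np.flatnonzero(crest)
    # components of the crest subgraph
    g = mesh.edge_graph().tocoo()
    keep = crest[g.row] & crest[g.col]
    sub = sparse.csr_matrix((np.ones(keep.sum()), (g.row[keep], g.col[keep])),
                            shape=(n, n))
    n_comp, comp = csgraph.connected_components(sub, directed=False)

    for c in np.unique(comp[crest_idx]):
        members = crest_idx[comp[crest_idx] == c]
        root = members[np.lexsort((members, -distance[members]))[0]]
        parent[root] = -1
        claimed[root] = True
        # max-distance-first frontier growth (ties: lowest vertex index)
        heap: list[tuple[float, int]] = []
        for u in neighbors[root]:
            if crest[u]:
                heapq.heappush(heap, (-distance[u], int(u)))
        in_heap = {int(u) for u in neighbors[root] if crest[u]}
        while heap:
            _, v = heapq.heappop(heap)
            if claimed[v]:
                continue
            cands = [int(u) for u in neighbors[v] if claimed[u]]
            best = min(cands, key=lambda u: (-distance[u], u))
            parent[v] = best
            claimed[v] = True
            for u in neighbors[v]:
                u = int(u)
                if crest[u] and not claimed[u] and u not in in_heap:
                    heapq.heappush(heap, (-distance[u], u))
                    in_heap.add(u)
    return parent


def prune_and_extract(mesh: SurfaceMesh, parent: np.ndarray,
                      distance: np.ndarray,
                      length_threshold: float) -> CrestGraph:
    """Prune short side branches of the marching trees; extract trunks.

    The significance of a branch is its maximum downstream path length
    (geodesic mm from the branch's first edge to its deepest leaf).  At
    every tree vertex the deepest child branch is always kept — it is the
    trunk continuation — while any other child branch is deleted when its
    downstream length is below ``length_threshold``.  This removes every
    leaf-to-bifurcation spur shorter than the threshold, including nested
    ones, without ever eroding the main trunk, and is idempotent.
    Surviving vertices of degree >= 3 are gyral hinges; ``arm_count`` is
    the trunk-graph degree.
    """
    verts = np.flatnonzero(parent >= -1)
    children: dict[int, list[int]] = {int(v): [] for v in verts}
    roots = [int(v) for v in verts if parent[v] == -1]
    for v in verts:
        p = parent[v]
        if p >= 0:
            children[int(p)].append(int(v))

    pos = mesh.vertices

    def edge_len(a: int, b: int) -> float:
        return float(np.linalg.norm(pos[a] - pos[b]))

    # max downstream path length per vertex, children before parents
    topo: list[int] = []
    for r in roots:
        stack = [r]
        while stack:
            v = stack.pop()
            topo.append(v)
            stack.extend(children[v])
    depth = {int(v): 0.0 for v in verts}
    for v in reversed(topo):
        for c in children[v]:
            depth[v] = max(depth[v], edge_len(v, c) + depth[c])

    keep: set[int] = set()
    for r in roots:
        keep.add(r)
        stack = [r]
        while stack:
            v = stack.pop()
            kids = children[v]
            if not kids:
                continue
            branch_len = {c: edge_len(v, c) + depth[c] for c in kids}
            deepest = min(kids, key=lambda c: (-branch_len[c], c))
            for c in kids:
                if c == deepest or branch_len[c] >= length_threshold:
                    keep.add(c)
                    stack.append(c)

    adj: dict[int, set[int]] = {v: set() for v in keep}
    for v in keep:
        p = int(parent[v])
        if p >= 0 and p in keep:
            adj[v].add(p)
            adj[p].add(v)

    nodes = np.array(sorted(adj), dtype=np.int64)
    edges = np.array(sorted({(min(v, u), max(v, u))
                             for v, nb in adj.items() for u in nb}),
                     dtype=np.int64).reshape(-1, 2)
    hinges = [(v, len(adj[v])) for v in sorted(adj) if len(adj[v]) >= 3]
    dist = {int(v): float(distance[v]) for v in nodes
            if np.isfinite(distance[v])}
    return CrestGraph(nodes=nodes, edges=edges, hinges=hinges, distance=dist)


def detect_hinges(mesh: SurfaceMesh, altitude: np.ndarray | None = None,
                  level: float = 0.0,
                  length_threshold: float | None = None,
                  smoothing_iters: int = 200) -> CrestGraph:
    """Full four-stage hinge-detection pipeline.

    ``altitude`` defaults to the mesh's stored altitude, or is computed by
    :func:`compute_gyral_altitude` when absent.  ``length_threshold``
    defaults to 6x the median mesh edge length.
    """
    if altitude is None:
        altitude = (mesh.altitude if mesh.altitude is not None
                    else compute_gyral_altitude(mesh, smoothing_iters))
    if length_threshold is None:
        e = mesh.edges()
        lens = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]],
                              axis=1)
        length_threshold = 6.0 * float(np.median(lens))
    seg = watershed_segment(mesh, altitude, level)
    dist = distance_transform_crest(mesh, seg)
    parent = build_crest_trees(mesh, seg, dist)
    return prune_and_extract(mesh, parent, dist, length_threshold)
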