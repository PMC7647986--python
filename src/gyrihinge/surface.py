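"""Triangulated cortical surface container.

A :class:`SurfaceMesh` holds vertices, triangle faces, and an optional
per-vertex *gyral altitude* scalar: the signed displacement of each vertex
from the mid-surface separating gyri from sulci (positive on gyral crowns,
negative in sulcal fundi).  All coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


@dataclass
class SurfaceMesh:
    """Edge-manifold triangle mesh with optional per-vertex altitude.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex index triples
    altitude : (n,) float array or None
        Signed gyral altitude per vertex, mm.
    """

    vertices: np.ndarray
    faces: np.ndarray
    altitude: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if self.altitude is not None:
            self.altitude = np.asarray(self.altitude, dtype=np.float64)
            if self.altitude.shape != (len(self.vertices),):
                raise ValueError("altitude must be per-vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def face_areas(self) -> np.ndarray:
        if "face_areas" not in self._cache:
            v = self.vertices
            a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
            b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
            self._cache["face_areas"] = 0.5 * np.linalg.norm(
                np.cross(a, b), axis=1)
        return self._cache["face_areas"]

    @property
    def vertex_area(self) -> np.ndarray:
        """Barycentric vertex area: one third of incident triangle areas, mm^2."""
        if "vertex_area" not in self._cache:
            va = np.zeros(self.n_vertices)
            fa = self.face_areas / 3.0
            for k in range(3):
                np.add.at(va, self.faces[:, k], fa)
            self._cache["vertex_area"] = va
        return self._cache["vertex_area"]

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges as (n_edges, 2) sorted index pairs."""
        if "edges" not in self._cache:
            e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                           self.faces[:, [2, 0]]])
            e.sort(axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    def edge_graph(self) -> sparse.csr_matrix:
        """Sparse symmetric graph of mesh edges weighted by Euclidean length."""
        if "edge_graph" not in self._cache:
            e = self.edges()
            w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                               axis=1)
            n = self.n_vertices
            g = sparse.coo_matrix(
                (np.concatenate([w, w]),
                 (np.concatenate([e[:, 0], e[:, 1]]),
                  np.concatenate([e[:, 1], e[:, 0]]))), shape=(n, n))
            self._cache["edge_graph"] = g.tocsr()
        return self._cache["edge_graph"]

    def vertex_neighbors(self) -> list[np.ndarray]:
        """Adjacency lists (sorted vertex indices) from the edge graph."""
        if "neighbors" not in self._cache:
            g = self.edge_graph()
            self._cache["neighbors"] = [
                g.indices[g.indptr[i]:g.indptr[i + 1]]
                for i in range(self.n_vertices)
            ]
        return self._cache["neighbors"]

    def check_edge_manifold(self) -> None:
        """Raise if any edge borders more than two faces."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        if counts.size and counts.max() > 2:
            raise ValueError("mesh is not edge-manifold")

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit length where defined)."""
        if "vertex_normals" not in self._cache:
            v = self.vertices
            fn = np.cross(v[self.faces[:, 1]] - v[self.faces[:, 0]],
                          v[self.faces[:, 2]] - v[self.faces[:, 0]])
            vn = np.zeros_like(v)
            for k in range(3):
                np.add.at(vn, self.faces[:, k], fn)
            norms = np.linalg.norm(vn, axis=1)
            norms[norms == 0] = 1.0
            self._cache["vertex_normals"] = vn / norms[:, None]
        return self._cache["vertex_normals"]
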