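"""Equal-area surface parcellation and convolution-class patch labelling.

Patches are the nodes of the structural connectome.  Each patch is labelled
by the folding pattern it covers: a patch with more than half of its area
inside sulcal basins is **SULCAL**; a remaining (gyral) patch touched by a
detected 3-hinge vertex is **H3**; the other gyral patches are **H2**
(ordinary two-armed gyral segments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .hinges import BasinSegmentation, CrestGraph
from .surface import SurfaceMesh

__all__ = ["H3", "H2", "SULCAL", "CLASS_NAMES", "Parcellation",
           "PatchLabels", "equal_area_parcellate", "label_patches"]

H3, H2, SULCAL = 0, 1, 2
CLASS_NAMES = {H3: "H3", H2: "H2", SULCAL: "SULCAL"}


@dataclass
class Parcellation:
    """Per-vertex patch assignment with per-patch surface areas (mm^2)."""

    patch_id: np.ndarray
    patch_area: np.ndarray
    hemisphere: np.ndarray | None = None

    @property
    def n_patches(self) -> int:
        return len(self.patch_area)

    def vertices_of(self, patch: int) -> np.ndarray:
        return np.flatnonzero(self.patch_id == patch)


@dataclass
class PatchLabels:
    """Convolution class per patch: H3 (0), H2 (1) or SULCAL (2)."""

    classes: np.ndarray
    sulcal_fraction: np.ndarray
    hinge_count: np.ndarray

    @property
    def n_patches(self) -> int:
        return len(self.classes)

    def count(self, cls: int) -> int:
        return int(np.sum(self.classes == cls))


def _patch_components(patch_id: np.ndarray, graph: sparse.csr_matrix,
                      patch: int) -> tuple[int, np.ndarray]:
    verts = np.flatnonzero(patch_id == patch)
    sub = graph[verts][:, verts]
    n_comp, comp = csgraph.connected_components(sub, directed=False)
    return n_comp, comp


def equal_area_parcellate(mesh: SurfaceMesh, n_patches: int,
                          seed: int = 0, max_iters: int = 50,
                          area_ratio: float = 1.5) -> Parcellation:
    """Partition the surface into edge-connected patches of near-equal area.

    Farthest-point seeding on the mesh edge graph, geodesic Voronoi
    assignment, then Lloyd-style iterations: seeds move to patch medoids
    and multiplicative distance weights grow/shrink with patch area until
    the max/min area ratio drops under ``area_ratio`` (or ``max_iters`` is
    reached).  Deterministic for a given seed.
    """
    n = mesh.n_vertices
    if not (1 <= n_patches <= n):
        raise ValueError("n_patches must be in [1, n_vertices]")
    g = mesh.edge_graph()
    varea = mesh.vertex_area

    if n_patches == 1:
        return Parcellation(patch_id=np.zeros(n, dtype=np.int64),
                            patch_area=np.array([varea.sum()]))

    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(n))]
    d = csgraph.dijkstra(g, directed=False, indices=seeds[0], min_only=True)
    for _ in range(n_patches - 1):
        cand = int(np.argmax(d))
        seeds.append(cand)
        d_new = csgraph.dijkstra(g, directed=False, indices=cand,
                                 min_only=True)
        d = np.minimum(d, d_new)

    weights = np.ones(n_patches)
    target = varea.sum() / n_patches
    patch_id = None
    for _ in range(max_iters):
        dists = csgraph.dijkstra(g, directed=False, indices=seeds)
        patch_id = np.argmin(dists * weights[:, None], axis=0)
        patch_id = _repair_fragments(patch_id, g, n_patches)
        areas = np.bincount(patch_id, weights=varea, minlength=n_patches)
        if areas.min() > 0 and areas.max() / areas.min() <= area_ratio:
            break
        # re-centre each seed at the vertex nearest the patch centroid
        for k in range(n_patches):
            verts = np.flatnonzero(patch_id == k)
            if verts.size:
                centroid = mesh.vertices[verts].mean(axis=0)
                off = np.linalg.norm(mesh.vertices[verts] - centroid, axis=1)
                seeds[k] = int(verts[np.argmin(off)])
        weights *= (areas / max(target, 1e-12)) ** 0.5
        weights = np.clip(weights, 1e-3, 1e3)

    areas = np.bincount(patch_id, weights=varea, minlength=n_patches)
    if areas.min() <= 0:
        raise ValueError("n_patches exceeds achievable connectivity: "
                         "empty patch produced")
    return Parcellation(patch_id=patch_id.astype(np.int64), patch_area=areas)


def _repair_fragments(patch_id: np.ndarray, g: sparse.csr_matrix,
                      n_patches: int) -> np.ndarray:
    """Reassign disconnected patch fragments to the adjacent majority patch."""
    patch_id = patch_id.copy()
    coo = g.tocoo()
    for k in range(n_patches):
        verts = np.flatnonzero(patch_id == k)
        if verts.size == 0:
            continue
        sub = g[verts][:, verts]
        n_comp, comp = csgraph.connected_components(sub, directed=False)
        if n_comp <= 1:
            continue
        sizes = np.bincount(comp)
        main = int(np.argmax(sizes))
        for c in range(n_comp):
            if c == main:
                continue
            frag = verts[comp == c]
            mask = np.isin(coo.row, frag) & ~np.isin(coo.col, frag)
            nb_patches = patch_id[coo.col[mask]]
            nb_patches = nb_patches[nb_patches != k]
            if nb_patches.size:
                patch_id[frag] = np.bincount(nb_patches).argmax()
    return patch_id


def label_patches(parc: Parcellation, seg: BasinSegmentation,
                  crest: CrestGraph, mesh: SurfaceMesh) -> PatchLabels:
    """Assign each patch its convolution class.

    ``sulcal_fraction`` is the vertex-area fraction of the patch lying in
    sulcal basins; a patch is SULCAL when it exceeds 0.5.  Among gyral
    patches, any patch containing a detected hinge vertex is H3 and the
    rest are H2.  The sulcal rule is applied first, so a sulcal-majority
    patch stays SULCAL even if it contains a hinge.
    """
    if len(parc.patch_id) != mesh.n_vertices \
            or len(seg.basin_id) != mesh.n_vertices:
        raise ValueError("parcellation/segmentation vertex counts mismatch")
    varea = mesh.vertex_area
    n_p = parc.n_patches
    in_basin = seg.basin_id >= 0
    sulcal_area = np.bincount(parc.patch_id, weights=varea * in_basin,
                              minlength=n_p)
    frac = np.divide(sulcal_area, parc.patch_area,
                     out=np.zeros(n_p), where=parc.patch_area > 0)

    hinge_count = np.zeros(n_p, dtype=np.int64)
    for v, _arms in crest.hinges:
        hinge_count[parc.patch_id[v]] += 1

    classes = np.full(n_p, H2, dtype=np.int64)
    classes[hinge_count >= 1] = H3
    classes[frac > 0.5] = SULCAL
    return PatchLabels(classes=classes, sulcal_fraction=frac,
                       hinge_count=hinge_count)
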