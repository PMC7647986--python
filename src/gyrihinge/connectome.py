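"""Patch-level structural connectome construction from streamlines.

Connective strength between two patches is the number of streamlines
terminating in both: each streamline endpoint snaps to the patch of its
nearest surface vertex (within a snap radius), and w_ij counts fibers whose
two endpoints land in distinct cortical patches i and j.  Fibers ending
within a single patch or off the cortex are excluded from the weight matrix
but retained for conservation audits and class-wise connection tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .parcellation import H2, H3, SULCAL, Parcellation, PatchLabels
from .surface import SurfaceMesh

__all__ = ["NONCORTICAL", "StreamlineSet", "WeightedNetwork",
           "assign_endpoints", "build_connectivity", "termination_density",
           "class_connection_counts"]

NONCORTICAL = -1


@dataclass
class StreamlineSet:
    """Ordered 3-D polylines (mm), each with at least two points."""

    polylines: list[np.ndarray]

    def __post_init__(self) -> None:
        self.polylines = [np.asarray(p, dtype=np.float64)
                          for p in self.polylines]
        for p in self.polylines:
            if p.ndim != 2 or p.shape[1] != 3 or len(p) < 2:
                raise ValueError("each polyline must be (>=2, 3)")

    @property
    def total_count(self) -> int:
        return len(self.polylines)

    def endpoints(self) -> np.ndarray:
        """(n, 2, 3) array of first/last points."""
        if not self.polylines:
            return np.empty((0, 2, 3))
        return np.stack([[p[0], p[-1]] for p in self.polylines])


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative patch-level connectivity.

    ``weights[i, j]`` is the streamline count (or planted weight) between
    nodes i and j; the diagonal is zero.  The binary adjacency and the
    max-scaled weights used by the Onnela clustering coefficient are
    derived on demand and never stored separately.
    """

    weights: np.ndarray
    labels: PatchLabels | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        return (self.weights > 0).astype(np.float64)

    @property
    def scaled_weights(self) -> np.ndarray:
        mx = self.weights.max()
        if mx == 0:
            raise ValueError("all-zero weight matrix cannot be scaled")
        return self.weights / mx


def assign_endpoints(streamlines: StreamlineSet, mesh: SurfaceMesh,
                     parc: Parcellation, snap_mm: float = 2.0
                     ) -> list[tuple[int, int]]:
    """Map each streamline to an order-normalised patch pair (i <= j).

    An endpoint farther than ``snap_mm`` from every surface vertex is
    NONCORTICAL (-1).
    """
    if snap_mm <= 0:
        raise ValueError("snap_mm must be positive")
    if streamlines.total_count == 0:
        return []
    tree = cKDTree(mesh.vertices)
    ends = streamlines.endpoints().reshape(-1, 3)
    dist, idx = tree.query(ends)
    patch = np.where(dist <= snap_mm, parc.patch_id[idx], NONCORTICAL)
    patch = patch.reshape(-1, 2)
    return [(int(min(a, b)), int(max(a, b))) for a, b in patch]


def build_connectivity(pairs: list[tuple[int, int]],
                       n_patches: int) -> tuple[WeightedNetwork, dict]:
    """Count fiber endpoint pairs into a symmetric weight matrix.

    Returns the network plus an audit dict with ``within_patch`` and
    ``noncortical`` exclusion counts; cortical edge fibers (W.sum()/2)
    plus exclusions equal the total fiber count.
    """
    w = np.zeros((n_patches, n_patches))
    within = 0
    noncort = 0
    for i, j in pairs:
        if i == NONCORTICAL or j == NONCORTICAL:
            noncort += 1
        elif i == j:
            within += 1
        else:
            if not (0 <= i < n_patches and 0 <= j < n_patches):
                raise ValueError(f"patch index out of range: ({i}, {j})")
            w[i, j] += 1
            w[j, i] += 1
    audit = {"within_patch": within, "noncortical": noncort,
             "total": len(pairs)}
    return WeightedNetwork(weights=w), audit


def termination_density(streamlines: StreamlineSet, mesh: SurfaceMesh,
                        snap_mm: float = 2.0) -> np.ndarray:
    """Fiber termination density: endpoints per mm^2 of vertex area."""
    varea = mesh.vertex_area
    if np.any(varea <= 0):
        raise ValueError("mesh has zero-area vertices")
    counts = np.zeros(mesh.n_vertices)
    if streamlines.total_count:
        tree = cKDTree(mesh.vertices)
        ends = streamlines.endpoints().reshape(-1, 3)
        dist, idx = tree.query(ends)
        hit = idx[dist <= snap_mm]
        np.add.at(counts, hit, 1.0)
    return counts / varea


def class_connection_counts(pairs: list[tuple[int, int]],
                            labels: PatchLabels, patch_area: np.ndarray,
                            non_includes_sulcal: bool = True,
                            area_unit_mm2: float = 100.0) -> np.ndarray:
    """Area-corrected 3x3 fiber-count table over {H3, H2, NON}.

    Raw fiber counts between endpoint classes are divided by the summed
    surface area (in units of ``area_unit_mm2`` mm^2, i.e. cm^2 by default)
    of all patches belonging to the two classes.  NON covers noncortical
    terminations and, by default, sulcal patches.
    """
    NON = 2

    def cls_of(p: int) -> int:
        if p == NONCORTICAL:
            return NON
        c = labels.classes[p]
        if c == H3:
            return 0
        if c == H2:
            return 1
        return NON  # sulcal folds into NON (dropped earlier otherwise)

    raw = np.zeros((3, 3))
    for i, j in pairs:
        if not non_includes_sulcal:
            # sulcal endpoints are dropped entirely in this mode
            if (i != NONCORTICAL and labels.classes[i] == SULCAL) or \
                    (j != NONCORTICAL and labels.classes[j] == SULCAL):
                continue
        a, b = cls_of(i), cls_of(j)
        raw[a, b] += 1
        if a != b:
            raw[b, a] += 1

    area = np.zeros(3)
    area[0] = patch_area[labels.classes == H3].sum()
    area[1] = patch_area[labels.classes == H2].sum()
    area[2] = patch_area[labels.classes == SULCAL].sum() \
        if non_includes_sulcal else 0.0
    area = area / area_unit_mm2

    table = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            denom = area[a] if a == b else area[a] + area[b]
            table[a, b] = raw[a, b] / denom if denom > 0 else 0.0
    return table
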