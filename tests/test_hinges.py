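"""Hinge-detection stages: altitude, watershed, distance, trees, pruning."""

import numpy as np
import pytest

from gyrihinge import (SurfaceMesh, build_crest_trees, compute_gyral_altitude,
                       detect_hinges, distance_transform_crest,
                       prune_and_extract, watershed_segment)
from gyrihinge.hinges import CREST


def grid_mesh(altitude_fn, nx=21, ny=21, spacing=1.0):
    """Rectangular sheet with z = altitude for watershed tests."""
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    alt = altitude_fn(gx, gy).ravel()
    vertices = np.column_stack([gx.ravel(), gy.ravel(), alt])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = a + ny
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return SurfaceMesh(vertices=vertices, faces=np.array(faces),
                       altitude=alt)


def two_pit_altitude(gx, gy):
    """Two wide Gaussian pits whose below-level floods collide at x = 10."""
    pit1 = np.exp(-((gx - 5) ** 2 + (gy - 10) ** 2) / 18.0)
    pit2 = np.exp(-((gx - 15) ** 2 + (gy - 10) ** 2) / 18.0)
    return 1.0 - 3.0 * (pit1 + pit2)


def one_pit_altitude(gx, gy):
    return 1.0 - 3.0 * np.exp(-((gx - 10) ** 2 + (gy - 10) ** 2) / 12.0)


def test_altitude_sign_convention(single_junction_mesh):
    mesh, gt = single_junction_mesh
    alt = compute_gyral_altitude(mesh)
    hinge = gt.hinge_locations[0]
    on_ridge = np.linalg.norm(mesh.vertices[:, :2] - hinge[None, :2],
                              axis=1) < 1.0
    far = np.linalg.norm(mesh.vertices[:, :2] - hinge[None, :2],
                         axis=1) > 25.0
    assert alt[on_ridge].mean() > 0
    assert alt[far].mean() < alt[on_ridge].mean()


def test_altitude_rejects_bad_iters(single_junction_mesh):
    mesh, _ = single_junction_mesh
    with pytest.raises(ValueError):
        compute_gyral_altitude(mesh, smoothing_iters=0)


def test_watershed_two_pits_collide():
    mesh = grid_mesh(two_pit_altitude)
    seg = watershed_segment(mesh, mesh.altitude, level=0.0)
    assert seg.n_basins == 2
    # collision ridge: some below-level vertices end up crest
    below = mesh.altitude < 0.0
    assert (seg.crest_mask & below).any()
    # the two pit centres land in different basins
    i1 = np.argmin(np.linalg.norm(mesh.vertices[:, :2] - [5, 10], axis=1))
    i2 = np.argmin(np.linalg.norm(mesh.vertices[:, :2] - [15, 10], axis=1))
    assert seg.basin_id[i1] != seg.basin_id[i2]
    assert seg.basin_id[i1] >= 0 and seg.basin_id[i2] >= 0


def test_watershed_single_pit():
    mesh = grid_mesh(one_pit_altitude)
    seg = watershed_segment(mesh, mesh.altitude, level=0.0)
    assert seg.n_basins == 1
    below = mesh.altitude < 0.0
    # no collision: every below-level vertex belongs to the basin
    assert (seg.basin_id[below] == 0).all()


def test_watershed_partition_property():
    mesh = grid_mesh(two_pit_altitude)
    seg = watershed_segment(mesh, mesh.altitude, level=0.0)
    below = mesh.altitude < 0.0
    # every vertex is either crest or in a basin; above-level is crest
    assert ((seg.basin_id >= 0) | seg.crest_mask).all()
    assert seg.crest_mask[~below].all()
    assert (seg.basin_id[~below] == CREST).all()


def test_watershed_threshold_crest_monotone_without_collisions():
    mesh = grid_mesh(one_pit_altitude)
    low = watershed_segment(mesh, mesh.altitude, level=-0.5)
    high = watershed_segment(mesh, mesh.altitude, level=0.5)
    assert (high.crest_mask <= low.crest_mask).all()
    assert high.crest_mask.sum() < low.crest_mask.sum()


def test_watershed_rejects_constant_field():
    mesh = grid_mesh(lambda gx, gy: np.zeros_like(gx))
    with pytest.raises(ValueError):
        watershed_segment(mesh, mesh.altitude, level=0.0)


def test_distance_transform_border_and_interior():
    mesh = grid_mesh(one_pit_altitude)
    seg = watershed_segment(mesh, mesh.altitude, level=0.0)
    dist = distance_transform_crest(mesh, seg)
    crest = seg.crest_mask
    assert np.isnan(dist[~crest]).all()
    assert np.isfinite(dist[crest]).all()
    neighbors = mesh.vertex_neighbors()
    border = [v for v in np.flatnonzero(crest)
              if any(not crest[u] for u in neighbors[v])]
    assert (dist[border] == 0).all()
    interior = crest.copy()
    interior[border] = False
    assert (dist[interior] > 0).all()


def test_crest_trees_span_and_root_at_maximum():
    mesh = grid_mesh(one_pit_altitude)
    seg = watershed_segment(mesh, mesh.altitude, level=0.0)
    dist = distance_transform_crest(mesh, seg)
    parent = build_crest_trees(mesh, seg, dist)
    crest = seg.crest_mask
    assert (parent[~crest] == -2).all()
    assert (parent[crest] >= -1).all()
    roots = np.flatnonzero(parent == -1)
    assert len(roots) >= 1
    for r in roots:
        assert dist[r] == pytest.approx(np.nanmax(dist))
    # every non-root crest vertex points at another crest vertex
    nonroot = np.flatnonzero(parent >= 0)
    assert crest[parent[nonroot]].all()


def test_prune_straight_ridge_has_no_hinges():
    # a single straight ridge: crest skeleton is a path, no 3-hinges
    def ridge(gx, gy):
        return 2.0 * np.exp(-((gy - 10.0) ** 2) / 2.0) - 0.8

    mesh = grid_mesh(ridge, nx=41, ny=21)
    crest = detect_hinges(mesh, mesh.altitude)
    assert crest.three_hinges == []


def test_detect_single_planted_junction(single_junction_mesh):
    mesh, gt = single_junction_mesh
    crest = detect_hinges(mesh)
    assert len(crest.three_hinges) == 1
    found = mesh.vertices[crest.three_hinges[0]]
    assert np.linalg.norm(found[:2] - gt.hinge_locations[0][:2]) <= 2.0


def test_prune_is_idempotent(single_junction_mesh):
    mesh, _ = single_junction_mesh
    seg = watershed_segment(mesh, mesh.altitude, 0.0)
    dist = distance_transform_crest(mesh, seg)
    parent = build_crest_trees(mesh, seg, dist)
    thr = 6.0
    once = prune_and_extract(mesh, parent, dist, thr)
    # re-prune the surviving forest: parent pointers restricted to kept set
    kept = set(int(v) for v in once.nodes)
    parent2 = np.full_like(parent, -2)
    for v in kept:
        p = int(parent[v])
        parent2[v] = p if (p in kept or p == -1) else -1
    twice = prune_and_extract(mesh, parent2, dist, thr)
    assert set(map(int, twice.nodes)) == kept
    assert twice.hinges == once.hinges
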