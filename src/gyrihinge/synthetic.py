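"""Synthetic inputs with known ground truth for the full pipeline.

Three families of generators:

* **Folded surfaces** — rectangular triangulated sheets whose altitude
  field is a sum of Gaussian ridge bumps along a planted crest skeleton.
  Y-shaped skeleton elements provide ground-truth 3-hinge junctions with
  analytic locations, so hinge-detection recovery can be scored exactly.
* **Network cohorts** — weighted modular graphs in which a designated
  minority of nodes (the planted "3-hinge" hubs) receives boosted edge
  probability, edge weight and cross-module wiring, emulating the
  hub-like contrasts the pipeline is designed to measure.
* **Sparse-coded signal matrices** — X = D @ alpha + noise with known
  per-column support, the ground truth for dictionary-learning recovery.

All generators are pure functions of their seed; cohort subjects draw from
counter-derived per-subject streams so cohorts are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import NONCORTICAL, StreamlineSet
from .connectome import WeightedNetwork
from .parcellation import H2, H3, SULCAL, Parcellation, PatchLabels
from .surface import SurfaceMesh

__all__ = ["SurfaceGroundTruth", "CohortSpec", "SignalGroundTruth",
           "gen_folded_surface", "gen_network_cohort", "gen_streamlines",
           "gen_signal_matrix", "planted_weight_matrix"]

# ridge geometry (mm): bump height/width and basin depth chosen so crest
# half-width is ~1.8 mm at the default altitude level of 0
RIDGE_HEIGHT = 4.0
RIDGE_SIGMA = 1.5
BASIN_DEPTH = 1.5
ARM_LENGTH = 12.0
CELL = 44.0


@dataclass
class SurfaceGroundTruth:
    """Planted crest skeleton of a synthetic folded sheet."""

    hinge_locations: list[np.ndarray]     # 3-D points (mm)
    ridge_skeleton: list[np.ndarray]      # polylines (k, 3)
    basin_count: int


@dataclass
class CohortSpec:
    """Conditions for a planted-hub network cohort.

    ``hub_degree_boost`` multiplies both edge probability and edge weight
    on hub-incident pairs by (1 + boost); ``hub_crossmodule_prob`` replaces
    the background cross-module edge probability for hub pairs.
    ``rich_club_prob`` densifies hub-hub pairs (both endpoints H3) so the
    hub sub-network is self-sustaining under s-core pruning; it is scaled
    by min(boost, 1) so that with boost = 0 and cross-module probability
    equal to the background, H3 and H2 nodes are exchangeable (a null
    cohort).
    """

    n_subjects: int = 10
    n_patches: int = 200
    n_h3: int = 25
    n_h2: int = 100
    hub_degree_boost: float = 1.0
    hub_crossmodule_prob: float = 0.2
    rich_club_prob: float = 0.75
    n_modules: int = 4
    noise_sd: float = 0.05
    seed: int = 0
    background_p_in: float = 0.35
    background_p_out: float = 0.05
    sulcal_attenuation: float = 0.5

    def __post_init__(self) -> None:
        if self.n_h3 + self.n_h2 > self.n_patches:
            raise ValueError("n_h3 + n_h2 must not exceed n_patches")
        for p in (self.hub_crossmodule_prob, self.rich_club_prob,
                  self.background_p_in, self.background_p_out):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.hub_degree_boost < 0 or self.noise_sd < 0:
            raise ValueError("boost and noise_sd must be nonnegative")
        if self.n_modules > self.n_patches:
            raise ValueError("n_modules exceeds n_patches")


@dataclass
class SignalGroundTruth:
    """True dictionary and sparse coefficients behind a signal matrix."""

    true_dictionary: np.ndarray   # (t, k)
    true_coefficients: np.ndarray  # (k, n)
    support_counts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.support_counts is None:
            self.support_counts = (
                np.abs(self.true_coefficients) > 0).sum(axis=0)


def _segment_distances(points: np.ndarray, segs: np.ndarray) -> np.ndarray:
    """Min distance from each 2-D point to a set of 2-D segments."""
    a, b = segs[:, 0], segs[:, 1]                      # (m, 2)
    ab = b - a
    ab2 = np.maximum((ab ** 2).sum(axis=1), 1e-12)
    ap = points[:, None, :] - a[None, :, :]            # (n, m, 2)
    t = np.clip(np.einsum("nmd,md->nm", ap, ab) / ab2, 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    return np.linalg.norm(points[:, None, :] - proj, axis=2).min(axis=1)


def gen_folded_surface(n_ridges: int = 0, n_junctions: int = 1,
                       mesh_resolution: float = 1.0, seed: int = 0
                       ) -> tuple[SurfaceMesh, SurfaceGroundTruth]:
    """Triangulated sheet with planted ridge skeleton and Y-junctions.

    Each junction is a Y of three ~120-degree arms; each extra ridge is an
    isolated straight segment.  The altitude field is
    ``RIDGE_HEIGHT * exp(-d^2 / (2 sigma^2)) - BASIN_DEPTH`` of the
    distance to the skeleton, plus a small smooth random undulation, and
    the sheet is embedded with z = altitude so the geometry is genuinely
    folded.
    """
    if n_junctions < 0 or n_ridges < 0:
        raise ValueError("counts must be nonnegative")
    if mesh_resolution <= 0:
        raise ValueError("mesh_resolution must be positive")
    if mesh_resolution > 2.0 * RIDGE_SIGMA:
        raise ValueError(
            "infeasible layout: mesh_resolution too coarse to resolve "
            f"ridges of width {RIDGE_SIGMA} mm")
    rng = np.random.default_rng(seed)

    n_elem = max(n_junctions + n_ridges, 1)
    n_cols = int(np.ceil(np.sqrt(n_elem)))
    n_rows = int(np.ceil(n_elem / n_cols))
    width, height = n_cols * CELL, n_rows * CELL
    if 2 * ARM_LENGTH + 6 * mesh_resolution > CELL:
        raise ValueError("infeasible layout: junctions too close for the "
                         "requested resolution")

    segs: list[np.ndarray] = []
    hinge_xy: list[np.ndarray] = []
    order = rng.permutation(n_rows * n_cols)[:n_elem]
    for e in range(n_elem):
        r, c = divmod(int(order[e]), n_cols)
        center = np.array([(c + 0.5) * CELL, (r + 0.5) * CELL])
        center = center + rng.uniform(-3, 3, size=2)
        if e < n_junctions:
            theta0 = rng.uniform(0, 2 * np.pi)
            for j in range(3):
                ang = theta0 + j * 2 * np.pi / 3 \
                    + rng.uniform(-np.pi / 12, np.pi / 12)
                L = ARM_LENGTH + rng.uniform(-2, 2)
                tip = center + L * np.array([np.cos(ang), np.sin(ang)])
                segs.append(np.stack([center, tip]))
            hinge_xy.append(center)
        else:
            ang = rng.uniform(0, 2 * np.pi)
            u = np.array([np.cos(ang), np.sin(ang)])
            segs.append(np.stack([center - ARM_LENGTH * u,
                                  center + ARM_LENGTH * u]))
    segs_arr = np.stack(segs) if segs else np.zeros((0, 2, 2))

    def altitude_at(xy: np.ndarray) -> np.ndarray:
        if segs_arr.shape[0]:
            d = _segment_distances(xy, segs_arr)
            alt = RIDGE_HEIGHT * np.exp(-d ** 2 / (2 * RIDGE_SIGMA ** 2))
        else:
            alt = np.zeros(len(xy))
        # clamp far tails to an exactly flat basin floor so the background
        # is a single connected plateau (one sulcal water source)
        alt = np.where(alt < 0.05, 0.05, alt)
        return alt - BASIN_DEPTH

    nx = int(round(width / mesh_resolution)) + 1
    ny = int(round(height / mesh_resolution)) + 1
    xs = np.linspace(0, width, nx)
    ys = np.linspace(0, height, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    alt = altitude_at(xy)
    vertices = np.column_stack([xy, alt])

    faces = []
    for r in range(ny - 1):
        for c in range(nx - 1):
            v00 = r * nx + c
            v01 = v00 + 1
            v10 = v00 + nx
            v11 = v10 + 1
            faces.append([v00, v01, v11])
            faces.append([v00, v11, v10])
    mesh = SurfaceMesh(vertices=vertices, faces=np.array(faces),
                       altitude=alt)

    hinges_3d = [np.append(h, altitude_at(h[None])[0]) for h in hinge_xy]
    skeleton = []
    for s in segs:
        ts = np.linspace(0, 1, max(int(np.linalg.norm(s[1] - s[0])), 2) + 1)
        pts = s[0] + ts[:, None] * (s[1] - s[0])
        skeleton.append(np.column_stack([pts, altitude_at(pts)]))
    gt = SurfaceGroundTruth(hinge_locations=hinges_3d,
                            ridge_skeleton=skeleton, basin_count=1)
    return mesh, gt


def planted_weight_matrix(classes: np.ndarray, module: np.ndarray,
                          spec: CohortSpec,
                          rng: np.random.Generator) -> np.ndarray:
    """Symmetric planted-hub weight matrix for the given class labels.

    Hub-incident pairs (any H3 endpoint) get edge probability and weight
    multiplied by (1 + hub_degree_boost), cross-module hub pairs at least
    ``hub_crossmodule_prob``; hub-hub pairs (both endpoints H3) form a
    rich club with edge probability at least rich_club_prob (scaled by
    min(boost, 1)) and a second weight boost, so the hub core survives
    s-core pruning on its own; sulcal-incident pairs are attenuated,
    emulating the sparser sampling of sulcal fundi by deterministic
    tractography.
    """
    n = len(classes)
    hub = classes == H3
    same = module[:, None] == module[None, :]
    prob = np.where(same, spec.background_p_in, spec.background_p_out)
    hub_pair = hub[:, None] | hub[None, :]
    both_hub = hub[:, None] & hub[None, :]
    cross_hub = hub_pair & ~same
    prob = np.where(cross_hub,
                    np.maximum(prob, spec.hub_crossmodule_prob), prob)
    prob = np.where(hub_pair,
                    np.clip(prob * (1 + spec.hub_degree_boost), 0, 0.95),
                    prob)
    rc = spec.rich_club_prob * min(spec.hub_degree_boost, 1.0)
    prob = np.where(both_hub, np.maximum(prob, rc), prob)
    sulcal_pair = (classes[:, None] == SULCAL) | (classes[None] == SULCAL)
    prob = np.where(sulcal_pair, prob * spec.sulcal_attenuation, prob)

    iu = np.triu_indices(n, k=1)
    edge = rng.random(len(iu[0])) < prob[iu]
    w_vals = rng.lognormal(mean=0.0, sigma=0.5, size=len(iu[0]))
    w_vals = np.where(hub_pair[iu], w_vals * (1 + spec.hub_degree_boost),
                      w_vals)
    w_vals = np.where(both_hub[iu], w_vals * (1 + spec.hub_degree_boost),
                      w_vals)
    if spec.noise_sd > 0:
        w_vals = w_vals + rng.normal(0, spec.noise_sd, size=len(w_vals))
    w_vals = np.maximum(w_vals, 0.05) * edge
    w = np.zeros((n, n))
    w[iu] = w_vals
    return w + w.T


def gen_network_cohort(spec: CohortSpec
                       ) -> list[tuple[WeightedNetwork, PatchLabels,
                                       np.ndarray]]:
    """Cohort of weighted modular networks with planted H3 hubs.

    Each subject uses an independent stream derived from (seed, subject),
    so regenerating any subject alone reproduces it.
    """
    out = []
    n = spec.n_patches
    module = (np.arange(n) * spec.n_modules) // n
    for subj in range(spec.n_subjects):
        rng = np.random.default_rng([spec.seed, subj])
        perm = rng.permutation(n)
        classes = np.full(n, SULCAL, dtype=np.int64)
        classes[perm[:spec.n_h3]] = H3
        classes[perm[spec.n_h3:spec.n_h3 + spec.n_h2]] = H2
        hub = classes == H3
        w = planted_weight_matrix(classes, module, spec, rng)

        labels = PatchLabels(classes=classes,
                             sulcal_fraction=(classes == SULCAL).astype(float),
                             hinge_count=(classes == H3).astype(np.int64))
        net = WeightedNetwork(weights=w, labels=labels)
        out.append((net, labels, np.flatnonzero(hub)))
    return out


def gen_streamlines(mesh: SurfaceMesh, parc: Parcellation,
                    target_counts: np.ndarray, total_fibers: int,
                    seed: int = 0) -> StreamlineSet:
    """Streamlines whose endpoint patch pairs reproduce ``target_counts``.

    ``target_counts`` may be (P, P) over patches, or (P+1, P+1) where the
    extra last index plants non-cortical terminations (endpoints placed
    far above the sheet, beyond any snap radius).  The matrix must be
    symmetric and its upper triangle (with diagonal) must sum to
    ``total_fibers``.
    """
    tc = np.asarray(target_counts)
    P = parc.n_patches
    if tc.shape not in {(P, P), (P + 1, P + 1)}:
        raise ValueError("target_counts must be (P, P) or (P+1, P+1)")
    if not np.array_equal(tc, tc.T):
        raise ValueError("target_counts must be symmetric")
    iu = np.triu_indices(tc.shape[0])
    if int(tc[iu].sum()) != total_fibers:
        raise ValueError("target_counts upper triangle must sum to "
                         "total_fibers")
    rng = np.random.default_rng(seed)
    patch_verts = [parc.vertices_of(p) for p in range(P)]
    for p in range(P):
        if np.any(tc[p] > 0) and len(patch_verts[p]) == 0:
            raise ValueError(f"patch {p} has zero vertices")

    normals = mesh.vertex_normals()
    zmax = mesh.vertices[:, 2].max()
    span = mesh.vertices[:, :2].mean(axis=0)

    def endpoint(p: int) -> np.ndarray:
        if p == tc.shape[0] - 1 and tc.shape[0] == P + 1:
            off = rng.uniform(-5, 5, size=2)
            return np.array([span[0] + off[0], span[1] + off[1],
                             zmax + 30.0 + rng.uniform(0, 10)])
        v = int(rng.choice(patch_verts[p]))
        return mesh.vertices[v] + 0.2 * normals[v]

    polylines = []
    for a, b in zip(*iu):
        for _ in range(int(tc[a, b])):
            e0, e1 = endpoint(int(a)), endpoint(int(b))
            mid = 0.5 * (e0 + e1) + np.array([0, 0, 5.0])
            polylines.append(np.stack([e0, mid, e1]))
    order = rng.permutation(len(polylines))
    return StreamlineSet(polylines=[polylines[i] for i in order])


def gen_signal_matrix(t: int, n: int, k: int, sparsity: int = 1,
                      noise_sd: float = 0.0, seed: int = 0
                      ) -> tuple[np.ndarray, SignalGroundTruth]:
    """Signal matrix X = D @ alpha + noise with known sparse supports.

    Dictionary atoms are unit-norm smooth random time series; each of the
    n signal columns mixes exactly ``sparsity`` atoms with coefficients of
    magnitude in [1, 2].
    """
    if sparsity > k:
        raise ValueError("sparsity must not exceed k")
    if min(t, n, k) < 1:
        raise ValueError("t, n, k must be positive")
    rng = np.random.default_rng(seed)
    D = rng.standard_normal((t, k))
    # mild temporal smoothing so atoms resemble slow hemodynamic series
    kernel = np.array([0.25, 0.5, 0.25])
    for _ in range(2):
        D = np.apply_along_axis(
            lambda s: np.convolve(s, kernel, mode="same"), 0, D)
    D /= np.linalg.norm(D, axis=0, keepdims=True)

    alpha = np.zeros((k, n))
    for i in range(n):
        support = rng.choice(k, size=sparsity, replace=False)
        coefs = rng.uniform(1.0, 2.0, size=sparsity) \
            * rng.choice([-1.0, 1.0], size=sparsity)
        alpha[support, i] = coefs
    X = D @ alpha
    if noise_sd > 0:
        X = X + rng.normal(0, noise_sd, size=X.shape)
    return X, SignalGroundTruth(true_dictionary=D, true_coefficients=alpha)
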