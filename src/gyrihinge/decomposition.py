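"""s-core and nodal-strength decompositions with class ratio curves.

The s-core of a weighted graph is the maximal subgraph in which every
surviving node's summed connection weight is at least s.  It is found by
iteratively deleting nodes whose residual strength < s until a fixpoint
is reached — the weighted analogue of the k-core.  The
nodal-strength decomposition is the simpler single-pass filter that drops
nodes whose full-network strength falls below s.

Ratio curves track, as s rises, the fraction of surviving nodes belonging
to each convolution class; in hub-enriched networks the 3-hinge curve
climbs and eventually surpasses the 2-hinge curve.  A label-shuffling
permutation test scores whether that crossing could arise by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import WeightedNetwork
from .parcellation import H2, H3, SULCAL, PatchLabels

__all__ = ["RatioCurve", "s_core", "strength_decompose", "ratio_curves",
           "crossing_permutation_test", "default_s_levels",
           "survivor_sets"]

S_CORE = "S_CORE"
NODAL_STRENGTH = "NODAL_STRENGTH"


@dataclass
class RatioCurve:
    """Class fractions among surviving nodes across s levels.

    Levels with no survivors have NaN ratios and ``preserved_counts`` 0.
    """

    s_levels: np.ndarray
    ratio_h3: np.ndarray
    ratio_h2: np.ndarray
    ratio_sulcal: np.ndarray
    preserved_counts: np.ndarray
    method: str


def s_core(net: WeightedNetwork, s: float,
           edge_prune: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Survivor mask and per-node core membership at level s.

    Returns ``(mask, residual_strength)`` where ``mask[i]`` is True when
    node i is preserved after the s-level pruning and
    ``residual_strength`` is the node's summed weight in the surviving
    subgraph.  The default rule iteratively deletes nodes whose residual
    strength falls below s; with ``edge_prune`` individual edges of
    weight < s are additionally removed first (a strictly harsher
    variant that no longer reduces to the k-core on unit weights).
    """
    if s < 0:
        raise ValueError("s must be nonnegative")
    w = net.weights.copy()
    if edge_prune:
        w[w < s] = 0.0
    alive = np.ones(net.n_nodes, dtype=bool)
    while True:
        strength = (w * np.outer(alive, alive)).sum(axis=1)
        drop = alive & (strength < s)
        if not drop.any():
            break
        alive &= ~drop
    strength = (w * np.outer(alive, alive)).sum(axis=1) * alive
    return alive, strength


def s_core_levels(net: WeightedNetwork,
                  s_levels: np.ndarray) -> np.ndarray:
    """Per-node core level: the largest s at which the node survives."""
    levels = np.full(net.n_nodes, -np.inf)
    for s in s_levels:
        mask, _ = s_core(net, float(s))
        levels[mask] = s
    return levels


def strength_decompose(net: WeightedNetwork, s: float) -> np.ndarray:
    """Single-pass survivor mask: full-network strength >= s."""
    if s < 0:
        raise ValueError("s must be nonnegative")
    return net.weights.sum(axis=1) >= s


def default_s_levels(net: WeightedNetwork, n_levels: int = 50) -> np.ndarray:
    """Linear grid of s levels from 0 to the maximum nodal strength."""
    return np.linspace(0.0, float(net.weights.sum(axis=1).max()), n_levels)


def survivor_sets(net: WeightedNetwork, s_levels: np.ndarray,
                  method: str = S_CORE) -> np.ndarray:
    """(n_levels, n_nodes) boolean survivor masks for each s level."""
    if method == S_CORE:
        return np.stack([s_core(net, float(s))[0] for s in s_levels])
    if method == NODAL_STRENGTH:
        return np.stack([strength_decompose(net, float(s))
                         for s in s_levels])
    raise ValueError(f"unknown method {method!r}")


def _ratios_from_masks(masks: np.ndarray, classes: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                  np.ndarray]:
    fmasks = masks.astype(float)
    counts = fmasks.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r3 = (fmasks @ (classes == H3)) / counts
        r2 = (fmasks @ (classes == H2)) / counts
        rs = (fmasks @ (classes == SULCAL)) / counts
    empty = counts == 0
    for r in (r3, r2, rs):
        r[empty] = np.nan
    return r3, r2, rs, counts.astype(np.int64)


def ratio_curves(net: WeightedNetwork, labels: PatchLabels,
                 s_levels: np.ndarray | None = None,
                 method: str = S_CORE) -> RatioCurve:
    """Per-subject class ratio curves over the decomposition levels.

    At the lowest level (s = 0) the ratios equal the intact class
    fractions of the network.
    """
    if s_levels is None:
        s_levels = default_s_levels(net)
    s_levels = np.asarray(s_levels, dtype=float)
    if np.any(np.diff(s_levels) < 0):
        raise ValueError("s_levels must be ascending")
    masks = survivor_sets(net, s_levels, method)
    r3, r2, rs, counts = _ratios_from_masks(masks, labels.classes)
    return RatioCurve(s_levels=s_levels, ratio_h3=r3, ratio_h2=r2,
                      ratio_sulcal=rs, preserved_counts=counts,
                      method=method)


def curve_crossing_event(r3: np.ndarray, r2: np.ndarray) -> bool:
    """True when the 3-hinge ratio strictly exceeds the 2-hinge ratio at
    any defined level."""
    ok = np.isfinite(r3) & np.isfinite(r2)
    return bool(np.any(r3[ok] > r2[ok]))


def crossing_permutation_test(net: WeightedNetwork, labels: PatchLabels,
                              s_levels: np.ndarray | None = None,
                              method: str = S_CORE, n_perm: int = 1000,
                              seed: int = 0) -> float:
    """Label-shuffling p-value for the 3-hinge-surpasses-2-hinge event.

    The survivor sets depend only on the network, so they are computed
    once; each permutation shuffles the class labels (preserving class
    sizes) and re-evaluates the ratio curves.  The p-value uses the
    add-one correction p = (1 + #events) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    classes = labels.classes
    if (classes == H3).sum() == 0 or (classes == H2).sum() == 0:
        raise ValueError("both H3 and H2 classes must be nonempty")
    if s_levels is None:
        s_levels = default_s_levels(net)
    s_levels = np.asarray(s_levels, dtype=float)
    masks = survivor_sets(net, s_levels, method)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        shuffled = classes[rng.permutation(len(classes))]
        r3, r2, _, _ = _ratios_from_masks(masks, shuffled)
        if curve_crossing_event(r3, r2):
            hits += 1
    return (1 + hits) / (1 + n_perm)
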