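"""s-core / nodal-strength decompositions and ratio curves."""

import numpy as np
import pytest

from gyrihinge import RatioCurve, WeightedNetwork, s_core
from gyrihinge.decomposition import (NODAL_STRENGTH, S_CORE,
                                     crossing_permutation_test,
                                     curve_crossing_event, default_s_levels,
                                     ratio_curves, strength_decompose,
                                     survivor_sets)
from gyrihinge.parcellation import H2, H3, SULCAL, PatchLabels
from helpers import star_network, triangle_network
from oracles import oracle_s_core_survivors


def test_s_core_trivial_and_triangle():
    net = triangle_network(weight=5.0)
    mask0, _ = s_core(net, 0.0)
    assert mask0.all()
    mask11, _ = s_core(net, 11.0)  # each node strength 10
    assert not mask11.any()
    with pytest.raises(ValueError):
        s_core(net, -1.0)


def test_s_core_star_example():
    # star: center strength 4, leaves 1 -> only the center could meet s=2,
    # but alone it has residual strength 0, so the core is empty
    net = star_network(n_leaves=4)
    mask, residual = s_core(net, 2.0)
    assert not mask.any()
    # at s = 1 everything survives with residual strengths intact
    mask1, residual1 = s_core(net, 1.0)
    assert mask1.all()
    assert residual1 == pytest.approx([4.0, 1, 1, 1, 1])


def test_s_core_matches_set_oracle(random_network):
    for s in [0.0, 0.5, 1.5, 3.0]:
        mask, _ = s_core(random_network, s)
        assert set(np.flatnonzero(mask)) == oracle_s_core_survivors(
            random_network.weights, s)


def test_s_core_nestedness(random_network):
    prev = None
    for s in np.linspace(0, 5, 11):
        mask, _ = s_core(random_network, float(s))
        if prev is not None:
            assert (mask <= prev).all()
        prev = mask


def test_edge_prune_mode_is_harsher(random_network):
    for s in [0.3, 0.8]:
        plain, _ = s_core(random_network, s)
        pruned, _ = s_core(random_network, s, edge_prune=True)
        assert (pruned <= plain).all()


def test_strength_decompose_oracle(random_network):
    st = random_network.weights.sum(axis=1)
    for s in [0.0, 1.0, 2.5]:
        assert np.array_equal(strength_decompose(random_network, s),
                              st >= s)


def test_ratio_curves_basic_properties(hub_cohort):
    net, labels, _ = hub_cohort[0]
    levels = default_s_levels(net, 20)
    for method in (S_CORE, NODAL_STRENGTH):
        curve = ratio_curves(net, labels, levels, method)
        assert isinstance(curve, RatioCurve)
        ok = np.isfinite(curve.ratio_h3)
        total = (curve.ratio_h3[ok] + curve.ratio_h2[ok]
                 + curve.ratio_sulcal[ok])
        assert total == pytest.approx(np.ones(ok.sum()))
        assert (np.diff(curve.preserved_counts) <= 0).all()
        # level 0: intact class fractions
        n = labels.n_patches
        assert curve.ratio_h3[0] == pytest.approx(labels.count(H3) / n)
        assert curve.ratio_h2[0] == pytest.approx(labels.count(H2) / n)


def test_ratio_curves_all_h2():
    net = triangle_network()
    labels = PatchLabels(classes=np.array([H2, H2, H2]),
                         sulcal_fraction=np.zeros(3),
                         hinge_count=np.zeros(3, dtype=int))
    curve = ratio_curves(net, labels, np.array([0.0, 1.0]), S_CORE)
    assert curve.ratio_h2 == pytest.approx([1.0, 1.0])
    assert curve.ratio_h3 == pytest.approx([0.0, 0.0])


def test_ratio_curves_reject_descending_levels(hub_cohort):
    net, labels, _ = hub_cohort[0]
    with pytest.raises(ValueError):
        ratio_curves(net, labels, np.array([1.0, 0.5]))


def test_survivor_sets_unknown_method(random_network):
    with pytest.raises(ValueError):
        survivor_sets(random_network, np.array([0.0]), "BOGUS")


def test_curve_crossing_event():
    assert curve_crossing_event(np.array([0.1, 0.6]), np.array([0.5, 0.5]))
    assert not curve_crossing_event(np.array([0.1, np.nan]),
                                    np.array([0.5, np.nan]))


def test_crossing_permutation_boundaries():
    net = triangle_network()
    labels = PatchLabels(classes=np.array([H3, H2, SULCAL]),
                         sulcal_fraction=np.array([0.0, 0.0, 1.0]),
                         hinge_count=np.array([1, 0, 0]))
    # n_perm = 1: p is 1/2 or 1 depending on the single shuffle's event
    p = crossing_permutation_test(net, labels, np.array([0.0]),
                                  n_perm=1, seed=0)
    assert p in (0.5, 1.0)
    with pytest.raises(ValueError):
        crossing_permutation_test(net, labels, n_perm=0)
    bad = PatchLabels(classes=np.array([H2, H2, H2]),
                      sulcal_fraction=np.zeros(3),
                      hinge_count=np.zeros(3, dtype=int))
    with pytest.raises(ValueError):
        crossing_permutation_test(net, bad, n_perm=10)


def test_crossing_permutation_planted_hubs(hub_cohort):
    net, labels, _ = hub_cohort[0]
    p = crossing_permutation_test(net, labels, method=S_CORE,
                                  n_perm=500, seed=1)
    assert p <= 0.05
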