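"""Nodal graph metrics: closed forms, oracles, partitions."""

import numpy as np
import pytest

from gyrihinge import (ModulePartition, WeightedNetwork, betweenness,
                       clustering, compute_all_metrics, degree,
                       local_efficiency, partition_modules, participation,
                       strength)
from helpers import star_network, triangle_network
from oracles import (oracle_betweenness, oracle_clustering,
                     oracle_local_efficiency, oracle_participation)


def test_degree_and_strength():
    w = np.array([[0.0, 2.0, 0.5], [2.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
    net = WeightedNetwork(weights=w)
    assert degree(net).tolist() == [2, 1, 1]
    assert strength(net) == pytest.approx([2.5, 2.0, 0.5])


def test_triangle_closed_forms():
    net = triangle_network()
    assert clustering(net) == pytest.approx([1.0, 1.0, 1.0])
    assert local_efficiency(net) == pytest.approx([1.0, 1.0, 1.0])
    assert betweenness(net) == pytest.approx([0.0, 0.0, 0.0])


def test_path_and_star_betweenness():
    p3 = WeightedNetwork(weights=np.array([[0.0, 1, 0], [1, 0, 1],
                                           [0, 1, 0.0]]))
    assert betweenness(p3) == pytest.approx([0.0, 1.0, 0.0])
    star = star_network(n_leaves=4)
    assert betweenness(star) == pytest.approx([6.0, 0, 0, 0, 0])


def test_betweenness_binarized_ignores_weights():
    rng = np.random.default_rng(3)
    w = np.triu(rng.uniform(0.5, 2.0, (8, 8)) * (rng.random((8, 8)) < 0.6),
                1)
    w = w + w.T
    net = WeightedNetwork(weights=w)
    binary = WeightedNetwork(weights=(w > 0).astype(float))
    assert betweenness(net, binarized=True) == pytest.approx(
        betweenness(binary))


def test_even_split_participation():
    w = np.zeros((5, 5))
    w[0, 1] = w[0, 2] = w[1, 0] = w[2, 0] = 1.0
    w[3, 4] = w[4, 3] = 1.0
    net = WeightedNetwork(weights=w)
    part = ModulePartition(module_id=np.array([0, 0, 1, 1, 1]),
                           gamma=1.0, modularity=0.0, seed=0)
    # node 0 splits its 2 links evenly over 2 modules -> 1 - 2*(1/2)^2
    assert participation(net, part)[0] == pytest.approx(0.5)
    # isolated-in-module node 3 connects only within its module
    assert participation(net, part)[3] == pytest.approx(0.0)


def test_oracle_agreement_small_random_graphs():
    rng = np.random.default_rng(23)
    for _ in range(10):
        n = int(rng.integers(5, 12))
        w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.5), 1)
        w = w + w.T
        if w.max() == 0:
            continue
        net = WeightedNetwork(weights=w)
        assert betweenness(net) == pytest.approx(oracle_betweenness(w),
                                                 abs=1e-9)
        assert local_efficiency(net) == pytest.approx(
            oracle_local_efficiency(w), abs=1e-9)
        assert clustering(net) == pytest.approx(oracle_clustering(w),
                                                abs=1e-9)
        part = partition_modules(net, seed=0)
        assert participation(net, part) == pytest.approx(
            oracle_participation(w, part.module_id), abs=1e-9)


def test_partition_modules_recovers_planted_blocks():
    rng = np.random.default_rng(5)
    n = 30
    module = np.repeat([0, 1, 2], 10)
    prob = np.where(module[:, None] == module[None, :], 0.8, 0.05)
    w = np.triu((rng.random((n, n)) < prob) * rng.uniform(0.5, 1.5, (n, n)),
                1)
    w = w + w.T
    net = WeightedNetwork(weights=w)
    part = partition_modules(net, gamma=1.0, seed=0)
    # partition must be deterministic and match the planted blocks
    again = partition_modules(net, gamma=1.0, seed=0)
    assert np.array_equal(part.module_id, again.module_id)
    assert part.modularity > 0.3
    for m in range(3):
        block = part.module_id[module == m]
        assert len(np.unique(block)) == 1


def test_partition_modules_errors():
    net = triangle_network()
    with pytest.raises(ValueError):
        partition_modules(net, gamma=0.0)
    with pytest.raises(ValueError):
        partition_modules(WeightedNetwork(weights=np.zeros((3, 3))))


def test_degenerate_nodes_are_zero():
    # node 2 is isolated; node 1 has a single neighbour
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    net = WeightedNetwork(weights=w)
    assert clustering(net)[1] == 0.0
    assert local_efficiency(net)[1] == 0.0
    part = ModulePartition(module_id=np.array([0, 0, 1]), gamma=1.0,
                           modularity=0.0, seed=0)
    assert participation(net, part)[2] == 0.0


def test_compute_all_metrics_table(hub_cohort):
    net, labels, _hubs = hub_cohort[0]
    table = compute_all_metrics(net, seed=0, subject_id="s0", labels=labels)
    assert len(table) == net.n_nodes
    assert {"degree", "strength", "betweenness", "efficiency",
            "clustering", "participation", "module_id",
            "class"} <= set(table.columns)
    assert set(table["class"].unique()) <= {"H3", "H2", "SULCAL"}
    assert (table["subject_id"] == "s0").all()
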