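"""Shared fixtures: small meshes, networks and cohorts."""

import numpy as np
import pytest

from gyrihinge import (CohortSpec, WeightedNetwork, equal_area_parcellate,
                       gen_folded_surface, gen_network_cohort)


@pytest.fixture(scope="session")
def single_junction_mesh():
    """A folded sheet with one planted Y-junction."""
    return gen_folded_surface(n_junctions=1, seed=0)


@pytest.fixture(scope="session")
def multi_junction_mesh():
    """A folded sheet with four planted Y-junctions."""
    return gen_folded_surface(n_junctions=4, seed=3)


@pytest.fixture(scope="session")
def small_parcellation(multi_junction_mesh):
    mesh, _ = multi_junction_mesh
    return equal_area_parcellate(mesh, 30, seed=1)


@pytest.fixture(scope="session")
def hub_cohort():
    """Three-subject planted-hub cohort, 120 patches."""
    spec = CohortSpec(n_subjects=3, n_patches=120, n_h3=15, n_h2=60, seed=5)
    return gen_network_cohort(spec)


@pytest.fixture()
def random_network():
    rng = np.random.default_rng(17)
    n = 15
    w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.5), 1)
    w = w + w.T
    return WeightedNetwork(weights=w)
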