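"""Tiny closed-form networks shared across test modules."""

import numpy as np

from gyrihinge import WeightedNetwork


def triangle_network(weight=1.0):
    w = np.full((3, 3), float(weight))
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(weights=w)


def star_network(n_leaves=4, weight=1.0):
    n = n_leaves + 1
    w = np.zeros((n, n))
    w[0, 1:] = weight
    w[1:, 0] = weight
    return WeightedNetwork(weights=w)
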