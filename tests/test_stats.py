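"""Group statistics: z-scoring, t-tests, permutation tests, species."""

import numpy as np
import pandas as pd
import pytest

from gyrihinge import (compare_classes, cross_species_compare,
                       label_permutation_test, ttest_two_sample,
                       zscore_within_subject)
from gyrihinge.stats import comparisons_to_frame


def metric_table(rng, n_subjects=3, n_nodes=40, h3_shift=0.0):
    rows = []
    for s in range(n_subjects):
        classes = np.array(["H3"] * 8 + ["H2"] * 20 + ["SULCAL"] * 12)
        rng.shuffle(classes)
        for i, cls in enumerate(classes):
            base = rng.normal()
            if cls == "H3":
                base += h3_shift
            rows.append({"subject_id": s, "node": i, "class": cls,
                         "degree": base + 5.0, "strength": 2 * base + 1.0})
    return pd.DataFrame(rows)


def test_zscore_within_subject_means_and_sds():
    rng = np.random.default_rng(0)
    table = metric_table(rng)
    z = zscore_within_subject(table, ["degree", "strength"])
    for _, grp in z.groupby("subject_id"):
        for col in ("degree", "strength"):
            assert grp[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp[col].std(ddof=0) == pytest.approx(1.0)


def test_zscore_idempotent():
    rng = np.random.default_rng(1)
    table = metric_table(rng)
    once = zscore_within_subject(table, ["degree"])
    twice = zscore_within_subject(once, ["degree"])
    assert twice["degree"].to_numpy() == pytest.approx(
        once["degree"].to_numpy())


def test_zscore_rejects_zero_variance():
    table = pd.DataFrame({"subject_id": [0, 0], "degree": [1.0, 1.0]})
    with pytest.raises(ValueError):
        zscore_within_subject(table, ["degree"])


def test_ttest_identical_and_separated():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    t, p = ttest_two_sample(x, x.copy())
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    y = x + 100.0 + np.array([0.01, -0.02, 0.005, 0.0])
    _, p2 = ttest_two_sample(x, y)
    assert p2 < 1e-3
    with pytest.raises(ValueError):
        ttest_two_sample(np.array([1.0]), x)


def test_ttest_calibration():
    rng = np.random.default_rng(2)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        _, p = ttest_two_sample(rng.standard_normal(20),
                                rng.standard_normal(20))
        rejections += p <= 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


def test_permutation_extreme_case():
    values = np.concatenate([np.full(10, 5.0), np.zeros(40)])
    is_h3 = np.zeros(50, dtype=bool)
    is_h3[:10] = True
    p = label_permutation_test(values, is_h3, n_perm=200, seed=0)
    assert p == pytest.approx(1 / 201)


def test_permutation_affine_invariance():
    rng = np.random.default_rng(3)
    values = rng.standard_normal(30)
    is_h3 = np.zeros(30, dtype=bool)
    is_h3[:8] = True
    p1 = label_permutation_test(values, is_h3, n_perm=100, seed=5)
    p2 = label_permutation_test(3.0 * values + 7.0, is_h3, n_perm=100,
                                seed=5)
    assert p1 == p2


def test_permutation_errors():
    values = np.arange(10.0)
    with pytest.raises(ValueError):
        label_permutation_test(values, np.ones(10, dtype=bool), n_perm=10)
    with pytest.raises(ValueError):
        label_permutation_test(values, np.zeros(10, dtype=bool), n_perm=0)


def test_compare_classes_detects_planted_shift():
    rng = np.random.default_rng(4)
    table = metric_table(rng, h3_shift=2.0)
    comps = compare_classes(table, n_perm=200, seed=0,
                            metrics=["degree", "strength"])
    frame = comparisons_to_frame(comps)
    assert set(frame["metric"]) == {"degree", "strength"}
    assert (frame["direction"] == "h3>h2").all()
    assert (frame["p_permutation"] < 0.05).all()
    assert (frame["p_ttest"] < 0.05).all()


def test_cross_species_planted_contrast():
    rng = np.random.default_rng(6)
    cohorts = {"human": metric_table(rng, h3_shift=3.0),
               "macaque": metric_table(rng, h3_shift=0.0)}
    out = cross_species_compare(cohorts, metrics=["degree"])
    assert set(out["class"]) == {"H3", "H2"}
    h3_row = out[(out["class"] == "H3")].iloc[0]
    assert h3_row["p"] < 0.01
    with pytest.raises(ValueError):
        cross_species_compare({"human": cohorts["human"]})
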