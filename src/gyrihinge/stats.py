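"""Group statistics comparing 3-hinge and 2-hinge patches.

Metrics are z-scored within each subject (over all of that subject's
patches) so that subjects with different network scales are comparable,
then pooled across subjects into an H3 group and an H2 group.  A Welch
two-sample t-test and a size-preserving label-permutation test assess
whether the two folding patterns differ in mean.  Cross-species contrasts
add a second z-scoring across subjects within each species before pairwise
t-tests per class and metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import METRIC_COLUMNS

__all__ = ["GroupComparison", "zscore_within_subject", "ttest_two_sample",
           "label_permutation_test", "compare_classes",
           "cross_species_compare"]


@dataclass
class GroupComparison:
    """One metric's H3-vs-H2 contrast."""

    metric: str
    mean_h3: float
    sd_h3: float
    mean_h2: float
    sd_h2: float
    t: float
    p_ttest: float
    p_permutation: float | None
    n_perm: int | None

    @property
    def direction(self) -> str:
        return "h3>h2" if self.mean_h3 >= self.mean_h2 else "h2>h3"


def zscore_within_subject(table: pd.DataFrame,
                          columns: list[str] | None = None) -> pd.DataFrame:
    """Z-score each metric within each subject over all its patches."""
    columns = columns or [c for c in METRIC_COLUMNS if c in table.columns]
    out = table.copy()
    out[columns] = out[columns].astype(float)
    for sid, idx in table.groupby("subject_id").groups.items():
        for col in columns:
            vals = table.loc[idx, col].to_numpy(dtype=float)
            if len(vals) < 2:
                raise ValueError("need >= 2 nodes per subject to z-score")
            sd = vals.std(ddof=0)
            if sd == 0:
                raise ValueError(
                    f"zero variance in metric {col!r} for subject {sid!r}")
            out.loc[idx, col] = (vals - vals.mean()) / sd
    return out


def ttest_two_sample(x: np.ndarray, y: np.ndarray,
                     equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def label_permutation_test(values: np.ndarray, is_h3: np.ndarray,
                           n_perm: int = 1000, seed: int = 0,
                           subject_id: np.ndarray | None = None) -> float:
    """Size-preserving label-shuffling test of the directed mean difference.

    The statistic is the directed mean difference mean(larger class) -
    mean(smaller class), i.e. 3-hinge minus 2-hinge when 3-hinges have
    the greater mean and vice versa; the same directed statistic is
    evaluated on every shuffled labelling (otherwise the post-hoc
    direction choice would double the type-I error).  Null labels are
    drawn by shuffling within each subject when ``subject_id`` is given,
    keeping per-subject group sizes intact; the statistic pools over all
    subjects.  p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    is_h3 = np.asarray(is_h3, dtype=bool)
    if is_h3.all() or (~is_h3).all():
        raise ValueError("both classes must be nonempty")

    def stat(mask: np.ndarray) -> float:
        return abs(values[mask].mean() - values[~mask].mean())

    observed = stat(is_h3)
    rng = np.random.default_rng(seed)
    if subject_id is None:
        groups = [np.arange(len(values))]
    else:
        subject_id = np.asarray(subject_id)
        groups = [np.flatnonzero(subject_id == s)
                  for s in np.unique(subject_id)]
    hits = 0
    mask = is_h3.copy()
    for _ in range(n_perm):
        for idx in groups:
            mask[idx] = is_h3[idx][rng.permutation(len(idx))]
        if stat(mask) >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def compare_classes(table: pd.DataFrame, n_perm: int = 1000, seed: int = 0,
                    metrics: list[str] | None = None,
                    zscore: bool = True) -> list[GroupComparison]:
    """Per-metric H3-vs-H2 contrasts on a pooled multi-subject table.

    The table must carry ``subject_id``, ``class`` and metric columns;
    only gyral (H3/H2) rows enter the group comparison, while z-scoring
    runs over all patches of each subject.
    """
    metrics = metrics or [c for c in METRIC_COLUMNS if c in table.columns]
    if zscore:
        table = zscore_within_subject(table, metrics)
    gyral = table[table["class"].isin(["H3", "H2"])]
    is_h3 = (gyral["class"] == "H3").to_numpy()
    subj = gyral["subject_id"].to_numpy()
    out = []
    for m_i, metric in enumerate(metrics):
        vals = gyral[metric].to_numpy(dtype=float)
        x, y = vals[is_h3], vals[~is_h3]
        t, p = ttest_two_sample(x, y)
        p_perm = label_permutation_test(
            vals, is_h3, n_perm=n_perm,
            seed=np.random.SeedSequence([seed, m_i]).generate_state(1)[0]
            % (2 ** 31), subject_id=subj)
        out.append(GroupComparison(
            metric=metric, mean_h3=float(x.mean()), sd_h3=float(x.std()),
            mean_h2=float(y.mean()), sd_h2=float(y.std()), t=t, p_ttest=p,
            p_permutation=p_perm, n_perm=n_perm))
    return out


def comparisons_to_frame(comps: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([{
        "metric": c.metric, "mean_h3": c.mean_h3, "sd_h3": c.sd_h3,
        "mean_h2": c.mean_h2, "sd_h2": c.sd_h2, "t": c.t,
        "p_ttest": c.p_ttest, "p_permutation": c.p_permutation,
        "n_perm": c.n_perm, "direction": c.direction,
    } for c in comps])


def cross_species_compare(cohorts: dict[str, pd.DataFrame],
                          metrics: list[str] | None = None) -> pd.DataFrame:
    """Pairwise cross-species t-tests per class and metric.

    Each cohort table is first z-scored within subject, then a second
    z-scoring is applied across all of the species' patch values per
    metric, so class subsets deviate from zero exactly to the extent the
    class is extreme within its species.  Rows cover every species pair x
    {H3, H2} x metric.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two species")
    metrics = metrics or METRIC_COLUMNS
    normed: dict[str, pd.DataFrame] = {}
    for species, tab in cohorts.items():
        if tab["subject_id"].nunique() < 2:
            raise ValueError(f"species {species!r} needs >= 2 subjects")
        for cls in ("H3", "H2"):
            if not (tab["class"] == cls).any():
                raise ValueError(f"species {species!r} missing class {cls}")
        tab = zscore_within_subject(tab, metrics)
        tab = tab.copy()
        for m in metrics:
            v = tab[m].to_numpy(dtype=float)
            tab[m] = (v - v.mean()) / v.std(ddof=0)
        normed[species] = tab

    rows = []
    for sp_a, sp_b in combinations(sorted(normed), 2):
        for cls in ("H3", "H2"):
            a = normed[sp_a][normed[sp_a]["class"] == cls]
            b = normed[sp_b][normed[sp_b]["class"] == cls]
            for m in metrics:
                t, p = ttest_two_sample(a[m].to_numpy(), b[m].to_numpy())
                rows.append({"species_a": sp_a, "species_b": sp_b,
                             "class": cls, "metric": m,
                             "mean_a": float(a[m].mean()),
                             "mean_b": float(b[m].mean()),
                             "t": t, "p": p})
    return pd.DataFrame(rows)
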