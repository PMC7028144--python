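"""Group-comparison statistics for phenotype contrasts.

Two designs cover the figures this pipeline reproduces: a two-group
comparison (Welch's unequal-variance t-test, two-sided) and a multi-group
design (one-way ANOVA with all pairwise Tukey HSD adjusted p-values from
the studentized-range distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ParameterError

__all__ = ["GroupComparison", "welch_t", "anova_tukey"]


@dataclass
class GroupComparison:
    """Result of one group comparison on one metric."""

    metric: str
    test: str  # "welch_t" or "anova_tukey"
    groups: list[str]
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    statistic: float  # t (Welch) or F (ANOVA)
    df: float | tuple[float, float]
    p_value: float
    pairwise_adjusted_p: dict[tuple[str, str], float] = field(default_factory=dict)


def _group_stats(values: Mapping[str, Sequence[float]]):
    n = {g: len(v) for g, v in values.items()}
    mean = {g: float(np.mean(v)) for g, v in values.items()}
    sd = {g: float(np.std(v, ddof=1)) for g, v in values.items()}
    return n, mean, sd


def welch_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    metric: str = "value",
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Welch's two-sided unequal-variance t-test.

    Zero variance in both groups with equal means yields ``p = 1`` by
    convention (with unequal means, ``p = 0`` and an infinite statistic).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 values per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ParameterError("non-finite values in input")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            t, df, p = 0.0, float(len(a) + len(b) - 2), 1.0
        else:
            t = float("inf") * float(np.sign(a.mean() - b.mean()))
            df, p = float(len(a) + len(b) - 2), 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, df, p = float(res.statistic), float(res.df), float(res.pvalue)
    n, mean, sd = _group_stats({labels[0]: a, labels[1]: b})
    return GroupComparison(
        metric=metric,
        test="welch_t",
        groups=list(labels),
        n=n,
        mean=mean,
        sd=sd,
        statistic=t,
        df=df,
        p_value=p,
    )


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
    metric: str = "value",
) -> GroupComparison:
    """One-way ANOVA with all-pairs Tukey HSD adjusted p-values."""
    if len(groups) < 3:
        raise InsufficientDataError("need >= 3 groups for ANOVA + Tukey HSD")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise InsufficientDataError(f"group {g!r} has < 2 values")
        if not np.isfinite(v).all():
            raise ParameterError(f"non-finite values in group {g!r}")
    labels = list(arrays)
    data = [arrays[g] for g in labels]
    f_res = stats.f_oneway(*data)
    tukey = stats.tukey_hsd(*data)
    pairwise = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairwise[(labels[i], labels[j])] = float(tukey.pvalue[i, j])
    n_total = sum(len(v) for v in data)
    df = (float(len(labels) - 1), float(n_total - len(labels)))
    n, mean, sd = _group_stats(arrays)
    return GroupComparison(
        metric=metric,
        test="anova_tukey",
        groups=labels,
        n=n,
        mean=mean,
        sd=sd,
        statistic=float(f_res.statistic),
        df=df,
        p_value=float(f_res.pvalue),
        pairwise_adjusted_p=pairwise,
    )
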