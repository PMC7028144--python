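"""Ploidy-class quantification from DNA-content flow cytometry.

Nuclei stained for DNA content fall on a geometric intensity ladder:
2C, 4C, 8C, 16C, 32C populations at intensity ratios 1:2:4:8:16
(endoreplication doubles the genome without division).  Instead of manual
instrument gates, classification is deterministic: with a 2C anchor
intensity ``a``, a nucleus of intensity ``I`` belongs to class index
``k = round(log2(I/a))`` clipped to [0, 4].  Every nucleus is classified;
the decision boundaries sit halfway between classes on the log2 axis.

The anchor is either supplied or estimated as the lowest sufficiently
tall mode of a kernel density estimate on log2 intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnchorEstimationError, DomainError, InsufficientDataError
from .synthetic import PLOIDY_CLASSES

__all__ = [
    "PloidyProportions",
    "estimate_anchor",
    "classify_ploidy",
    "ploidy_proportions",
    "compare_ploidy",
]

#: Minimum nuclei for anchor estimation.
MIN_NUCLEI_FOR_ANCHOR = 100
#: A KDE mode must exceed this fraction of the tallest mode to count.
MODE_DENSITY_FRACTION = 0.10


@dataclass
class PloidyProportions:
    """Per-sample ploidy-class counts and proportions."""

    sample_id: str
    genotype: str
    counts: dict[str, int]
    proportions: dict[str, float]
    n_total: int
    anchor_used: float

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_total:
            raise DomainError("class counts must sum to n_total")
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise DomainError("proportions must sum to 1")


def estimate_anchor(intensities) -> float:
    """Estimate the 2C peak intensity from a mixed nuclear population.

    A Gaussian KDE is evaluated on log2 intensity; local maxima whose
    density exceeds 10 % of the global maximum are candidate population
    modes, and the lowest one is taken as the 2C peak.
    """
    intensities = np.asarray(intensities, dtype=float)
    if (intensities <= 0).any():
        raise DomainError("intensities must be > 0")
    if len(intensities) < MIN_NUCLEI_FOR_ANCHOR:
        raise InsufficientDataError(
            f"need >= {MIN_NUCLEI_FOR_ANCHOR} nuclei to estimate the 2C anchor"
        )
    log_i = np.log2(intensities)
    if np.ptp(log_i) == 0.0:
        return float(2.0 ** log_i[0])
    kde = stats.gaussian_kde(log_i)
    grid = np.linspace(log_i.min() - 0.5, log_i.max() + 0.5, 1024)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.nonzero(interior)[0] + 1
    peaks = peaks[dens[peaks] >= MODE_DENSITY_FRACTION * dens.max()]
    if peaks.size == 0:
        raise AnchorEstimationError(
            "no density mode above 10% of the maximum; supply anchor explicitly"
        )
    return float(2.0 ** grid[peaks[0]])


def classify_ploidy(intensities, anchor: float) -> np.ndarray:
    """Assign each nucleus to its ploidy class (array of labels).

    ``k = round(log2(I/anchor))`` clipped to ``[0, 4]``; the class label
    is ``2C·2^k``.  Classification is scale-invariant: rescaling all
    intensities and the anchor together leaves the classes unchanged.
    """
    intensities = np.asarray(intensities, dtype=float)
    if anchor <= 0:
        raise DomainError("anchor must be > 0")
    if (intensities <= 0).any():
        raise DomainError("intensities must be > 0")
    k = np.clip(np.rint(np.log2(intensities / anchor)).astype(int), 0, 4)
    return np.asarray(PLOIDY_CLASSES)[k]


def ploidy_proportions(
    classes,
    sample_id: str = "sample1",
    genotype: str = "wt",
    anchor_used: float = float("nan"),
) -> PloidyProportions:
    """Count nuclei per ploidy class; absent classes get zero."""
    classes = np.asarray(classes)
    if classes.size == 0:
        raise InsufficientDataError("need at least one classified nucleus")
    counts = {c: int((classes == c).sum()) for c in PLOIDY_CLASSES}
    n = int(classes.size)
    if sum(counts.values()) != n:
        raise DomainError(f"unknown class labels present: {set(classes) - set(PLOIDY_CLASSES)}")
    props = {c: counts[c] / n for c in PLOIDY_CLASSES}
    return PloidyProportions(
        sample_id=sample_id,
        genotype=genotype,
        counts=counts,
        proportions=props,
        n_total=n,
        anchor_used=anchor_used,
    )


def _welch_cellwise(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t, Satterthwaite df and p, with the zero-variance convention."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_ploidy(
    group_a: Sequence[PloidyProportions],
    group_b: Sequence[PloidyProportions],
    bh: bool = False,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Per-class Welch t-tests on per-sample class proportions.

    One two-sided test per ploidy class, comparing the per-sample
    proportions between the two groups.  Raw p-values are reported; a
    Benjamini–Hochberg column across the five classes is optional (off
    by default).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InsufficientDataError("need >= 2 samples per group")
    rows = []
    for cls in PLOIDY_CLASSES:
        pa = np.array([s.proportions[cls] for s in group_a], dtype=float)
        pb = np.array([s.proportions[cls] for s in group_b], dtype=float)
        t, df, p = _welch_cellwise(pa, pb)
        rows.append(
            {
                "class": cls,
                f"mean_{label_a}": pa.mean(),
                f"mean_{label_b}": pb.mean(),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if bh:
        table["p_bh"] = stats.false_discovery_control(table["p"], method="bh")
    return table
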