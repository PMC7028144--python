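"""Independent brute-force oracles for the scan rules.

Deliberately naive reimplementations (plain Python loops over 1-based
indices, taken straight from the rule statements) used to cross-check the
vectorised detectors.  They must stay independent of the package code.
"""

from __future__ import annotations


def brute_plateau(positions, values, frac=0.95):
    """First position with value >= frac * mean of the strictly later values.

    Returns None when no index qualifies (the detector's error case).
    """
    n = len(values)
    for j in range(n - 1):
        rest = values[j + 1 :]
        if values[j] >= frac * (sum(rest) / len(rest)):
            return positions[j]
    return None


def brute_elongation_onset(lengths):
    """Smallest 1-based i >= 2 with lengths[i] >= 2*lengths[i-1] and a
    longer successor; None if the rule never fires."""
    n = len(lengths)
    for i in range(2, n):  # 1-based candidate, needs a successor
        if lengths[i - 1] >= 2.0 * lengths[i - 2] and lengths[i] > lengths[i - 1]:
            return i
    return None


def brute_maturation_onset(lengths, onset, tol=0.05, n_mature=5):
    """Smallest 1-based i > onset whose successor is within (1+tol) of it,
    with n_mature cells remaining from i; None if the rule never fires."""
    n = len(lengths)
    for i in range(onset + 1, n - n_mature + 2):
        if lengths[i] <= (1.0 + tol) * lengths[i - 1]:
            return i
    return None
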