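"""Segmentation of ordered cortical cell-length profiles.

A cell file, read from the first cell after the cortex/endodermis initial
outward, is split into three zones by two literal scan rules applied to the
raw lengths (no pre-smoothing by default, mirroring how the measurement is
done by eye at the microscope):

* **rapid-elongation onset** — the first cell at least twice as long as its
  predecessor, whose successor is longer still (the successor condition
  skips recently divided cells);
* **maturation onset** — the first subsequent cell whose successor is at
  most ``(1 + tol)`` times its own length, i.e. elongation has stopped.

Cell indices are 1-based in every user-facing value (cell 1 = first cell
after the initial); 0-based indexing is confined to the array internals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, SegmentationError
from .synthetic import CellLengthProfile

__all__ = [
    "StaticZoneSummary",
    "SeedlingSummary",
    "detect_elongation_onset",
    "detect_maturation_onset",
    "mature_cell_length",
    "segment_profile",
    "summarize_seedling",
]

#: Minimum number of cells for segmentation to be attempted.
MIN_CELLS = 8
#: Number of mature-zone cells averaged for the mature cell length.
N_MATURE_AVG = 5


@dataclass
class StaticZoneSummary:
    """Zone statistics of a single segmented cell file (indices 1-based)."""

    root_id: str
    file_side: str
    elongation_onset_index: int
    maturation_onset_index: int
    meristem_cell_count: int
    meristem_length: float  # µm, includes qc_offset
    mature_cell_length: float  # µm


@dataclass
class SeedlingSummary:
    """Per-seedling average of the left and right cortical files."""

    root_id: str
    elongation_onset_index: float
    maturation_onset_index: float
    meristem_cell_count: float
    meristem_length: float
    mature_cell_length: float
    n_files_used: int
    partial: bool = False


def _median3(lengths: np.ndarray) -> np.ndarray:
    """3-cell running median, ends passed through unchanged."""
    out = lengths.copy()
    if len(lengths) >= 3:
        stacked = np.stack([lengths[:-2], lengths[1:-1], lengths[2:]])
        out[1:-1] = np.median(stacked, axis=0)
    return out


def detect_elongation_onset(
    profile: CellLengthProfile, median_filter: bool = False
) -> int:
    """Return the 1-based index of the first rapid-elongation-zone cell.

    The rule: the smallest ``i >= 2`` with
    ``lengths[i] >= 2·lengths[i-1]`` and ``lengths[i+1] > lengths[i]``.
    The final cell can never qualify (it has no successor).

    Raises
    ------
    SegmentationError
        If no cell satisfies the doubling rule.
    """
    lengths = np.asarray(profile.lengths, dtype=float)
    if len(lengths) < 3:
        raise InsufficientDataError(
            f"{profile.root_id}/{profile.file_side}: need >= 3 cells"
        )
    scan = _median3(lengths) if median_filter else lengths
    doubled = scan[1:-1] >= 2.0 * scan[:-2]
    rising = scan[2:] > scan[1:-1]
    hits = np.nonzero(doubled & rising)[0]
    if hits.size == 0:
        raise SegmentationError(
            f"{profile.root_id}/{profile.file_side}: no cell twice as long as "
            "its predecessor with a longer successor"
        )
    return int(hits[0]) + 2  # 0-based position i corresponds to cell i+2


def detect_maturation_onset(
    profile: CellLengthProfile,
    onset: int,
    tol: float = 0.05,
    median_filter: bool = False,
) -> int:
    """Return the 1-based index of the first mature-zone cell.

    The rule: the smallest ``i > onset`` with
    ``lengths[i+1] <= (1 + tol)·lengths[i]`` and at least
    ``N_MATURE_AVG`` cells available from ``i`` onward.

    Raises
    ------
    SegmentationError
        If no qualifying cell leaves five cells for the mature average.
    """
    lengths = np.asarray(profile.lengths, dtype=float)
    n = len(lengths)
    if onset < 2 or onset > n:
        raise InsufficientDataError(f"invalid elongation onset index {onset}")
    scan = _median3(lengths) if median_filter else lengths
    for i in range(onset + 1, n - N_MATURE_AVG + 2):  # 1-based candidates
        if scan[i] <= (1.0 + tol) * scan[i - 1]:  # successor vs candidate
            return i
    raise SegmentationError(
        f"{profile.root_id}/{profile.file_side}: no cell with a successor "
        f"within {100 * tol:.0f}% of its length and {N_MATURE_AVG} cells remaining"
    )


def mature_cell_length(profile: CellLengthProfile, maturation_onset: int) -> float:
    """Arithmetic mean (µm) of the first five mature-zone cells."""
    lengths = np.asarray(profile.lengths, dtype=float)
    if maturation_onset < 1 or maturation_onset + N_MATURE_AVG - 1 > len(lengths):
        raise InsufficientDataError(
            f"need {N_MATURE_AVG} cells at and after index {maturation_onset}"
        )
    sl = lengths[maturation_onset - 1 : maturation_onset - 1 + N_MATURE_AVG]
    return float(np.mean(sl))


def segment_profile(
    profile: CellLengthProfile,
    tol: float = 0.05,
    median_filter: bool = False,
) -> StaticZoneSummary:
    """Segment one cell file and collect its zone statistics.

    The meristem length is ``qc_offset`` plus the summed lengths of cells
    1..onset−1, so it is measured from the quiescent centre even though the
    file itself starts at the cortex/endodermis initial.
    """
    if len(profile) < MIN_CELLS:
        raise InsufficientDataError(
            f"{profile.root_id}/{profile.file_side}: need >= {MIN_CELLS} cells, "
            f"got {len(profile)}"
        )
    onset = detect_elongation_onset(profile, median_filter=median_filter)
    maturation = detect_maturation_onset(
        profile, onset, tol=tol, median_filter=median_filter
    )
    lengths = np.asarray(profile.lengths, dtype=float)
    return StaticZoneSummary(
        root_id=profile.root_id,
        file_side=profile.file_side,
        elongation_onset_index=onset,
        maturation_onset_index=maturation,
        meristem_cell_count=onset - 1,
        meristem_length=float(profile.qc_offset + lengths[: onset - 1].sum()),
        mature_cell_length=mature_cell_length(profile, maturation),
    )


def summarize_seedling(
    left: StaticZoneSummary | None,
    right: StaticZoneSummary | None,
) -> SeedlingSummary:
    """Average the left and right cortical files of one seedling.

    If one file failed segmentation, the other file's values are used and
    the summary is flagged ``partial``.
    """
    files = [s for s in (left, right) if s is not None]
    if not files:
        raise InsufficientDataError("no successfully segmented file supplied")

    def mean(attr: str) -> float:
        return float(np.mean([getattr(s, attr) for s in files]))

    return SeedlingSummary(
        root_id=files[0].root_id,
        elongation_onset_index=mean("elongation_onset_index"),
        maturation_onset_index=mean("maturation_onset_index"),
        meristem_cell_count=mean("meristem_cell_count"),
        meristem_length=mean("meristem_length"),
        mature_cell_length=mean("mature_cell_length"),
        n_files_used=len(files),
        partial=len(files) < 2,
    )
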