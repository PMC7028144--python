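"""Kinematic analysis of particle displacements from the root growth zone.

The growing root is treated as a one-dimensional continuum.  Raw velocity
points are formed from particle displacements, smoothed into a monotone
velocity profile ``v̂(x)``, and the classical kinematic quantities follow:

* cell flux ``F(x) = v(x)/ℓ(x)`` at discrete positions, with cell lengths
  taken from a paired cortical cell file;
* the meristem boundary ``L̂m`` and growth-zone boundary ``L̂g`` by the
  95 % plateau rule — the first point whose flux (respectively velocity)
  reaches 95 % of the average of the remaining points in the growth zone;
* final velocity ``V̂`` (mean velocity on the plateau), cell production
  ``P̂ = V̂/ℓ̂m``, cell-cycle duration ``T̂c = ln2·N̂/P̂``, the local
  relative elongation-rate profile ``r̂ = dv̂/dx``, and the elongation-zone
  transit time ``t̂e = ∫ dx/v̂``.

The velocity fit is a local quadratic kernel regression (tricube weights)
followed by a pool-adjacent-violators projection onto non-decreasing
profiles.  For sparse per-root data the bandwidth can be widened locally so
every window holds at least ``min_points`` observations (nearest-neighbour
floor); with ``min_points=None`` a window holding fewer than 3 points is an
estimation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .errors import (
    BoundaryNotFoundError,
    DomainError,
    EstimationError,
    InsufficientDataError,
    SegmentationError,
)
from .static_profile import N_MATURE_AVG, segment_profile
from .synthetic import CellLengthProfile, ParticleObservations

__all__ = [
    "VelocityProfile",
    "KinematicSummary",
    "estimate_velocity_profile",
    "compute_flux",
    "plateau_boundary",
    "meristem_boundary",
    "growth_zone_boundary",
    "cell_production_rate",
    "cell_cycle_duration",
    "strain_rate_profile",
    "elongation_transit_time",
    "interpolate_cell_lengths",
    "analyze_root",
    "analyze_cohort",
]


@dataclass
class VelocityProfile:
    """A fitted velocity profile on a uniform position grid.

    ``v`` is non-negative and non-decreasing after monotonization.
    ``raw_midpoints``/``raw_velocities`` keep the particle-level points
    the fit was built from.
    """

    grid: np.ndarray  # µm, uniform, strictly increasing
    v: np.ndarray  # µm h⁻¹
    raw_midpoints: np.ndarray
    raw_velocities: np.ndarray
    bandwidth: float
    monotonized: bool = True
    metadata: dict = field(default_factory=dict)

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def interp(self, x):
        """Linear interpolation of ``v̂`` at positions ``x``."""
        return np.interp(x, self.grid, self.v)


@dataclass
class KinematicSummary:
    """Scalar kinematic outputs for one root (units in field names)."""

    root_id: str
    meristem_length_um: float  # L̂m
    growth_zone_length_um: float  # L̂g
    final_velocity_um_h: float  # V̂
    cell_production_per_h: float  # P̂ = V̂ / ℓ̂m
    meristem_cell_count: float  # N̂
    cell_cycle_duration_h: float  # T̂c = ln2·N̂/P̂
    mature_cell_length_um: float  # ℓ̂m
    transit_time_h: float  # t̂e
    n_source: str  # "static" or "length_fallback"
    profile: VelocityProfile | None = None
    strain_rate: np.ndarray | None = None


def estimate_velocity_profile(
    obs: ParticleObservations,
    bandwidth: float = 50.0,
    grid_step: float = 1.0,
    min_points: int | None = None,
) -> VelocityProfile:
    """Fit a monotone velocity profile from particle displacements.

    Each record contributes one raw point: velocity ``(x_end−x_start)/dt``
    at the displacement midpoint.  A local quadratic regression with
    tricube weights of half-width ``bandwidth`` (µm) is evaluated on a
    uniform grid covering the occupied positions, then projected to the
    nearest non-decreasing sequence and clamped at zero.
    """
    if bandwidth <= 0:
        raise EstimationError("bandwidth must be > 0")
    if grid_step <= 0:
        raise EstimationError("grid_step must be > 0")
    rec = obs.records
    if len(rec) == 0:
        raise InsufficientDataError("no particle records")
    if len(rec) < 10:
        raise InsufficientDataError(
            f"need >= 10 particle records, got {len(rec)}"
        )
    mids = ((rec["x_start_um"] + rec["x_end_um"]) / 2.0).to_numpy(float)
    vels = ((rec["x_end_um"] - rec["x_start_um"]) / rec["dt_h"]).to_numpy(float)
    if np.ptp(mids) == 0.0:
        raise EstimationError("all particle midpoints identical; no profile")

    lo = max(0.0, math.ceil(mids.min() / grid_step) * grid_step)
    hi = math.floor(mids.max() / grid_step) * grid_step
    if hi <= lo:
        raise EstimationError("occupied position range shorter than one grid step")
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)

    # per-grid-point bandwidth, optionally widened to hold min_points
    h = np.full(grid.shape, float(bandwidth))
    dist = np.abs(mids[None, :] - grid[:, None])  # (G, n)
    if min_points is not None:
        k = min(max(int(min_points), 3), len(mids))
        knn = np.partition(dist, k - 1, axis=1)[:, k - 1]
        h = np.maximum(h, knn * (1.0 + 1e-9))
    else:
        counts = (dist <= bandwidth).sum(axis=1)
        if (counts < 3).any():
            x_bad = grid[np.argmax(counts < 3)]
            raise EstimationError(
                f"fewer than 3 particles within ±{bandwidth:g} µm of "
                f"x = {x_bad:g} µm; widen the bandwidth or set min_points"
            )

    u = (mids[None, :] - grid[:, None]) / h[:, None]
    w = np.where(np.abs(u) < 1.0, (1.0 - np.abs(u) ** 3) ** 3, 0.0)
    # weighted quadratic fit in the scaled coordinate u; value = intercept
    s0 = w.sum(axis=1)
    s1 = (w * u).sum(axis=1)
    s2 = (w * u**2).sum(axis=1)
    s3 = (w * u**3).sum(axis=1)
    s4 = (w * u**4).sum(axis=1)
    t0 = (w * vels).sum(axis=1)
    t1 = (w * u * vels).sum(axis=1)
    t2 = (w * u**2 * vels).sum(axis=1)
    A = np.stack(
        [
            np.stack([s0, s1, s2], axis=-1),
            np.stack([s1, s2, s3], axis=-1),
            np.stack([s2, s3, s4], axis=-1),
        ],
        axis=-2,
    )
    A = A + 1e-10 * np.eye(3)  # guard against coincident-point singularity
    b = np.stack([t0, t1, t2], axis=-1)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    v_grid = beta[..., 0]

    v_mono = isotonic_regression(v_grid, increasing=True).x
    v_mono = np.maximum(v_mono, 0.0)
    return VelocityProfile(
        grid=grid,
        v=v_mono,
        raw_midpoints=mids,
        raw_velocities=vels,
        bandwidth=float(bandwidth),
        monotonized=True,
        metadata={
            "kernel": "tricube",
            "degree": 2,
            "grid_step": float(grid_step),
            "min_points": min_points,
        },
    )


def compute_flux(v, cell_length):
    """Cell flux ``F = v/ℓ`` (h⁻¹), elementwise at shared positions."""
    v = np.asarray(v, dtype=float)
    cell_length = np.asarray(cell_length, dtype=float)
    if (cell_length <= 0).any():
        raise DomainError("cell length must be > 0 at every evaluated position")
    out = v / cell_length
    return out if out.ndim else float(out)


def plateau_boundary(
    positions: Sequence[float],
    values: Sequence[float],
    frac: float = 0.95,
    include_candidate: bool = False,
) -> float:
    """First position whose value reaches ``frac`` of the remaining mean.

    Scans ascending positions for the smallest ``j`` with
    ``values[j] >= frac · mean(values[j+1:])`` — the candidate point is
    excluded from the "remaining" mean unless ``include_candidate`` is
    set.  The last point never qualifies (its remaining set is empty).

    Raises
    ------
    BoundaryNotFoundError
        If no point satisfies the rule.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise InsufficientDataError("need at least 3 points for the plateau rule")
    if positions.shape != values.shape:
        raise DomainError("positions and values must have the same length")
    # suffix means: mean of values[j+1:] for j = 0..n-2
    csum = np.cumsum(values[::-1])[::-1]  # csum[j] = sum(values[j:])
    if include_candidate:
        rem_mean = csum[:-1] / np.arange(n, 1, -1)
    else:
        rem_mean = csum[1:] / np.arange(n - 1, 0, -1)
    ok = values[:-1] >= frac * rem_mean
    hits = np.nonzero(ok)[0]
    if hits.size == 0:
        raise BoundaryNotFoundError(
            f"no point reaches {100 * frac:g}% of the remaining mean"
        )
    return float(positions[hits[0]])


def _growth_zone_stop(v: np.ndarray) -> int:
    """Index (inclusive) closing the plateau-rule scan window.

    The "growth zone" for the plateau scans is where the fitted velocity
    is still below 99 % of its maximum, plus one plateau point.
    """
    vmax = v.max()
    reached = np.nonzero(v >= 0.99 * vmax)[0]
    stop = int(reached[0]) if reached.size else len(v) - 1
    return min(max(stop, 2), len(v) - 1)  # keep >= 3 points in the window


def interpolate_cell_lengths(
    grid: np.ndarray, profile: CellLengthProfile
) -> np.ndarray:
    """Cell-length field ℓ(x) on ``grid`` from one cortical file.

    Each length is attached to the proximal boundary of its cell and
    linearly interpolated.  (Attaching at cell midpoints lags the true
    steady-state length field by half a cell — about 15 % where lengths
    grow 35 % per cell — which breaks flux conservation; the proximal
    convention is exact for a noiseless steady-state file.)  Grid
    positions outside the covered range get NaN and are excluded from
    flux-based boundary detection.
    """
    bounds = profile.boundaries()
    lengths = np.asarray(profile.lengths, dtype=float)
    out = np.interp(grid, bounds, lengths, left=np.nan, right=np.nan)
    return out


def meristem_boundary(
    profile: VelocityProfile,
    cell_lengths_at_grid: np.ndarray,
    frac: float = 0.95,
    include_candidate: bool = False,
) -> float:
    """Meristem length ``L̂m``: plateau rule applied to the flux profile."""
    stop = _growth_zone_stop(profile.v)
    sl = slice(0, stop + 1)
    l_grid = np.asarray(cell_lengths_at_grid, dtype=float)[sl]
    valid = np.isfinite(l_grid) & (l_grid > 0)
    if valid.sum() < 3:
        raise InsufficientDataError(
            "cell-length coverage of the growth zone too short for flux"
        )
    flux = compute_flux(profile.v[sl][valid], l_grid[valid])
    return plateau_boundary(
        profile.grid[sl][valid], flux, frac=frac, include_candidate=include_candidate
    )


def growth_zone_boundary(
    profile: VelocityProfile,
    frac: float = 0.95,
    include_candidate: bool = False,
) -> tuple[float, float]:
    """Growth-zone length ``L̂g`` and final velocity ``V̂``.

    ``L̂g`` is the plateau rule applied to the velocity profile; ``V̂`` is
    the mean fitted velocity over all grid points at or beyond ``L̂g``.
    """
    stop = _growth_zone_stop(profile.v)
    sl = slice(0, stop + 1)
    lg = plateau_boundary(
        profile.grid[sl], profile.v[sl], frac=frac,
        include_candidate=include_candidate,
    )
    v_final = float(profile.v[profile.grid >= lg].mean())
    return lg, v_final


def cell_production_rate(final_velocity: float, mature_length: float) -> float:
    """``P̂ = V̂ / ℓ̂m`` (cells h⁻¹): final velocity over mature cell length."""
    if mature_length <= 0:
        raise DomainError("mature cell length must be > 0")
    return final_velocity / mature_length


def cell_cycle_duration(n_meristem: float, production: float) -> float:
    """``T̂c = ln2 · N̂ / P̂`` (h), assuming exponential doubling."""
    if production <= 0:
        raise DomainError("cell production must be > 0")
    if n_meristem < 1:
        raise DomainError("meristem cell count must be >= 1")
    return math.log(2.0) * n_meristem / production


def strain_rate_profile(profile: VelocityProfile) -> np.ndarray:
    """Local relative elongation rate ``r̂ = dv̂/dx`` (h⁻¹) on the grid.

    Central differences in the interior, one-sided at the ends, clamped
    at zero (the monotone profile makes negatives numerical noise only).
    """
    if len(profile.grid) < 3:
        raise InsufficientDataError("grid shorter than 3 points")
    r = np.gradient(profile.v, profile.grid)
    return np.maximum(r, 0.0)


def elongation_transit_time(
    profile: VelocityProfile, lm: float, lg: float
) -> float:
    """Transit time ``t̂e = ∫_{L̂m}^{L̂g} dx / v̂(x)`` (h).

    The fitted profile is piecewise linear between grid points, so each
    segment integrates in closed form (``Δx/v`` where flat, ``ln`` ratio
    where sloped); the sum is exact for the interpolant.
    """
    if not lm < lg:
        raise DomainError("need L̂m < L̂g")
    knots = profile.grid[(profile.grid > lm) & (profile.grid < lg)]
    xs = np.concatenate(([lm], knots, [lg]))
    vs = profile.interp(xs)
    if (vs <= 0).any():
        raise DomainError("velocity must be > 0 on the whole transit interval")
    dx = np.diff(xs)
    v0, v1 = vs[:-1], vs[1:]
    slope = (v1 - v0) / dx
    flat = np.abs(slope) * dx < 1e-12 * np.maximum(v0, v1)
    seg = np.where(flat, dx / np.where(v0 > 0, v0, 1.0),
                   np.log(np.where(v1 > 0, v1, 1.0) / np.where(v0 > 0, v0, 1.0))
                   / np.where(slope != 0.0, slope, 1.0))
    return float(seg.sum())


def _mature_length_from_file(
    cell_profile: CellLengthProfile, lg: float
) -> float:
    """Mean length of the first five cells lying wholly beyond ``L̂g``."""
    bounds = cell_profile.boundaries()
    beyond = np.asarray(cell_profile.lengths)[bounds >= lg]
    if beyond.size == 0:
        raise InsufficientDataError(
            f"{cell_profile.root_id}: no cells wholly beyond L̂g = {lg:.0f} µm"
        )
    return float(beyond[:N_MATURE_AVG].mean())


def _meristem_count_fallback(
    cell_profile: CellLengthProfile, lm: float
) -> float:
    """``N̂ = L̂m / median meristem cell length`` when the doubling rule fails."""
    mids = cell_profile.midpoints()
    in_meristem = np.asarray(cell_profile.lengths)[mids <= lm]
    if in_meristem.size == 0:
        raise InsufficientDataError("no cells with midpoints inside L̂m")
    return lm / float(np.median(in_meristem))


def analyze_root(
    obs: ParticleObservations,
    cell_profile: CellLengthProfile,
    bandwidth: float = 50.0,
    grid_step: float = 1.0,
    min_points: int | None = 16,
    plateau_frac: float = 0.95,
    include_candidate: bool = False,
    static_tol: float = 0.05,
    keep_profile: bool = True,
) -> KinematicSummary:
    """Full kinematic analysis of one root.

    The meristem cell number ``N̂`` comes from the paired static profile
    (doubling-rule segmentation) when that succeeds; otherwise it falls
    back to ``L̂m`` divided by the median meristem cell length.  The
    default ``min_points=16`` keeps per-root fits stable at realistic
    particle counts (~40/root); it is inactive on dense data, where the
    fixed bandwidth already covers more points.
    """
    vp = estimate_velocity_profile(
        obs, bandwidth=bandwidth, grid_step=grid_step, min_points=min_points
    )
    lg, v_final = growth_zone_boundary(
        vp, frac=plateau_frac, include_candidate=include_candidate
    )
    l_grid = interpolate_cell_lengths(vp.grid, cell_profile)
    lm = meristem_boundary(
        vp, l_grid, frac=plateau_frac, include_candidate=include_candidate
    )
    if not lm < lg:
        raise EstimationError(
            f"{cell_profile.root_id}: L̂m ({lm:.0f}) not below L̂g ({lg:.0f})"
        )
    mature_len = _mature_length_from_file(cell_profile, lg)
    production = cell_production_rate(v_final, mature_len)
    try:
        n_meristem = float(segment_profile(cell_profile, tol=static_tol).meristem_cell_count)
        n_source = "static"
    except (SegmentationError, InsufficientDataError):
        n_meristem = _meristem_count_fallback(cell_profile, lm)
        n_source = "length_fallback"
    tc = cell_cycle_duration(n_meristem, production)
    te = elongation_transit_time(vp, lm, lg)
    return KinematicSummary(
        root_id=cell_profile.root_id,
        meristem_length_um=lm,
        growth_zone_length_um=lg,
        final_velocity_um_h=v_final,
        cell_production_per_h=production,
        meristem_cell_count=n_meristem,
        cell_cycle_duration_h=tc,
        mature_cell_length_um=mature_len,
        transit_time_h=te,
        n_source=n_source,
        profile=vp if keep_profile else None,
        strain_rate=strain_rate_profile(vp) if keep_profile else None,
    )


_SUMMARY_COLUMNS = [
    "root_id",
    "Lm_um",
    "Lg_um",
    "V_um_per_h",
    "P_cells_per_h",
    "N_meristem",
    "Tc_h",
    "mature_len_um",
    "transit_h",
    "n_source",
]


def analyze_cohort(
    roots: Sequence[tuple[ParticleObservations, CellLengthProfile]],
    **kwargs,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Analyze a cohort of roots, collecting per-root failures.

    Returns a summary table (one row per successfully analyzed root, in
    the ``kinematics_summary.csv`` schema) and a ``root_id -> message``
    map of the roots whose analysis raised a package error.
    """
    rows = []
    failures: dict[str, str] = {}
    for obs, prof in roots:
        try:
            s = analyze_root(obs, prof, keep_profile=False, **kwargs)
        except (
            EstimationError,
            BoundaryNotFoundError,
            InsufficientDataError,
            DomainError,
            SegmentationError,
        ) as exc:
            failures[prof.root_id] = f"{type(exc).__name__}: {exc}"
            continue
        rows.append(
            {
                "root_id": s.root_id,
                "Lm_um": s.meristem_length_um,
                "Lg_um": s.growth_zone_length_um,
                "V_um_per_h": s.final_velocity_um_h,
                "P_cells_per_h": s.cell_production_per_h,
                "N_meristem": s.meristem_cell_count,
                "Tc_h": s.cell_cycle_duration_h,
                "mature_len_um": s.mature_cell_length_um,
                "transit_h": s.transit_time_h,
                "n_source": s.n_source,
            }
        )
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS), failures
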