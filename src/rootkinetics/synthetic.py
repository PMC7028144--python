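"""Synthetic observations from a known steady-state growth zone.

Three kinds of raw data are emulated, mirroring how the corresponding real
measurements are taken:

* toner-particle displacements over a fixed interval (velocity raw data),
  with additive Gaussian error on both recorded positions;
* ordered cortical cell-length files, with multiplicative lognormal
  length variation (biological variation scales with cell size);
* per-nucleus DNA-content fluorescence intensities on the geometric
  2C–32C ladder, with multiplicative lognormal stain/instrument spread.

Every simulator takes a single integer ``seed``; identical seeds reproduce
byte-identical observation tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError
from .growthzone import GrowthZoneSpec

__all__ = [
    "PLOIDY_CLASSES",
    "ParticleObservations",
    "CellLengthProfile",
    "PloidySample",
    "simulate_particles",
    "simulate_cell_file",
    "simulate_ploidy",
    "simulate_cohort",
]

#: DNA-content classes on the geometric ladder (2C = unreplicated diploid).
PLOIDY_CLASSES: tuple[str, ...] = ("2C", "4C", "8C", "16C", "32C")


@dataclass
class ParticleObservations:
    """Per-root particle-displacement records.

    ``records`` has columns ``root_id, x_start_um, x_end_um, dt_h``;
    positions are µm from the quiescent centre, increasing shootward.
    """

    records: pd.DataFrame
    position_noise_sd: float = 0.0
    n_discarded: int = 0

    def __post_init__(self) -> None:
        required = {"root_id", "x_start_um", "x_end_um", "dt_h"}
        missing = required - set(self.records.columns)
        if missing:
            raise ParameterError(f"particle records missing columns {sorted(missing)}")
        if not (self.records["dt_h"] > 0).all():
            raise ParameterError("all dt_h must be > 0")
        # Displacement must be non-negative up to noise.  Both recorded
        # positions carry independent error, so the displacement noise sd
        # is sqrt(2)·position_noise_sd; records beyond 3 sd negative are
        # physically impossible and dropped as gross outliers.
        slack = 3.0 * math.sqrt(2.0) * self.position_noise_sd
        disp = self.records["x_end_um"] - self.records["x_start_um"]
        bad = disp < -slack
        if bad.any():
            self.n_discarded = int(bad.sum())
            self.records = self.records.loc[~bad].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CellLengthProfile:
    """Ordered cortical cell lengths for one file of one root.

    ``lengths[0]`` is cell 1, the first cell after the cortex/endodermis
    initial; ``qc_offset`` is the distance (µm) from the QC to the proximal
    end of cell 1 (default 0).
    """

    root_id: str
    lengths: np.ndarray
    file_side: str = "single"
    qc_offset: float = 0.0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.ndim != 1:
            raise ParameterError("lengths must be a 1-d sequence")
        if not (self.lengths > 0).all():
            raise ParameterError("all cell lengths must be > 0")
        if self.file_side not in ("left", "right", "single"):
            raise ParameterError(f"unknown file_side {self.file_side!r}")

    def __len__(self) -> int:
        return len(self.lengths)

    def boundaries(self) -> np.ndarray:
        """Proximal boundary positions (µm from QC) of each cell."""
        return self.qc_offset + np.concatenate(([0.0], np.cumsum(self.lengths[:-1])))

    def midpoints(self) -> np.ndarray:
        """Midpoint positions (µm from QC) of each cell."""
        return self.boundaries() + 0.5 * self.lengths


@dataclass
class PloidySample:
    """Per-nucleus DNA-content intensities for one flow-cytometry sample."""

    sample_id: str
    genotype: str
    intensities: np.ndarray
    true_proportions: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not (self.intensities > 0).all():
            raise ParameterError("all intensities must be > 0")
        if self.true_proportions is not None:
            total = sum(self.true_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ParameterError("true_proportions must sum to 1")

    def __len__(self) -> int:
        return len(self.intensities)


def _rk4_advance(spec: GrowthZoneSpec, x0: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    """Integrate dx/dt = v(x) with classical RK4, vectorised over particles."""
    h = dt / n_steps
    x = np.array(x0, dtype=float)
    v = spec.velocity
    for _ in range(n_steps):
        k1 = v(x)
        k2 = v(x + 0.5 * h * k1)
        k3 = v(x + 0.5 * h * k2)
        k4 = v(x + h * k3)
        x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return x


def simulate_particles(
    spec: GrowthZoneSpec,
    n_particles: int,
    dt: float = 1.0,
    position_noise_sd: float = 0.0,
    seed: int | None = None,
    root_id: str = "root1",
    rng: np.random.Generator | None = None,
) -> ParticleObservations:
    """Simulate toner-particle displacements over an interval ``dt`` (h).

    Start positions are uniform on ``[0, X_max − V·dt]`` so that no
    trajectory leaves the domain; end positions come from RK4 integration
    of ``dx/dt = v(x)`` with step ``dt/100``.  Independent Gaussian noise
    of sd ``position_noise_sd`` is added to both recorded positions.
    """
    if n_particles < 1:
        raise ParameterError("n_particles must be >= 1")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    upper = spec.domain_extent - spec.final_velocity * dt
    if upper <= 0:
        raise DomainError(
            "dt too large: trajectories would exit the domain "
            f"(X_max = {spec.domain_extent:.0f} µm, V·dt = "
            f"{spec.final_velocity * dt:.0f} µm)"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    x_start = rng.uniform(0.0, upper, size=n_particles)
    x_end = _rk4_advance(spec, x_start, dt, n_steps=100)
    if position_noise_sd > 0:
        x_start = x_start + rng.normal(0.0, position_noise_sd, size=n_particles)
        x_end = x_end + rng.normal(0.0, position_noise_sd, size=n_particles)
    records = pd.DataFrame(
        {
            "root_id": root_id,
            "x_start_um": x_start,
            "x_end_um": x_end,
            "dt_h": dt,
        }
    )
    return ParticleObservations(records, position_noise_sd=position_noise_sd)


def simulate_cell_file(
    spec: GrowthZoneSpec,
    length_cv: float = 0.0,
    seed: int | None = None,
    root_id: str = "root1",
    file_side: str = "single",
    qc_offset: float = 0.0,
    n_mature: int = 6,
    rng: np.random.Generator | None = None,
) -> CellLengthProfile:
    """Lay cells end-to-end from the QC following the steady-state length field.

    Cell ``k`` with proximal boundary ``x_k`` gets length
    ``l(x_k)·exp(ε_k)`` with ``ε_k ~ N(0, σ²)``, ``σ² = ln(1+cv²)``
    (the lognormal whose coefficient of variation is ``length_cv``),
    truncated to ±3σ.  Generation continues until at least ``n_mature``
    cells lie wholly beyond the growth zone.
    """
    if not 0.0 <= length_cv < 0.5:
        raise ParameterError("length_cv must be in [0, 0.5)")
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(length_cv**2))
    lg = spec.growth_zone_length
    lengths: list[float] = []
    x = 0.0
    beyond = 0
    while beyond < n_mature:
        base = spec.cell_length(x)
        if sigma > 0.0:
            eps = rng.normal(0.0, sigma)
            while abs(eps) > 3.0 * sigma:  # truncate by resampling
                eps = rng.normal(0.0, sigma)
            length = base * math.exp(eps)
        else:
            length = base
        if x >= lg:
            beyond += 1
        lengths.append(length)
        x += length
    return CellLengthProfile(
        root_id=root_id,
        lengths=np.array(lengths),
        file_side=file_side,
        qc_offset=qc_offset,
    )


def simulate_ploidy(
    proportions: dict[str, float],
    n: int = 10_000,
    anchor: float = 100.0,
    cv: float = 0.05,
    seed: int | None = None,
    sample_id: str = "sample1",
    genotype: str = "wt",
    rng: np.random.Generator | None = None,
) -> PloidySample:
    """Simulate per-nucleus DNA-content fluorescence intensities.

    Each nucleus is assigned class ``c`` from ``proportions``; its
    intensity is ``anchor·(c/2)·exp(η)`` with ``η ~ N(0, ln(1+cv²))``,
    so the 2C population centres on ``anchor`` and classes sit on the
    geometric 1:2:4:8:16 ladder.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if anchor <= 0:
        raise ParameterError("anchor must be > 0")
    if not 0.0 <= cv < 0.25:
        raise ParameterError("cv must be in [0, 0.25)")
    unknown = set(proportions) - set(PLOIDY_CLASSES)
    if unknown:
        raise ParameterError(f"unknown ploidy classes {sorted(unknown)}")
    probs = np.array([proportions.get(c, 0.0) for c in PLOIDY_CLASSES], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ParameterError("proportions must be non-negative and sum to 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    k = rng.choice(len(PLOIDY_CLASSES), size=n, p=probs / probs.sum())
    intensities = anchor * np.exp2(k).astype(float)
    if cv > 0.0:
        sigma = math.sqrt(math.log1p(cv**2))
        intensities = intensities * np.exp(rng.normal(0.0, sigma, size=n))
    return PloidySample(
        sample_id=sample_id,
        genotype=genotype,
        intensities=intensities,
        true_proportions={c: float(p) for c, p in zip(PLOIDY_CLASSES, probs)},
    )


def simulate_cohort(
    spec: GrowthZoneSpec,
    n_roots: int,
    particles_per_root: int = 40,
    dt: float = 1.0,
    position_noise_sd: float = 5.0,
    length_cv: float = 0.05,
    seed: int | None = None,
    root_prefix: str = "root",
) -> list[tuple[ParticleObservations, CellLengthProfile]]:
    """Simulate ``n_roots`` roots sharing one growth zone.

    Per-root sub-streams are spawned deterministically from the single
    seed, so the whole cohort is reproducible from one integer.
    """
    if n_roots < 1:
        raise ParameterError("n_roots must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    root_seeds = ss.spawn(n_roots)
    out = []
    for i, ss in enumerate(root_seeds, start=1):
        rng = np.random.default_rng(ss)
        rid = f"{root_prefix}{i}"
        obs = simulate_particles(
            spec, particles_per_root, dt=dt,
            position_noise_sd=position_noise_sd, root_id=rid, rng=rng,
        )
        prof = simulate_cell_file(
            spec, length_cv=length_cv, root_id=rid, rng=rng,
        )
        out.append((obs, prof))
    return out
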