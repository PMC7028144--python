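"""Steady-state model of the root growth zone.

The growing root apex is treated as a one-dimensional continuum.  Position
``x`` (µm) is measured from the quiescent centre (QC), increasing shootward.
Material at position ``x`` moves away from the tip with velocity ``v(x)``
(µm h⁻¹); the local relative elemental growth rate (strain rate) is
``r(x) = dv/dx`` (h⁻¹).  The model is piecewise:

* meristem ``[0, Lm]`` — constant strain rate ``r_m``, constant cell
  length ``l0`` (divisions keep cell length constant while flux rises);
* elongation zone ``[Lm, Lg]`` (``Lg = Lm + Le``) — a strain-rate "bump"
  whose integral ``A_e`` (µm h⁻¹) sets the extra velocity gained there;
* mature zone ``x > Lg`` — no growth, ``v = V`` constant.

Derived steady-state quantities:

* final velocity ``V = r_m·Lm + A_e`` (the root elongation rate),
* cell production ``P = r_m·Lm / l0`` (cells per file per hour),
* mature cell length ``l_mature = V / P`` (flux conservation ``F = v/l = P``
  for every ``x ≥ Lm``),
* meristem cell number ``N = Lm / l0`` and cell-cycle duration
  ``Tc = ln 2 · N / P`` (exponential doubling of the proliferating
  population).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import integrate

from .errors import ParameterError

__all__ = [
    "GrowthZoneSpec",
    "build_velocity_field",
    "derive_length_and_flux",
    "transit_time_true",
]

BumpShape = Literal["raised_cosine", "rectangular"]


@dataclass(frozen=True)
class GrowthZoneSpec:
    """Ground-truth parameters of a steady-state growth zone.

    Parameters
    ----------
    meristem_length
        ``Lm`` (µm), QC to the end of the division zone.
    initial_cell_length
        ``l0`` (µm), cortical cell length inside the meristem.
    meristem_strain_rate
        ``r_m`` (h⁻¹), constant relative expansion rate in the meristem.
    elongation_zone_length
        ``Le`` (µm); the growth zone ends at ``Lg = Lm + Le``.
    elongation_strain_integral
        ``A_e`` (µm h⁻¹), integral of the elongation-zone strain-rate bump;
        equals the velocity gained across the elongation zone.
    bump_shape
        ``raised_cosine`` (default; smooth, unimodal, matches published
        REGR profiles) or ``rectangular`` (kept for closed-form tests).
    domain_extent
        ``X_max`` (µm); defaults to ``Lg + 6·l_mature`` and must leave at
        least five mature cell lengths beyond the growth zone.
    """

    meristem_length: float
    initial_cell_length: float
    meristem_strain_rate: float
    elongation_zone_length: float
    elongation_strain_integral: float
    bump_shape: BumpShape = "raised_cosine"
    domain_extent: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.meristem_length > 0:
            raise ParameterError("meristem_length (Lm) must be > 0")
        if not self.initial_cell_length > 0:
            raise ParameterError("initial_cell_length (l0) must be > 0")
        if not self.meristem_strain_rate > 0:
            raise ParameterError("meristem_strain_rate (r_m) must be > 0")
        if not self.elongation_zone_length > 0:
            raise ParameterError("elongation_zone_length (Le) must be > 0")
        if self.elongation_strain_integral < 0:
            raise ParameterError("elongation_strain_integral (A_e) must be >= 0")
        if self.bump_shape not in ("raised_cosine", "rectangular"):
            raise ParameterError(f"unknown bump_shape {self.bump_shape!r}")
        if self.domain_extent is None:
            object.__setattr__(
                self,
                "domain_extent",
                self.growth_zone_length + 6.0 * self.mature_cell_length,
            )
        min_extent = self.growth_zone_length + 5.0 * self.mature_cell_length
        if self.domain_extent < min_extent:
            raise ParameterError(
                "domain_extent (X_max) must be >= Lg + 5 mature cell lengths "
                f"({min_extent:.1f} µm)"
            )

    # -- derived steady-state quantities -------------------------------
    @property
    def growth_zone_length(self) -> float:
        """``Lg = Lm + Le`` (µm)."""
        return self.meristem_length + self.elongation_zone_length

    @property
    def final_velocity(self) -> float:
        """``V = r_m·Lm + A_e`` (µm h⁻¹), the root elongation rate."""
        return (
            self.meristem_strain_rate * self.meristem_length
            + self.elongation_strain_integral
        )

    @property
    def cell_production(self) -> float:
        """``P = r_m·Lm/l0`` (cells h⁻¹ per file)."""
        return (
            self.meristem_strain_rate
            * self.meristem_length
            / self.initial_cell_length
        )

    @property
    def mature_cell_length(self) -> float:
        """``l_mature = V/P`` (µm), by flux conservation."""
        return self.final_velocity / self.cell_production

    @property
    def meristem_cell_count(self) -> float:
        """``N = Lm/l0`` (cells per file in the meristem)."""
        return self.meristem_length / self.initial_cell_length

    @property
    def cell_cycle_duration(self) -> float:
        """``Tc = ln2·N/P`` (h), assuming exponential doubling."""
        return math.log(2.0) * self.meristem_cell_count / self.cell_production

    # -- continuous fields ---------------------------------------------
    def strain_rate(self, x):
        """``r(x)`` (h⁻¹), vectorised over ``x``."""
        x = np.asarray(x, dtype=float)
        lm, le = self.meristem_length, self.elongation_zone_length
        out = np.where(x <= lm, self.meristem_strain_rate, 0.0)
        in_bump = (x > lm) & (x < lm + le)
        u = np.clip(x - lm, 0.0, le)
        if self.bump_shape == "rectangular":
            bump = np.full_like(u, self.elongation_strain_integral / le)
        else:  # raised cosine: (A_e/Le)(1 - cos(2πu/Le)), integral A_e
            bump = (self.elongation_strain_integral / le) * (
                1.0 - np.cos(2.0 * np.pi * u / le)
            )
        out = np.where(in_bump, bump, out)
        return out if out.ndim else float(out)

    def velocity(self, x):
        """``v(x) = ∫₀ˣ r(u) du`` (µm h⁻¹), in closed form."""
        x = np.asarray(x, dtype=float)
        lm, le = self.meristem_length, self.elongation_zone_length
        ae = self.elongation_strain_integral
        v_m = self.meristem_strain_rate * np.minimum(x, lm)
        u = np.clip(x - lm, 0.0, le)
        if self.bump_shape == "rectangular":
            v_e = (ae / le) * u
        else:
            v_e = (ae / le) * (u - (le / (2.0 * np.pi)) * np.sin(2.0 * np.pi * u / le))
        out = v_m + v_e
        return out if out.ndim else float(out)

    def cell_length(self, x):
        """Steady-state cell length ``l(x)`` (µm): ``l0`` in the meristem,
        ``v(x)/P`` in the elongation zone, ``l_mature`` beyond ``Lg``."""
        x = np.asarray(x, dtype=float)
        out = np.where(
            x <= self.meristem_length,
            self.initial_cell_length,
            np.minimum(
                np.asarray(self.velocity(x)) / self.cell_production,
                self.mature_cell_length,
            ),
        )
        return out if out.ndim else float(out)

    def flux(self, x):
        """Cell flux ``F(x) = v(x)/l(x)`` (h⁻¹)."""
        x = np.asarray(x, dtype=float)
        out = np.asarray(self.velocity(x)) / np.asarray(self.cell_length(x))
        return out if out.ndim else float(out)


def build_velocity_field(
    spec: GrowthZoneSpec,
) -> tuple[Callable, Callable]:
    """Return the pair of callables ``(v, r)`` on ``[0, X_max]``.

    ``v`` is the closed-form integral of the piecewise strain rate ``r``;
    ``v(0) = 0``, ``v`` is non-decreasing and equals ``V`` for ``x >= Lg``.
    """
    return spec.velocity, spec.strain_rate


def derive_length_and_flux(spec: GrowthZoneSpec) -> tuple[Callable, Callable]:
    """Return the pair of callables ``(l, F)`` on ``[0, X_max]``.

    ``F = v/l`` is continuous at ``Lm`` and equal to the cell production
    ``P`` for every ``x >= Lm`` (flux conservation).
    """
    return spec.cell_length, spec.flux


def transit_time_true(
    spec: GrowthZoneSpec,
    lower: float | None = None,
    upper: float | None = None,
) -> float:
    """Elongation-zone transit time ``∫ dx / v(x)`` (h) of the true field.

    Defaults to the interval ``[Lm, Lg]``.  Serves as the analytic oracle
    for the kinematic transit-time estimator.
    """
    a = spec.meristem_length if lower is None else lower
    b = spec.growth_zone_length if upper is None else upper
    val, _ = integrate.quad(
        lambda x: 1.0 / spec.velocity(x), a, b, epsrel=1e-10, limit=200
    )
    return val
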