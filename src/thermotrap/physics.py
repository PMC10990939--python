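"""Analytic backbone of thermogravitational accumulation.

A thin vertical water-filled gap (thickness ``alpha``, height ``h``) held
between a hot and a cold wall develops a laminar convection roll.  A solute
with Soret coefficient ``S_T`` drifts across the gap toward the cold wall
(for ``S_T > 0``) while the roll carries the cold-side fluid downward; the
interplay yields an exponential vertical concentration profile.  The
strength of the effect is governed by the dimensionless group

    q = dT * beta * g * rho * alpha^3 / (6 * eta * D)

and the steady-state profile (classical thermogravitational-column series
solution, truncated as printed) is

    c(y) = exp( -(q/120) / (1 + q^2/10080) * S_T * dT * y / alpha )

with ``y`` measured upward from the chamber bottom.  The exponent magnitude
at fixed ``S_T * dT * h / alpha`` is maximal at ``q = sqrt(10080) ~ 100.4``.

This module holds the domain types shared by the whole package and the
closed-form profile that the numerical chamber solver is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .water import WaterProperties, water_properties

__all__ = [
    "Solute",
    "ChamberGeometry",
    "ThermalConditions",
    "soret_exponent_q",
    "steady_profile",
    "steady_log_slope",
    "SINGLE_CHAMBER",
    "NETWORK_CHAMBER",
]

#: q at which the steady-state exponent is maximal
Q_OPTIMAL = float(np.sqrt(10080.0))


@dataclass(frozen=True)
class Solute:
    """A dissolved species with its transport coefficients.

    Parameters
    ----------
    name : str
    D : float
        Diffusion coefficient, m^2 s^-1.
    S_T : float
        Soret coefficient D_T / D, K^-1.  Positive values drift toward cold.
    sigma_random : float
        Random (replicate-to-replicate) error of ``S_T``, K^-1.
    sigma_systematic : float
        Systematic error as a fraction of ``S_T``.
    """

    name: str
    D: float
    S_T: float
    sigma_random: float = 0.0
    sigma_systematic: float = 0.0

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError(f"{self.name}: diffusion coefficient must be > 0")
        if not np.isfinite(self.S_T):
            raise ValueError(f"{self.name}: Soret coefficient must be finite")
        if self.sigma_random < 0 or self.sigma_systematic < 0:
            raise ValueError(f"{self.name}: error fields must be >= 0")

    @property
    def D_T(self) -> float:
        """Thermophoretic mobility D_T = S_T * D, m^2 s^-1 K^-1."""
        return self.S_T * self.D


@dataclass(frozen=True)
class ChamberGeometry:
    """Geometry of one heat-flow chamber (thin differentially heated gap)."""

    height: float = 0.05  # m
    width: float = 0.06  # m, enters only via volumetric-flow conversion
    thickness: float = 1.7e-4  # m, gap between hot and cold wall
    n_fractions: int = 4
    bottom_probe_height: float = 1.5e-3  # m, depth of the "bottom" average

    def __post_init__(self):
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if not (0 < self.bottom_probe_height < self.height):
            raise ValueError("bottom_probe_height must lie inside the chamber")
        if self.aspect_ratio <= 1:
            raise ValueError("thickness must be much smaller than height")

    @property
    def aspect_ratio(self) -> float:
        return self.height / self.thickness


@dataclass(frozen=True)
class ThermalConditions:
    """Wall temperatures of a chamber; properties are taken at the film mean."""

    T_cold: float
    T_hot: float

    def __post_init__(self):
        if self.T_hot < self.T_cold:
            raise ValueError("T_hot must be >= T_cold")

    @property
    def delta_T(self) -> float:
        return self.T_hot - self.T_cold

    @property
    def T_film(self) -> float:
        return 0.5 * (self.T_hot + self.T_cold)

    @property
    def water(self) -> WaterProperties:
        return water_properties(self.T_film)

    @classmethod
    def from_delta(cls, delta_T: float, T_mean: float = 32.5) -> "ThermalConditions":
        """Build from a temperature difference around a mean temperature."""
        return cls(T_cold=T_mean - delta_T / 2.0, T_hot=T_mean + delta_T / 2.0)


#: geometry of the 50 mm single measurement chamber
SINGLE_CHAMBER = ChamberGeometry(height=0.05)
#: geometry of one network chamber (200 mm tall, 60 mm wide)
NETWORK_CHAMBER = ChamberGeometry(height=0.2, width=0.06)


def soret_exponent_q(
    geometry: ChamberGeometry, thermal: ThermalConditions, D: float
) -> float:
    """Dimensionless thermogravitational group q = dT beta g rho alpha^3 / (6 eta D)."""
    if D <= 0:
        raise ValueError("diffusion coefficient must be > 0")
    w = thermal.water
    a = geometry.thickness
    return (
        thermal.delta_T
        * w.volume_expansion
        * w.gravitational_acceleration
        * w.density
        * a**3
        / (6.0 * w.dynamic_viscosity * D)
    )


def steady_log_slope(
    solute: Solute, geometry: ChamberGeometry, thermal: ThermalConditions
) -> float:
    """Vertical slope of ln c(y) in the closed-chamber steady state, m^-1.

    Negative for ``S_T > 0`` (bottom-enriched).
    """
    q = soret_exponent_q(geometry, thermal, solute.D)
    return (
        -(q / 120.0)
        / (1.0 + q**2 / 10080.0)
        * solute.S_T
        * thermal.delta_T
        / geometry.thickness
    )


def steady_profile(
    solute: Solute,
    geometry: ChamberGeometry,
    thermal: ThermalConditions,
    y_grid: np.ndarray,
) -> np.ndarray:
    """Closed-form steady concentration profile of a closed chamber.

    Parameters
    ----------
    y_grid : array
        Positions in m, measured upward from the chamber bottom.

    Returns
    -------
    array
        Concentrations normalized such that the chamber-height mean
        (continuous average over ``[0, height]``) equals 1.
    """
    y = np.asarray(y_grid, dtype=float)
    lam = steady_log_slope(solute, geometry, thermal)
    h = geometry.height
    if lam == 0.0:
        return np.ones_like(y)
    # mean of exp(lam*y) over [0, h]
    mean = (np.exp(lam * h) - 1.0) / (lam * h)
    return np.exp(lam * y) / mean
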