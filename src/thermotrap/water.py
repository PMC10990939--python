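"""Liquid-water property correlations.

Density follows the Kell (1975) atmospheric-pressure polynomial fit
(J. Chem. Eng. Data 20, 97-105; stated accuracy a few ppm over 0-150 °C).
The thermal volume-expansion coefficient ``beta = -(1/rho) d(rho)/dT`` is the
analytic derivative of the same polynomial, so the density maximum near
3.98 °C (beta = 0) is reproduced exactly.  Dynamic viscosity uses the
Vogel-type correlation ``eta = 2.414e-5 * 10**(247.8 / (T_K - 140))`` Pa s
(accurate to ~2.5 % between 0 and 100 °C).

All routines take the temperature in degrees Celsius and are vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: standard gravitational acceleration, m s^-2
G_STANDARD = 9.81

#: validity range of the correlations used here, °C
T_VALID_MIN = 5.0
T_VALID_MAX = 95.0

# Kell (1975) density polynomial coefficients, rho in kg m^-3, t in °C:
# rho(t) = (a0 + a1 t + ... + a5 t^5) / (1 + b t)
_KELL_NUM = np.array(
    [999.83952, 16.945176, -7.9870401e-3, -46.170461e-6, 105.56302e-9, -280.54253e-12]
)
_KELL_DEN = 16.879850e-3


@dataclass(frozen=True)
class WaterProperties:
    """Bulk properties of liquid water at one temperature.

    Attributes
    ----------
    temperature : float
        Temperature in °C.
    density : float
        ``rho`` in kg m^-3.
    dynamic_viscosity : float
        ``eta`` in Pa s.
    volume_expansion : float
        ``beta`` in K^-1 (positive above ~4 °C).
    gravitational_acceleration : float
        ``g`` in m s^-2 (constant).
    """

    temperature: float
    density: float
    dynamic_viscosity: float
    volume_expansion: float
    gravitational_acceleration: float = G_STANDARD


def _kell_density(t):
    powers = np.power.outer(np.asarray(t, dtype=float), np.arange(6))
    return powers @ _KELL_NUM / (1.0 + _KELL_DEN * np.asarray(t, dtype=float))


def _kell_density_derivative(t):
    t = np.asarray(t, dtype=float)
    num = np.power.outer(t, np.arange(6)) @ _KELL_NUM
    dnum = np.power.outer(t, np.arange(5)) @ (_KELL_NUM[1:] * np.arange(1, 6))
    den = 1.0 + _KELL_DEN * t
    return (dnum * den - num * _KELL_DEN) / den**2


def water_density(t_celsius):
    """Density of liquid water, kg m^-3."""
    return _kell_density(t_celsius)


def water_viscosity(t_celsius):
    """Dynamic viscosity of liquid water, Pa s."""
    t_kelvin = np.asarray(t_celsius, dtype=float) + 273.15
    return 2.414e-5 * 10.0 ** (247.8 / (t_kelvin - 140.0))


def water_expansion_coefficient(t_celsius):
    """Volume expansion coefficient ``beta = -(1/rho) d(rho)/dT``, K^-1."""
    return -_kell_density_derivative(t_celsius) / _kell_density(t_celsius)


def water_properties(t_celsius: float) -> WaterProperties:
    """Evaluate ``rho``, ``eta`` and ``beta`` at one film temperature.

    Raises
    ------
    ValueError
        If the temperature lies outside the documented 5-95 °C validity range.
    """
    t = float(t_celsius)
    if not (T_VALID_MIN <= t <= T_VALID_MAX):
        raise ValueError(
            f"temperature {t} °C outside correlation validity range "
            f"[{T_VALID_MIN}, {T_VALID_MAX}] °C"
        )
    return WaterProperties(
        temperature=t,
        density=float(water_density(t)),
        dynamic_viscosity=float(water_viscosity(t)),
        volume_expansion=float(water_expansion_coefficient(t)),
    )
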