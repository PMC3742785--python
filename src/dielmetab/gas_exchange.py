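"""Physical chemistry of air–water O₂ exchange.

Pure functions for equilibrium O₂ solubility, the freshwater O₂ Schmidt
number, the wind-speed parameterisation of the gas transfer velocity
k600, and conversion/temperature-standardisation of the volumetric
reaeration coefficient K.

Conventions
-----------
* ``k`` (lower case) is a gas transfer velocity in cm h⁻¹;
  ``K`` (upper case) is a volumetric reaeration coefficient in h⁻¹,
  ``K = k / (100 · z_mix)`` for a mixed layer of depth ``z_mix`` metres.
* ``K20`` is K standardised to 20 °C through the Schmidt-number ratio
  with exponent ½ (wind-roughened surface):
  ``K20 = K_T · (Sc(T)/Sc(20))^{1/2}``, so warm water (smaller Sc) has
  ``K_T > K20``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GasParams",
    "o2_saturation",
    "schmidt_o2",
    "k600_from_wind",
    "k_to_K",
    "standardize_K20",
    "destandardize_K20",
    "k20_from_wind",
]

#: Schmidt number of O2 in fresh water at 20 degC (Wanninkhof polynomial)
SC_O2_20 = 530.456

#: quadratic coefficient of the Ho et al. wind relation, cm h-1 / (m s-1)^2
HO_COEF = 0.266


@dataclass(frozen=True)
class GasParams:
    """Configuration for gas-exchange conversions."""

    mixing_depth_m: float = 0.5
    pressure_atm: float = 1.0
    schmidt_exponent: float = -0.5
    ho_coef: float = HO_COEF

    def __post_init__(self) -> None:
        if self.mixing_depth_m <= 0:
            raise ValueError("mixing_depth_m must be > 0")
        if self.pressure_atm <= 0:
            raise ValueError("pressure_atm must be > 0")


def o2_saturation(temp_C, pressure_atm: float = 1.0):
    """Equilibrium dissolved O₂ concentration in fresh water, mg L⁻¹.

    Benson–Krause fit (the basis of the USGS solubility tables) at
    salinity 0, scaled linearly with total pressure (Henry's law;
    9.092 mg L⁻¹ at 20 °C and 1 atm).
    """
    t = np.asarray(temp_C, dtype=float)
    if np.any((t <= 0) | (t >= 45)):
        raise ValueError("temperature outside (0, 45) degC")
    T = t + 273.15
    ln_c = (
        -139.34411
        + 1.575701e5 / T
        - 6.642308e7 / T**2
        + 1.243800e10 / T**3
        - 8.621949e11 / T**4
    )
    out = np.exp(ln_c) * pressure_atm
    return float(out) if np.isscalar(temp_C) else out


def schmidt_o2(temp_C):
    """Schmidt number of O₂ in fresh water (Wanninkhof cubic polynomial)."""
    t = np.asarray(temp_C, dtype=float)
    if np.any((t <= 0) | (t >= 40)):
        raise ValueError("temperature outside the (0, 40) degC fit range")
    out = 1800.6 - 120.1 * t + 3.7818 * t**2 - 0.047608 * t**3
    return float(out) if np.isscalar(temp_C) else out


def k600_from_wind(u10_ms, coef: float = HO_COEF):
    """Gas transfer velocity k600 (cm h⁻¹) from wind speed at 10 m.

    Quadratic wind relation ``k600 = coef · u10²`` with the Ho et al.
    coefficient 0.266 by default.
    """
    u = np.asarray(u10_ms, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be >= 0")
    out = coef * u**2
    return float(out) if np.isscalar(u10_ms) else out


def k_to_K(k_cmh, params: GasParams = GasParams()):
    """Convert a transfer velocity (cm h⁻¹) to a volumetric coefficient (h⁻¹)."""
    k = np.asarray(k_cmh, dtype=float)
    if np.any(k < 0):
        raise ValueError("transfer velocity must be >= 0")
    out = k / 100.0 / params.mixing_depth_m
    return float(out) if np.isscalar(k_cmh) else out


def standardize_K20(K_T, temp_C, params: GasParams = GasParams()):
    """Standardise an in-situ reaeration coefficient to 20 °C.

    ``K20 = K_T · (Sc(T)/Sc(20))^(−schmidt_exponent)``; with the default
    exponent −½ this is ``K_T·(Sc(T)/Sc(20))^{1/2}`` — below K_T for
    water warmer than 20 °C.
    """
    K = np.asarray(K_T, dtype=float)
    if np.any(K < 0):
        raise ValueError("K_T must be >= 0")
    ratio = schmidt_o2(temp_C) / SC_O2_20
    out = K * ratio ** (-params.schmidt_exponent)
    return float(out) if np.isscalar(K_T) and np.isscalar(temp_C) else out


def destandardize_K20(K20, temp_C, params: GasParams = GasParams()):
    """Inverse of :func:`standardize_K20`: K at in-situ temperature."""
    K = np.asarray(K20, dtype=float)
    if np.any(K < 0):
        raise ValueError("K20 must be >= 0")
    ratio = schmidt_o2(temp_C) / SC_O2_20
    out = K * ratio ** (params.schmidt_exponent)
    return float(out) if np.isscalar(K20) and np.isscalar(temp_C) else out


def k20_from_wind(u10_ms, params: GasParams = GasParams()):
    """Daily-mean wind speed → K₂₀ (h⁻¹) at the configured mixing depth.

    ``K20 = k600(u10) / 100 / z_mix``, treating the wind-derived k600 as
    the 20 °C transfer velocity (a ≈6% approximation of the full
    Schmidt-number chain from 600 to Sc(20) = 530).
    """
    return k_to_K(k600_from_wind(u10_ms, params.ho_coef), params)
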