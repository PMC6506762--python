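"""Air, water-vapour and radiation property functions.

Every other module builds on these primitives. All functions are pure,
accept scalars or numpy arrays, and use SI units internally: kelvin,
pascal, seconds, W m⁻², mol m⁻² s⁻¹. Degrees Celsius and percent RH
appear only at I/O boundaries.

Formulations
------------
* saturation vapour pressure: Buck (1981) over liquid water,
  ``es = 611.21 * exp((18.678 - tc/234.5) * tc / (tc + 257.14))`` with
  ``tc`` in °C — accurate to better than 0.1% over 0–50 °C;
* moist-air density: ideal-gas mixture of dry air and water vapour via
  partial pressures;
* specific heat of humid air: mass-weighted mixture rule
  ``Cs = Cp_dry*(1-q) + Cp_vap*q`` with specific humidity ``q``;
* latent heat of vaporization: the standard linear fit
  ``λ(T) = (2.501 - 0.002361*(T - 273.15)) × 1e6`` J kg⁻¹.

These are swappable behind this module's interface; any alternative
psychrometric formulation agreeing within ~1% over 0–40 °C yields
indistinguishable energy-balance results (temperature kinetics respond
far more strongly to conductances and heat capacity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STEFAN_BOLTZMANN",
    "GAS_CONSTANT",
    "AirState",
    "saturation_vapour_pressure",
    "air_vapour_pressure",
    "air_density",
    "humid_air_specific_heat",
    "latent_heat",
    "ppfd_to_shortwave",
    "molar_density",
    "gbh_to_gbw",
]

#: Stefan–Boltzmann constant, W m⁻² K⁻⁴ (CODATA).
STEFAN_BOLTZMANN = 5.670374419e-8
#: Universal gas constant, m³ Pa K⁻¹ mol⁻¹.
GAS_CONSTANT = 8.31446

# molar masses, kg mol⁻¹
_M_DRY = 0.0289652
_M_VAP = 0.018016

# specific heats at constant pressure, J kg⁻¹ K⁻¹
_CP_DRY = 1005.0
_CP_VAP = 1860.0

#: water-vapour/heat diffusivity correction for laminar boundary layers
#: (ratio of diffusivities to the 2/3 power).
RATIO_WH = 1.08

_T_MIN, _T_MAX = 230.0, 340.0


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= _T_MIN) or np.any(T >= _T_MAX):
        bad = np.atleast_1d(T)[(np.atleast_1d(T) <= _T_MIN) | (np.atleast_1d(T) >= _T_MAX)]
        raise ValueError(
            f"temperature {bad[0]:.2f} K outside supported range ({_T_MIN}, {_T_MAX}) K"
        )
    return T


@dataclass(frozen=True)
class AirState:
    """Thermodynamic state of the air surrounding the objects.

    Fields may be scalars or equally shaped numpy arrays (a time series
    of states). Temperatures in kelvin, RH as a fraction, pressure in Pa.
    """

    T_air: float | np.ndarray
    RH: float | np.ndarray
    P_atm: float | np.ndarray = 101325.0

    def __post_init__(self):
        T = np.asarray(self.T_air, dtype=float)
        rh = np.asarray(self.RH, dtype=float)
        p = np.asarray(self.P_atm, dtype=float)
        if np.any(T <= _T_MIN) or np.any(T >= _T_MAX):
            raise ValueError(f"T_air outside ({_T_MIN}, {_T_MAX}) K: {float(np.min(T)):.2f}")
        if np.any(rh < 0.0) or np.any(rh > 1.0):
            raise ValueError("RH must be a fraction in [0, 1]")
        if np.any(p <= 5e4) or np.any(p >= 1.2e5):
            raise ValueError("P_atm outside plausible range (5e4, 1.2e5) Pa")


def saturation_vapour_pressure(T):
    """Saturation vapour pressure over liquid water, Pa (Buck 1981).

    ``T`` in kelvin, restricted to (230, 340) K. Strictly increasing.
    """
    T = _check_temperature(T)
    tc = T - 273.15
    return 611.21 * np.exp((18.678 - tc / 234.5) * tc / (tc + 257.14))


def air_vapour_pressure(air: AirState):
    """Actual vapour pressure of the air, ``e_a = RH * es(T_air)``, Pa."""
    return np.asarray(air.RH, dtype=float) * saturation_vapour_pressure(air.T_air)


def air_density(air: AirState):
    """Moist-air density ρ, kg m⁻³ (ideal-gas partial-pressure mixture).

    Decreasing in temperature and in humidity (water is lighter than
    dry air).
    """
    T = np.asarray(air.T_air, dtype=float)
    P = np.asarray(air.P_atm, dtype=float)
    e = air_vapour_pressure(air)
    return ((P - e) * _M_DRY + e * _M_VAP) / (GAS_CONSTANT * T)


def _specific_humidity(air: AirState):
    e = air_vapour_pressure(air)
    P = np.asarray(air.P_atm, dtype=float)
    return 0.622 * e / (P - 0.378 * e)


def humid_air_specific_heat(air: AirState):
    """Specific heat capacity of humid air C_s, J kg⁻¹ K⁻¹ (mixture rule)."""
    q = _specific_humidity(air)
    return _CP_DRY * (1.0 - q) + _CP_VAP * q


def latent_heat(T):
    """Latent heat of vaporization of water λ(T), J kg⁻¹ (linear fit)."""
    T = _check_temperature(T)
    return (2.501 - 0.002361 * (T - 273.15)) * 1e6


def ppfd_to_shortwave(ppfd, factor: float):
    """Convert PPFD (µmol m⁻² s⁻¹) to shortwave irradiance (W m⁻²).

    ``factor`` is the radiation conversion factor of the light source in
    J µmol⁻¹, measured with a spectroradiometer for a given lamp; it is
    a required input because it is source-specific.
    """
    ppfd = np.asarray(ppfd, dtype=float)
    if np.any(ppfd < 0):
        raise ValueError(f"PPFD must be non-negative, got {float(np.min(ppfd))}")
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    return ppfd * factor


def molar_density(T, P):
    """Molar density of an ideal gas, ``P / (R T)``, mol m⁻³."""
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(T <= 0) or np.any(P <= 0):
        raise ValueError("T and P must be positive")
    return P / (GAS_CONSTANT * T)


def gbh_to_gbw(g_bh, T, P, sides: int = 2, ratio_wh: float = RATIO_WH):
    """Convert boundary-layer conductance to heat (m s⁻¹, one-sided) into
    a molar conductance to water vapour (mol m⁻² s⁻¹).

    ``g_bw = sides * ratio_wh * g_bh * P/(R T)``: the velocity-type heat
    conductance is scaled by the molar density of air, corrected for the
    higher diffusivity of water vapour relative to heat (``ratio_wh``,
    ≈1.08 for laminar layers), and aggregated over ``sides`` faces
    (2 for an amphistomatous leaf, 1 for a plate transpiring from one
    face only).
    """
    g_bh = np.asarray(g_bh, dtype=float)
    if np.any(g_bh < 0):
        raise ValueError("g_bh must be non-negative")
    if sides not in (0, 1, 2):
        raise ValueError("sides must be 0, 1 or 2")
    return sides * ratio_wh * g_bh * molar_density(T, P)
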