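"""Boundary-layer conductance from a black/white reference pair, and
the theoretical pore conductance of a perforated-membrane leaf replica.

Two references cut from the same aluminium sheet (identical k and very
similar ε) but painted black and white absorb different fractions of
the incident shortwave, so under a light step they separate in
temperature by an amount governed by the boundary-layer conductance to
heat g_bh: the stronger the convective coupling to the air, the smaller
the gap. Predicting the white reference's kinetics from the black one
through the differenced budget and adjusting a single constant g_bh to
fit the observation yields a passive estimate that needs no heater and
works under a fluctuating environment.

The replica's membrane conductance follows from pore diffusion: each
cylindrical pore of radius r and depth d conducts
``D π r² / (d + π r / 4)`` (single-end correction, the equivalent-length
form of the half-space disk access resistance), and the areal molar
conductance is the pore density times that, times P/(R T).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .energy_balance import ThermalObjectProps, predict_temperature_fast
from .physics import GAS_CONSTANT
from .signals import SmoothedEnvironment, Trace, smooth

log = logging.getLogger(__name__)

__all__ = ["PoreGeometry", "pore_conductance", "estimate_gbh", "water_vapour_diffusivity"]

_INCH2 = 0.0254 ** 2

#: reference water-vapour diffusivity in air at 20 °C, m² s⁻¹
_D_REF = 2.42e-5
_T_REF = 293.15
_P_REF = 101325.0


@dataclass(frozen=True)
class PoreGeometry:
    """Cylindrical pore array: diameter and depth in metres, areal
    density in pores m⁻²."""

    diameter: float
    depth: float
    density: float

    def __post_init__(self):
        if min(self.diameter, self.depth) <= 0 or self.density < 0:
            raise ValueError("pore diameter and depth must be > 0, density >= 0")
        if self.density > 0 and self.diameter >= 1.0 / np.sqrt(self.density):
            raise ValueError("pore diameter exceeds the inter-pore pitch")

    @classmethod
    def from_inch_density(cls, diameter: float, depth: float,
                          pores_per_inch2: float) -> "PoreGeometry":
        return cls(diameter, depth, pores_per_inch2 / _INCH2)


def water_vapour_diffusivity(T: float = _T_REF, P: float = _P_REF) -> float:
    """Binary diffusivity of water vapour in air, m² s⁻¹.

    Scaled from 2.42e-5 m² s⁻¹ at 20 °C, 1 atm with D ∝ T^1.75 / P.
    """
    return _D_REF * (T / _T_REF) ** 1.75 * (_P_REF / P)


def pore_conductance(geom: PoreGeometry, T: float = _T_REF, P: float = _P_REF) -> float:
    """Molar conductance of the pore array, mol m⁻² s⁻¹.

    ``g = n · D · π r² / (depth + π r / 4) · P/(R T)`` with a single
    end correction of equivalent length π r / 4.
    """
    r = geom.diameter / 2.0
    D = water_vapour_diffusivity(T, P)
    per_pore = D * np.pi * r ** 2 / (geom.depth + np.pi * r / 4.0)
    return float(geom.density * per_pore * P / (GAS_CONSTANT * T))


def estimate_gbh(black: Trace, white: Trace, env: SmoothedEnvironment,
                 props_black: ThermalObjectProps, props_white: ThermalObjectProps,
                 sw_factor: float, dt: float = 1.0, smoothing: float | None = None,
                 bounds: tuple[float, float] = (1e-4, 0.2)) -> tuple[float, float]:
    """Least-squares estimate of a constant g_bh from a reference pair.

    Smooths the black reference, predicts the white reference's
    temperature through the differenced budget (no latent term) for a
    trial g_bh shared by both references, and minimizes the squared
    error against the observed white trace.

    Returns ``(g_bh, rmse)`` in (m s⁻¹, K).
    """
    t0 = max(black.t[0], white.t[0], env.domain[0])
    t1 = min(black.t[-1], white.t[-1], env.domain[1])
    if t1 <= t0:
        raise ValueError("black and white traces do not overlap in time")
    ref = smooth(black, smoothing)
    mask = (white.t >= t0) & (white.t <= t1)
    t_obs = white.t[mask]
    # snap the comparison grid onto multiples of dt
    t_obs = t_obs[np.abs((t_obs - t_obs[0]) / dt - np.round((t_obs - t_obs[0]) / dt)) < 1e-6]
    y_obs = np.interp(t_obs, white.t, white.y)

    contrast = float(np.max(np.abs(
        np.interp(t_obs, black.t, black.y) - y_obs)))
    noise = max(ref.residual_sd, 1e-4)
    if contrast < 5.0 * noise:
        raise ValueError(
            f"references show no usable temperature contrast "
            f"(max |T_b - T_w| = {contrast:.4f} K < 5 x noise SD {noise:.4f} K); "
            f"g_bh is not identifiable"
        )

    def sse(g):
        p_w = props_white.with_(g_bh=g)
        p_b = props_black.with_(g_bh=g)
        pred = predict_temperature_fast(p_w, p_b, ref, env, None, float(y_obs[0]),
                                        t_obs, sw_factor, dt=dt)
        return float(np.sum((pred.y - y_obs) ** 2))

    res = minimize_scalar(sse, bounds=bounds, method="bounded",
                          options={"xatol": 1e-7})
    g_hat = float(res.x)
    rmse = float(np.sqrt(res.fun / t_obs.size))
    if g_hat <= bounds[0] * 1.01 or g_hat >= bounds[1] * 0.99:
        log.warning("estimated g_bh = %.4g m s^-1 sits at the search bound", g_hat)
    return g_hat, rmse
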