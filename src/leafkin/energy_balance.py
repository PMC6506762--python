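"""Leaf/reference energy budgets: fluxes, ODEs and steady states.

An object of areal heat capacity ``k`` (J m⁻² K⁻¹) exposed on both
faces exchanges energy by shortwave absorption, longwave emission,
sensible heat and (if it transpires) latent heat. Any imbalance is
stored and drives the temperature:

    k dT/dt = Rn − C − λE

The central trick of the package is *reference differencing*: writing
this budget for the object of interest (1) and for a non-transpiring
reference (2) in the same thermal environment and subtracting them. The
incident longwave term L_d — hard to measure inside a phenotyping
cabinet — is common to both and cancels, leaving an ODE for T1 driven
entirely by the measured reference kinetics (T2, dT2/dt), the measured
shortwave irradiance and air state, and the property contrast between
the two objects:

    dT1/dt = [ k2 dT2/dt + Is (s1 α1 − s2 α2) + 2θ (ε2 T2⁴ − ε1 T1⁴)
               + 2 ρ Cs (g_bh2 (T2 − T_air) − g_bh1 (T1 − T_air))
               − λE1 ] / k1

``s1, s2`` are per-object irradiance scales covering setups where the
reference sits at a site receiving a different light level than the
leaf (e.g. 300 vs 430 µmol m⁻² s⁻¹); with equal scales the term reduces
to the familiar Is (α1 − α2).

The latent flux uses the water-vapour gradient across the series chain
of boundary-layer and stomatal (or pore) conductance. The aggregated
convention is used throughout: g_bw already sums both faces via the
``transpiring_sides`` factor in the m s⁻¹ → mol m⁻² s⁻¹ conversion, so
λE enters each budget exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import _kernels, physics
from .gs_kinetics import GS_FLOOR, LightSchedule, StomatalKinetics, gs_schedule
from .physics import (
    GAS_CONSTANT,
    RATIO_WH,
    STEFAN_BOLTZMANN,
    AirState,
    air_density,
    air_vapour_pressure,
    gbh_to_gbw,
    humid_air_specific_heat,
    latent_heat,
    saturation_vapour_pressure,
)
from .signals import SmoothedEnvironment, SmoothSignal, Trace

log = logging.getLogger(__name__)

__all__ = [
    "ThermalObjectProps",
    "FluxBreakdown",
    "SolverConfig",
    "net_radiation",
    "sensible_heat",
    "total_conductance",
    "transpiration",
    "full_budget_rhs",
    "differenced_rhs",
    "predict_temperature",
    "predict_temperature_fast",
    "steady_state_temperature",
    "environment_arrays",
    "stage_grid",
    "resolve_conductance",
]


@dataclass(frozen=True)
class ThermalObjectProps:
    """Optical/thermal description of a flat two-faced object.

    alpha
        shortwave absorbance (0–1);
    epsilon
        longwave emissivity (0–1);
    k
        areal heat capacity ρ*·C*p·l*, J m⁻² K⁻¹;
    g_bh
        one-sided boundary-layer conductance to heat, m s⁻¹;
    transpiring_sides
        0 (dry reference), 1 (plate wet on one face) or 2
        (amphistomatous leaf);
    light_scale
        fraction of the nominal shortwave irradiance this object's site
        receives (references placed off-centre see less light).
    """

    alpha: float
    epsilon: float
    k: float
    g_bh: float = 0.0
    transpiring_sides: int = 0
    light_scale: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if self.k <= 0:
            raise ValueError("areal heat capacity k must be > 0")
        if self.g_bh < 0:
            raise ValueError("g_bh must be >= 0")
        if self.transpiring_sides not in (0, 1, 2):
            raise ValueError("transpiring_sides must be 0, 1 or 2")
        if self.light_scale < 0:
            raise ValueError("light_scale must be >= 0")

    def with_(self, **kw) -> "ThermalObjectProps":
        return replace(self, **kw)


@dataclass(frozen=True)
class FluxBreakdown:
    """Instantaneous budget terms, W m⁻²; storage = Rn − C − latent."""

    Rn: float
    C: float
    latent: float

    @property
    def storage(self) -> float:
        return self.Rn - self.C - self.latent


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive-solver settings for the (stiff) differenced ODE."""

    method: str = "BDF"
    rtol: float = 1e-6
    atol: float = 1e-8
    max_step: float = 5.0


def net_radiation(props: ThermalObjectProps, I_s, T, L_d=0.0):
    """Net radiation Rn = α·Is − 2θε·T⁴ + L_d, W m⁻².

    ``L_d`` is the incident longwave aggregated over both faces; it is
    only needed in forward simulation — it cancels in the differenced
    model.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    return (
        props.alpha * np.asarray(I_s, dtype=float)
        - 2.0 * STEFAN_BOLTZMANN * props.epsilon * T ** 4
        + L_d
    )


def sensible_heat(props: ThermalObjectProps, T, air: AirState):
    """Sensible heat C = 2·g_bh·ρ·Cs·(T − T_air), W m⁻² (both faces)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    rho = air_density(air)
    cs = humid_air_specific_heat(air)
    return 2.0 * props.g_bh * rho * cs * (T - np.asarray(air.T_air, dtype=float))


def total_conductance(g_bw, g_sw):
    """Series combination 1/(1/g_bw + 1/g_sw), mol m⁻² s⁻¹.

    Either conductance at 0 short-circuits the chain to 0; values above
    1e9 are treated as effectively infinite.
    """
    g_bw = np.asarray(g_bw, dtype=float)
    g_sw = np.asarray(g_sw, dtype=float)
    if np.any(g_bw < 0) or np.any(g_sw < 0):
        raise ValueError("conductances must be >= 0")
    g_bw, g_sw = np.broadcast_arrays(g_bw, g_sw)
    safe_b = np.where(g_bw > 0, g_bw, 1.0)
    safe_s = np.where(g_sw > 0, g_sw, 1.0)
    inv = np.where(g_bw >= 1e9, 0.0, 1.0 / safe_b) + np.where(g_sw >= 1e9, 0.0, 1.0 / safe_s)
    series = np.where(inv > 0, 1.0 / np.where(inv > 0, inv, 1.0), np.inf)
    out = np.where((g_bw > 0) & (g_sw > 0), series, 0.0)
    return float(out) if out.ndim == 0 else out


def transpiration(g_tw, T_leaf, air: AirState, clamp: bool = True, warn: bool = True):
    """Evaporative mass flux E, kg m⁻² s⁻¹.

    E = (0.622 ρ / P_atm) · (R T_leaf / P_atm) · g_tw · (es(T_leaf) − e_a):
    the molar flux through the total conductance times the vapour
    pressure gradient, converted to a mass flux per unit projected
    area. Negative values (condensation) are clamped to 0 by default
    with a logged warning.
    """
    g_tw = np.asarray(g_tw, dtype=float)
    if np.any(g_tw < 0):
        raise ValueError("g_tw must be >= 0")
    T_leaf = np.asarray(T_leaf, dtype=float)
    rho = air_density(air)
    P = np.asarray(air.P_atm, dtype=float)
    e_grad = saturation_vapour_pressure(T_leaf) - air_vapour_pressure(air)
    E = 0.622 * rho / P * (GAS_CONSTANT * T_leaf / P) * g_tw * e_grad
    if clamp and np.any(E < 0):
        log.log(logging.WARNING if warn else logging.DEBUG,
                "negative transpiration (condensation) clamped to 0")
        E = np.maximum(E, 0.0)
    return E


def latent_flux(props: ThermalObjectProps, g_sw, T, air: AirState,
                ratio_wh: float = RATIO_WH):
    """λE for an object, W m⁻², from its surface conductance g_sw.

    g_bw is derived from the object's heat conductance aggregated over
    its transpiring faces; λE enters the budget once.
    """
    if props.transpiring_sides == 0:
        return np.zeros_like(np.asarray(T, dtype=float)) + 0.0
    g_bw = gbh_to_gbw(props.g_bh, air.T_air, air.P_atm,
                      sides=props.transpiring_sides, ratio_wh=ratio_wh)
    g_tw = total_conductance(g_bw, np.maximum(g_sw, GS_FLOOR))
    E = transpiration(g_tw, T, air, warn=False)
    return latent_heat(T) * E


def full_budget_rhs(T, t, props: ThermalObjectProps, env: SmoothedEnvironment,
                    L_d, sw_factor: float, g_sw=0.0) -> float:
    """dT/dt = (Rn − C − λE)/k for a single object at time ``t``.

    ``L_d`` may be a scalar or a callable of t. Used by the synthetic
    generator and as the algebraic oracle for the differenced form.
    """
    air = AirState(env.t_air.value(t), np.clip(env.rh.value(t), 0.0, 1.0),
                   env.p_atm.value(t))
    I_s = physics.ppfd_to_shortwave(env.ppfd.value(t), sw_factor) * props.light_scale
    ld = L_d(t) if callable(L_d) else L_d
    Rn = net_radiation(props, I_s, T, ld)
    C = sensible_heat(props, T, air)
    lE = latent_flux(props, g_sw, T, air)
    return float((Rn - C - lE) / props.k)


def budget_terms(T, t, props: ThermalObjectProps, env: SmoothedEnvironment,
                 L_d, sw_factor: float, g_sw=0.0) -> FluxBreakdown:
    """Diagnostic flux breakdown at one instant (storage is the identity)."""
    air = AirState(env.t_air.value(t), np.clip(env.rh.value(t), 0.0, 1.0),
                   env.p_atm.value(t))
    I_s = physics.ppfd_to_shortwave(env.ppfd.value(t), sw_factor) * props.light_scale
    ld = L_d(t) if callable(L_d) else L_d
    return FluxBreakdown(
        Rn=float(net_radiation(props, I_s, T, ld)),
        C=float(sensible_heat(props, T, air)),
        latent=float(latent_flux(props, g_sw, T, air)),
    )


def differenced_rhs(T1, t, ref_signal: SmoothSignal, env: SmoothedEnvironment,
                    props1: ThermalObjectProps, props2: ThermalObjectProps,
                    latent1, sw_factor: float) -> float:
    """dT1/dt of the reference-differenced budget at time ``t``.

    ``props2`` must be non-transpiring; ``latent1`` is λE of the object
    of interest in W m⁻² (scalar or callable of (T1, t)).
    """
    if props2.transpiring_sides != 0:
        raise ValueError("the reference object must be non-transpiring")
    air = AirState(env.t_air.value(t), np.clip(env.rh.value(t), 0.0, 1.0),
                   env.p_atm.value(t))
    rho = air_density(air)
    cs = humid_air_specific_heat(air)
    T2 = float(ref_signal.value(t))
    dT2 = float(ref_signal.derivative(t))
    I_s = float(physics.ppfd_to_shortwave(env.ppfd.value(t), sw_factor))
    lE = latent1(T1, t) if callable(latent1) else latent1
    tair = float(air.T_air)
    return float(
        (
            props2.k * dT2
            + I_s * (props1.light_scale * props1.alpha - props2.light_scale * props2.alpha)
            + 2.0 * STEFAN_BOLTZMANN
            * (props2.epsilon * T2 ** 4 - props1.epsilon * T1 ** 4)
            + 2.0 * rho * cs
            * (props2.g_bh * (T2 - tair) - props1.g_bh * (T1 - tair))
            - lE
        )
        / props1.k
    )


def resolve_conductance(conductance):
    """Normalize the surface-conductance argument to a callable gs(t).

    Accepts ``None`` (no transpiration), a fixed scalar in
    mol m⁻² s⁻¹, a ``(StomatalKinetics, LightSchedule)`` pair, or any
    callable of t.
    """
    if conductance is None:
        return lambda t: np.zeros_like(np.asarray(t, dtype=float)) + 0.0
    if isinstance(conductance, (int, float)):
        g = float(conductance)
        if g < 0:
            raise ValueError("fixed conductance must be >= 0")
        return lambda t: np.full_like(np.asarray(t, dtype=float), g, dtype=float)
    if isinstance(conductance, tuple) and isinstance(conductance[0], StomatalKinetics):
        params, schedule = conductance
        return lambda t: gs_schedule(t, params, schedule)
    if callable(conductance):
        return conductance
    raise TypeError("conductance must be None, a scalar, (StomatalKinetics, "
                    "LightSchedule) or a callable of t")


def predict_temperature(props1: ThermalObjectProps, props2: ThermalObjectProps,
                        ref_signal: SmoothSignal, env: SmoothedEnvironment,
                        conductance, T1_0: float, t_eval: np.ndarray,
                        sw_factor: float, cfg: SolverConfig | None = None) -> Trace:
    """Predict the object's temperature kinetics on ``t_eval``.

    Integrates the differenced ODE with an adaptive implicit solver
    (BDF by default; the equation is stiff relative to the observation
    cadence). The surface conductance drives λE through the series
    chain at every step.
    """
    cfg = cfg or SolverConfig()
    t_eval = np.asarray(t_eval, dtype=float)
    lo = max(ref_signal.domain[0], env.domain[0])
    hi = min(ref_signal.domain[1], env.domain[1])
    if t_eval[0] < lo - 1e-9 or t_eval[-1] > hi + 1e-9:
        raise ValueError("requested output grid extends beyond the signal domains")
    gs_fun = resolve_conductance(conductance)

    def latent1(T1, t):
        if props1.transpiring_sides == 0:
            return 0.0
        air = AirState(env.t_air.value(t), np.clip(env.rh.value(t), 0.0, 1.0),
                       env.p_atm.value(t))
        return float(latent_flux(props1, float(gs_fun(t)), T1, air))

    def rhs(t, y):
        return [differenced_rhs(y[0], t, ref_signal, env, props1, props2,
                                latent1, sw_factor)]

    # restart the integrator at light switches: the RHS jumps there and
    # an adaptive method stepping across loses accuracy
    knots = getattr(env.ppfd, "_t", np.array([]))
    breaks = [float(b) for b in np.atleast_1d(knots)
              if t_eval[0] < b < t_eval[-1]]
    edges = np.concatenate(([t_eval[0]], breaks, [t_eval[-1]]))
    ys = np.empty_like(t_eval)
    y0 = float(T1_0)
    filled = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        seg_mask = (t_eval >= lo) & (t_eval <= hi) if hi == edges[-1] else \
            (t_eval >= lo) & (t_eval < hi)
        seg_eval = np.unique(np.concatenate((t_eval[seg_mask], [hi])))
        # keep the RHS one-sided within the segment
        shift = 1e-9 * max(1.0, hi - lo)
        sol = solve_ivp(rhs, (lo, hi - shift), [y0], method=cfg.method,
                        t_eval=np.clip(seg_eval, lo, hi - shift),
                        rtol=cfg.rtol, atol=cfg.atol, max_step=cfg.max_step)
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed at t = {sol.t[-1] if sol.t.size else lo:.1f} s: "
                f"{sol.message}"
            )
        vals = dict(zip(seg_eval, sol.y[0]))
        take = t_eval[seg_mask]
        ys[filled:filled + take.size] = [vals[v] for v in take]
        filled += take.size
        y0 = float(sol.y[0][-1])
    return Trace(t_eval, ys, channel="T_predicted")


def environment_arrays(env: SmoothedEnvironment, ts: np.ndarray, sw_factor: float):
    """Tabulate the environmental drivers on a grid (kernel input)."""
    ts = np.asarray(ts, dtype=float)
    tair = np.asarray(env.t_air.value(ts), dtype=float)
    rh = np.clip(np.asarray(env.rh.value(ts), dtype=float), 0.0, 1.0)
    patm = np.asarray(env.p_atm.value(ts), dtype=float)
    air = AirState(tair, rh, patm)
    return {
        "Is": np.asarray(physics.ppfd_to_shortwave(env.ppfd.value(ts), sw_factor)),
        "tair": tair,
        "rho": np.asarray(air_density(air)),
        "cs": np.asarray(humid_air_specific_heat(air)),
        "ea": np.asarray(air_vapour_pressure(air)),
        "patm": patm,
    }


def stage_grid(t0: float, t1: float, dt: float,
               eps: float = 1e-6) -> tuple[np.ndarray, int]:
    """RK4 stage-time grid covering [t0, t1] with step dt (dt must divide).

    Returns a (3, n) array of evaluation times per step — ``t_i + eps``
    (right limit), the midpoint, and ``t_{i+1} − eps`` (left limit) —
    so that drivers with jumps at grid points are always sampled on the
    correct side of the discontinuity.
    """
    n = int(round((t1 - t0) / dt))
    if n < 1 or abs(t0 + n * dt - t1) > 1e-6 * max(1.0, abs(t1)):
        raise ValueError("dt must divide the integration span")
    i = np.arange(n)
    ts = np.stack([t0 + i * dt + eps,
                   t0 + (i + 0.5) * dt,
                   t0 + (i + 1.0) * dt - eps])
    return ts, n


def predict_temperature_fast(props1: ThermalObjectProps, props2: ThermalObjectProps,
                             ref_signal: SmoothSignal, env: SmoothedEnvironment,
                             conductance, T1_0: float, t_eval: np.ndarray,
                             sw_factor: float, dt: float = 1.0) -> Trace:
    """Fixed-step RK4 variant of :func:`predict_temperature`.

    Tabulates all drivers on a half-step grid and runs the compiled
    kernel; ``t_eval`` points must be multiples of ``dt`` from the
    start. Used inside likelihood evaluations and as the brute-force
    oracle at small ``dt``.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    ts, n = stage_grid(t_eval[0], t_eval[-1], dt)
    arrs = environment_arrays(env, ts, sw_factor)
    gs_fun = resolve_conductance(conductance)
    gsw = np.maximum(np.asarray(gs_fun(ts), dtype=float), GS_FLOOR)
    T2 = np.asarray(ref_signal.value(ts), dtype=float)
    dT2 = np.asarray(ref_signal.derivative(ts), dtype=float)
    out = _kernels.rk4_differenced(
        float(T1_0), dt, n, T2, dT2, arrs["Is"], arrs["tair"], arrs["rho"],
        arrs["cs"], arrs["ea"], arrs["patm"],
        props1.k, props2.k, props1.alpha, props2.alpha,
        props1.epsilon, props2.epsilon, props1.g_bh, props2.g_bh,
        props1.light_scale, props2.light_scale,
        gsw, props1.transpiring_sides, RATIO_WH,
    )
    idx = np.round((t_eval - t_eval[0]) / dt).astype(int)
    if np.any(np.abs(t_eval[0] + idx * dt - t_eval) > 1e-6):
        raise ValueError("t_eval points must lie on the RK4 grid")
    return Trace(t_eval, out[idx], channel="T_predicted")


def steady_state_temperature(props: ThermalObjectProps, I_s: float, L_d: float,
                             air: AirState, g_sw: float = 0.0) -> float:
    """Root of Rn − C − λE = 0 at a fixed environment (equilibrium T).

    Scalar Brent root-finder on a bracket around T_air; serves as the
    analytic oracle for the terminal state of the dynamic model under a
    constant environment.
    """
    tair = float(np.asarray(air.T_air, dtype=float))

    def f(T):
        Rn = net_radiation(props, I_s * props.light_scale, T, L_d)
        C = sensible_heat(props, T, air)
        lE = latent_flux(props, g_sw, T, air)
        return float(Rn - C - lE)

    return brentq(f, tair - 30.0, tair + 44.0, xtol=1e-10)
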