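"""Forward simulation of complete thermography experiments.

Generates leaf, black/white reference and leaf-replica temperature
traces with known ground truth, so every stage of the pipeline —
smoothing, boundary-layer estimation, Bayesian parameter recovery — can
be tested end to end without any measured data.

The emulated protocol is a dark/light/dark light-step experiment in a
phenotyping cabinet: 10 min of darkness, 1 h at 430 µmol m⁻² s⁻¹, then
1 h of darkness, with the aluminium references sitting slightly off the
illuminated centre and receiving ~300/430 of the nominal light. Air
temperature and relative humidity drift slowly (piecewise-linearly)
after the light switches, as real cabinets do; the camera contributes
iid Gaussian noise with an SD of 0.03 K (the noise-equivalent
temperature difference class of research microbolometers); frames are
saved every 3 s.

Incident longwave is synthesized from a single wall temperature,
``L_d = 2 θ T_wall⁴`` (default: the wall tracks the air), because the
differenced model must be invariant to it; a custom wall trace can be
supplied specifically to probe that invariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _kernels
from .boundary_layer import PoreGeometry, pore_conductance
from .energy_balance import (
    ThermalObjectProps,
    environment_arrays,
    stage_grid,
    resolve_conductance,
    steady_state_temperature,
)
from .gs_kinetics import GS_FLOOR, LightSchedule, StomatalKinetics
from .physics import RATIO_WH, STEFAN_BOLTZMANN, AirState
from .signals import EnvironmentTrace, LinearSignal, SmoothedEnvironment, StepSignal, Trace

__all__ = [
    "Protocol",
    "SimulatedExperiment",
    "default_leaf_props",
    "default_black_props",
    "default_white_props",
    "default_kinetics",
    "make_environment",
    "simulate_experiment",
    "simulate_replica",
]


@dataclass(frozen=True)
class Protocol:
    """Experimental schedule and cabinet conditions for a simulation."""

    durations: tuple[float, ...] = (600.0, 3600.0, 3600.0)
    levels: tuple[float, ...] = (0.0, 430.0, 0.0)
    ref_light_scale: float = 300.0 / 430.0
    sw_factor: float = 0.22  # J µmol⁻¹; fixture default for white LEDs
    t_air0: float = 293.15
    dT_air_light: float = 1.0  # slow cabinet warming over the light hour, K
    rh0: float = 0.55
    dRH_light: float = -0.05
    p_atm: float = 101325.0
    wall_temp: float | tuple[tuple[float, float], ...] | None = None
    noise_sd: float = 0.03
    sample_interval: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if len(self.durations) != len(self.levels):
            raise ValueError("durations and levels must have equal length")
        if min(self.durations) <= 0:
            raise ValueError("phase durations must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.sample_interval <= 0:
            raise ValueError("sampling interval must be > 0")

    @property
    def total(self) -> float:
        return float(sum(self.durations))

    @property
    def switch_times(self) -> tuple[float, ...]:
        return tuple(np.cumsum(self.durations)[:-1])

    @property
    def schedule(self) -> LightSchedule:
        return LightSchedule(self.switch_times, self.levels, self.total)

    def _drift_breakpoints(self, base: float, delta: float):
        """Flat in the first phase, linear ramp of ``delta`` over the
        light phase, half-recovery by the end."""
        sw = self.switch_times
        if len(sw) < 2 or delta == 0.0:
            return (0.0, self.total), (base, base)
        t = (0.0, sw[0], sw[1], self.total)
        y = (base, base, base + delta, base + 0.5 * delta)
        return t, y

    def t_air_signal(self) -> LinearSignal:
        t, y = self._drift_breakpoints(self.t_air0, self.dT_air_light)
        return LinearSignal(t, y, "T_air")

    def rh_signal(self) -> LinearSignal:
        t, y = self._drift_breakpoints(self.rh0, self.dRH_light)
        return LinearSignal(t, y, "RH")

    def wall_signal(self) -> LinearSignal:
        if self.wall_temp is None:
            t, y = self._drift_breakpoints(self.t_air0, self.dT_air_light)
        elif isinstance(self.wall_temp, (int, float)):
            t, y = (0.0, self.total), (float(self.wall_temp),) * 2
        else:
            pts = np.asarray(self.wall_temp, dtype=float)
            t, y = pts[:, 0], pts[:, 1]
        return LinearSignal(t, y, "T_wall")

    def exact_environment(self) -> SmoothedEnvironment:
        """Noise-free differentiable environment signals (no smoothing
        step involved; the generator knows the truth)."""
        starts = np.concatenate(([0.0], np.asarray(self.switch_times)))
        knots = np.append(starts, self.total)
        levels = np.append(np.asarray(self.levels, dtype=float),
                           self.levels[-1])
        return SmoothedEnvironment(
            ppfd=StepSignal(knots, levels, "PPFD"),
            t_air=self.t_air_signal(),
            rh=self.rh_signal(),
            p_atm=LinearSignal((0.0, self.total), (self.p_atm, self.p_atm), "P_atm"),
        )


def default_leaf_props(g_bh: float = 0.0143) -> ThermalObjectProps:
    """Fixture wheat-like leaf: these are plausible mid-range values for
    a thin amphistomatous grass leaf, not measured claims."""
    return ThermalObjectProps(alpha=0.70, epsilon=0.96, k=900.0, g_bh=g_bh,
                              transpiring_sides=2, light_scale=1.0)


def default_black_props(protocol: Protocol, g_bh: float = 0.0143) -> ThermalObjectProps:
    """Black-painted aluminium strip (0.95 mm): k = ρ Cp l ≈ 2309 J m⁻² K⁻¹."""
    return ThermalObjectProps(alpha=0.95, epsilon=0.96, k=2309.0, g_bh=g_bh,
                              transpiring_sides=0,
                              light_scale=protocol.ref_light_scale)


def default_white_props(protocol: Protocol, g_bh: float = 0.0143) -> ThermalObjectProps:
    return ThermalObjectProps(alpha=0.30, epsilon=0.92, k=2309.0, g_bh=g_bh,
                              transpiring_sides=0,
                              light_scale=protocol.ref_light_scale)


def default_kinetics() -> StomatalKinetics:
    """Fixture stomatal parameters: dark baseline 0.05, light target
    0.5, final dark 0.025 mol m⁻² s⁻¹; opening twice as fast as closing
    (tau 300 vs 600 s) with 150 s lags."""
    return StomatalKinetics(g1=0.05, g2=0.5, g3=0.025, phi_i=150.0, tau_i=300.0,
                            phi_d=150.0, tau_d=600.0, s_l=0.0)


def make_environment(protocol: Protocol) -> EnvironmentTrace:
    """Environmental drivers sampled on the acquisition grid.

    PPFD is an exact step (samples at a switch time already carry the
    new level); T_air and RH follow the piecewise-linear drift spec;
    pressure is constant.
    """
    t = np.arange(0.0, protocol.total + 0.5 * protocol.sample_interval,
                  protocol.sample_interval)
    starts = np.concatenate(([0.0], np.asarray(protocol.switch_times)))
    phase = np.clip(np.searchsorted(starts, t, side="right") - 1, 0,
                    len(protocol.levels) - 1)
    ppfd = np.asarray(protocol.levels, dtype=float)[phase]
    return EnvironmentTrace(
        t=t,
        ppfd=ppfd,
        t_air=protocol.t_air_signal().value(t),
        rh=protocol.rh_signal().value(t),
        p_atm=np.full_like(t, protocol.p_atm),
    )


@dataclass
class SimulatedExperiment:
    """Traces plus the exact ground truth used to generate them."""

    env: EnvironmentTrace
    traces: dict[str, Trace]
    clean: dict[str, Trace]
    truth: dict[str, Any] = field(default_factory=dict)


def _simulate_object(protocol: Protocol, props: ThermalObjectProps,
                     conductance, dt_sim: float) -> Trace:
    """Integrate one object's full budget on the acquisition grid."""
    env = protocol.exact_environment()
    ts, n = stage_grid(0.0, protocol.total, dt_sim)
    arrs = environment_arrays(env, ts, protocol.sw_factor)
    wall = protocol.wall_signal().value(ts)
    Ld = 2.0 * STEFAN_BOLTZMANN * wall ** 4
    gs_fun = resolve_conductance(conductance)
    gsw = np.maximum(np.asarray(gs_fun(ts), dtype=float), GS_FLOOR)
    air0 = AirState(float(arrs["tair"][0, 0]), protocol.rh0, protocol.p_atm)
    g0 = float(gsw[0, 0]) if props.transpiring_sides else 0.0
    T0 = steady_state_temperature(props, float(arrs["Is"][0, 0]), float(Ld[0, 0]),
                                  air0, g_sw=g0)
    y = _kernels.rk4_full_budget(
        T0, dt_sim, n, arrs["Is"], arrs["tair"], arrs["rho"], arrs["cs"],
        arrs["ea"], arrs["patm"], Ld,
        props.k, props.alpha, props.epsilon, props.g_bh, props.light_scale,
        gsw, props.transpiring_sides, RATIO_WH,
    )
    t_full = np.arange(n + 1) * dt_sim
    m = int(round(protocol.sample_interval / dt_sim))
    if abs(m * dt_sim - protocol.sample_interval) > 1e-9:
        raise ValueError("dt_sim must divide the sampling interval")
    return Trace(t_full[::m], y[::m], channel="T")


def simulate_experiment(protocol: Protocol,
                        leaf_props: ThermalObjectProps | None = None,
                        gs: StomatalKinetics | float | None = None,
                        black_props: ThermalObjectProps | None = None,
                        white_props: ThermalObjectProps | None = None,
                        dt_sim: float = 0.25) -> SimulatedExperiment:
    """Simulate leaf + black/white references under a shared longwave
    environment and add seeded camera noise.

    ``gs`` may be a :class:`StomatalKinetics` (evaluated over the
    protocol's schedule), a fixed conductance (mol m⁻² s⁻¹) or ``None``
    (defaults to the fixture kinetics).
    """
    leaf_props = leaf_props or default_leaf_props()
    black_props = black_props or default_black_props(protocol)
    white_props = white_props or default_white_props(protocol)
    gs = default_kinetics() if gs is None else gs
    conductance = (gs, protocol.schedule) if isinstance(gs, StomatalKinetics) else gs

    clean = {
        "leaf": _simulate_object(protocol, leaf_props, conductance, dt_sim),
        "black": _simulate_object(protocol, black_props, None, dt_sim),
        "white": _simulate_object(protocol, white_props, None, dt_sim),
    }
    rng = np.random.default_rng(protocol.seed)
    traces = {
        name: Trace(tr.t, tr.y + protocol.noise_sd * rng.standard_normal(tr.t.size),
                    channel=f"T_{name}")
        for name, tr in clean.items()
    }
    truth: dict[str, Any] = {
        "seed": protocol.seed,
        "noise_sd": protocol.noise_sd,
        "leaf_props": leaf_props,
        "black_props": black_props,
        "white_props": white_props,
        "gs": gs,
        "T0": {name: float(tr.y[0]) for name, tr in clean.items()},
    }
    return SimulatedExperiment(env=make_environment(protocol), traces=traces,
                               clean=clean, truth=truth)


def simulate_replica(protocol: Protocol, geom: PoreGeometry,
                     plate_props: ThermalObjectProps | None = None,
                     black_props: ThermalObjectProps | None = None,
                     white_props: ThermalObjectProps | None = None,
                     dt_sim: float = 0.25) -> SimulatedExperiment:
    """Simulate the wet and dry leaf replica plus the reference pair.

    The wet replica transpires through one face (the felt side) at the
    constant membrane conductance given by the pore geometry; the dry
    replica is identical with zero latent flux.
    """
    plate_props = plate_props or ThermalObjectProps(
        alpha=0.96, epsilon=0.97, k=2400.0, g_bh=0.0143,
        transpiring_sides=1, light_scale=1.0)
    black_props = black_props or default_black_props(protocol,
                                                     g_bh=plate_props.g_bh)
    white_props = white_props or default_white_props(protocol,
                                                     g_bh=plate_props.g_bh)
    g_pore = pore_conductance(geom, protocol.t_air0, protocol.p_atm)
    dry_props = plate_props.with_(transpiring_sides=0)
    clean = {
        "wet": _simulate_object(protocol, plate_props, g_pore, dt_sim),
        "dry": _simulate_object(protocol, dry_props, None, dt_sim),
        "black": _simulate_object(protocol, black_props, None, dt_sim),
        "white": _simulate_object(protocol, white_props, None, dt_sim),
    }
    rng = np.random.default_rng(protocol.seed)
    traces = {
        name: Trace(tr.t, tr.y + protocol.noise_sd * rng.standard_normal(tr.t.size),
                    channel=f"T_{name}")
        for name, tr in clean.items()
    }
    truth: dict[str, Any] = {
        "seed": protocol.seed,
        "noise_sd": protocol.noise_sd,
        "g_pore": g_pore,
        "geom": geom,
        "plate_props": plate_props,
        "black_props": black_props,
        "white_props": white_props,
        "T0": {name: float(tr.y[0]) for name, tr in clean.items()},
    }
    return SimulatedExperiment(env=make_environment(protocol), traces=traces,
                               clean=clean, truth=truth)
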