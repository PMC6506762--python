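"""Dynamic stomatal-conductance model for step light changes.

After a step change in light, stomatal conductance g_sw relaxes from its
initial value ``g0`` toward a steady-state target ``G`` following a
rescaled Gompertz sigmoid with an initial lag ``phi`` and a time
constant ``tau``; during the light phase a slow linear drift of slope
``s_l`` can be superimposed:

    gs(t) = (G + s_l·t − g0) · S(t) + g0
    S(t)  = [exp(−exp((phi − t)/tau)) − exp(−exp(phi/tau))]
            / [1 − exp(−exp(phi/tau))]

The rescaling ``S`` guarantees gs(0) = g0 exactly even for positive
lags, and gs(∞) = G when s_l = 0. Over a dark/light/dark schedule the
model is applied piecewise: each phase starts from the conductance the
previous phase reached (continuity), targets that phase's steady state
(g1, g2 or g3), and uses the opening parameters (tau_i, phi_i) when the
target lies above the start value and the closing parameters
(tau_d, phi_d) otherwise. Stomata typically open roughly twice as fast
as they close, hence the separate parameter pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StomatalKinetics", "LightSchedule", "gs_sigmoid", "gs_schedule"]

#: floor applied to g_sw before it enters a series-conductance chain,
#: avoiding the 1/g singularity; configurable at call sites.
GS_FLOOR = 1e-6


@dataclass(frozen=True)
class StomatalKinetics:
    """Parameter set of the piecewise sigmoid over dark/light/dark.

    Units: conductances mol m⁻² s⁻¹, lags and time constants s, slope
    ``s_l`` mol m⁻² s⁻². Lags may be ≤ 0; time constants must be > 0.
    """

    g1: float
    g2: float
    g3: float
    phi_i: float
    tau_i: float
    phi_d: float
    tau_d: float
    s_l: float = 0.0

    def __post_init__(self):
        if min(self.g1, self.g2, self.g3) < 0:
            raise ValueError("steady-state targets g1, g2, g3 must be >= 0")
        if self.tau_i <= 0 or self.tau_d <= 0:
            raise ValueError("time constants tau_i, tau_d must be > 0")
        for name in ("phi_i", "phi_d", "s_l"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class LightSchedule:
    """Step light program: phase boundaries and the PPFD level of each.

    ``switch_times`` are the strictly increasing interior boundaries
    between the ``len(switch_times) + 1`` phases; ``levels`` gives the
    PPFD (µmol m⁻² s⁻¹) of every phase. ``t_end`` closes the span.
    """

    switch_times: tuple[float, ...]
    levels: tuple[float, ...]
    t_end: float

    def __post_init__(self):
        st = np.asarray(self.switch_times, dtype=float)
        if st.size and np.any(np.diff(st) <= 0):
            raise ValueError("switch_times must be strictly increasing")
        if len(self.levels) != len(self.switch_times) + 1:
            raise ValueError("need exactly one light level per phase")
        if st.size and st[-1] >= self.t_end:
            raise ValueError("t_end must exceed the last switch time")

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate(([0.0], np.asarray(self.switch_times, dtype=float)))

    @classmethod
    def dark_light_dark(
        cls, dark1: float = 600.0, light: float = 3600.0, dark2: float = 3600.0,
        level: float = 430.0,
    ) -> "LightSchedule":
        """The standard induction protocol: dark, one light step, dark."""
        return cls((dark1, dark1 + light), (0.0, level, 0.0), dark1 + light + dark2)


def gs_sigmoid(t, g0: float, G: float, tau: float, phi: float, s_l: float = 0.0):
    """Evaluate the rescaled Gompertz response at time ``t`` (s ≥ 0).

    ``t`` counts from the step change. Exact endpoints: gs(0) = g0 and,
    for s_l = 0, gs(t) → G as t → ∞.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (time since the step)")
    # clip exp arguments: exp(-exp(x)) underflows harmlessly for x > ~6.5
    z_t = np.exp(np.clip((phi - t) / tau, -745.0, 60.0))
    z_0 = float(np.exp(np.clip(phi / tau, -745.0, 60.0)))
    if z_0 < 1e-300:
        # phi/tau -> -inf limit: the double exponential degenerates to a
        # plain exponential approach, still exactly 0 at t = 0
        scale = -np.expm1(-t / tau)
    elif z_0 > 30.0:
        scale = (np.exp(-z_t) - np.exp(-z_0)) / (1.0 - np.exp(-z_0))
    else:
        # expm1 keeps the scaling exact when exp(phi/tau) is tiny and
        # both exp(-z) terms would round to 1
        scale = np.exp(-z_0) * np.expm1(z_0 - z_t) / (-np.expm1(-z_0))
    return (G + s_l * t - g0) * scale + g0


def _phase_params(params: StomatalKinetics, level: float, phase_index: int,
                  g0: float) -> tuple[float, float, float, float]:
    """Target, tau, phi and slope for one schedule phase."""
    if phase_index == 0:
        target = params.g1
    elif level > 0:
        target = params.g2
    else:
        target = params.g3
    if target >= g0:
        tau, phi = params.tau_i, params.phi_i
    else:
        tau, phi = params.tau_d, params.phi_d
    s_l = params.s_l if level > 0 else 0.0
    return target, tau, phi, s_l


def gs_schedule(t, params: StomatalKinetics, schedule: LightSchedule):
    """Stomatal conductance over a full light schedule, mol m⁻² s⁻¹.

    Piecewise application of :func:`gs_sigmoid` with the start value of
    each phase propagated for continuity. The first phase starts at its
    own steady state (g1 for an initially dark protocol), so the
    baseline is flat. ``t`` may be a scalar or array within
    [0, schedule.t_end].
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0) or np.any(t > schedule.t_end * (1 + 1e-12) + 1e-9):
        raise ValueError("t outside the schedule span")

    starts = schedule.starts
    ends = np.concatenate((starts[1:], [schedule.t_end]))
    out = np.empty_like(t)
    g0 = float(params.g1)  # first phase starts at its own target
    for j, (t0, t1, level) in enumerate(zip(starts, ends, schedule.levels)):
        target, tau, phi, s_l = _phase_params(params, level, j, g0)
        mask = (t >= t0) & (t <= t1) if j == len(starts) - 1 else (t >= t0) & (t < t1)
        if np.any(mask):
            out[mask] = gs_sigmoid(t[mask] - t0, g0, target, tau, phi, s_l)
        # propagate the phase-end value as the next phase's start
        g0 = float(gs_sigmoid(t1 - t0, g0, target, tau, phi, s_l))
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out
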