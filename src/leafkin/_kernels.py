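"""Compiled fixed-step integration kernels.

The Bayesian fit evaluates the energy-balance ODE thousands of times, so
the hot path is a classical RK4 loop compiled with numba over
*pre-tabulated* driver arrays: every time-dependent signal (reference
temperature and its derivative, irradiance, air state, vapour pressure,
stomatal conductance) is evaluated once per step at three stage times
and the loop then only indexes into those arrays.

Step light protocols make several drivers discontinuous at the switch
times (irradiance jumps, and the reference temperature's derivative
jumps with it). To keep full accuracy across a switch that falls on a
grid point, each signal is tabulated as a ``(3, n_steps)`` array holding
its value at ``t_i + ε`` (right limit, used by the first RK4 stage), at
the midpoint ``t_i + dt/2``, and at ``t_{i+1} − ε`` (left limit, used by
the last stage): every step then integrates its own phase's dynamics
exactly and never mixes the two sides of a discontinuity.

With leaf thermal time constants of ~20–50 s a step of 1–3 s keeps the
RK4 truncation error far below camera noise; the adaptive BDF path in
:mod:`leafkin.energy_balance` is the reference implementation and the
two are cross-checked in the test suite. Run at ``dt = 0.01`` s these
kernels double as a brute-force oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_THETA = 5.670374419e-8
_RGAS = 8.31446


@njit(cache=True)
def _es(T):
    tc = T - 273.15
    return 611.21 * np.exp((18.678 - tc / 234.5) * tc / (tc + 257.14))


@njit(cache=True)
def _lam(T):
    return (2.501 - 0.002361 * (T - 273.15)) * 1e6


@njit(cache=True)
def _latent_flux(T, rho, ea, patm, tair, gbh, gsw, sides, ratio_wh):
    """λE (W m⁻²) from the series conductance chain; clamped ≥ 0."""
    if sides == 0 or gsw <= 0.0 or gbh <= 0.0:
        return 0.0
    gbw = sides * ratio_wh * gbh * patm / (_RGAS * tair)
    gtw = 1.0 / (1.0 / gbw + 1.0 / gsw)
    e = 0.622 * rho / patm * (_RGAS * T / patm) * gtw * (_es(T) - ea)
    if e < 0.0:
        e = 0.0
    return _lam(T) * e


@njit(cache=True)
def _diff_rhs(T1, T2, dT2, Is, tair, rho, cs, ea, patm,
              k1, k2, a1, a2, e1, e2, gbh1, gbh2, s1, s2,
              gsw, sides, ratio_wh):
    lat = _latent_flux(T1, rho, ea, patm, tair, gbh1, gsw, sides, ratio_wh)
    return (
        k2 * dT2
        + Is * (s1 * a1 - s2 * a2)
        + 2.0 * _THETA * (e2 * T2 ** 4 - e1 * T1 ** 4)
        + 2.0 * rho * cs * (gbh2 * (T2 - tair) - gbh1 * (T1 - tair))
        - lat
    ) / k1


@njit(cache=True)
def rk4_differenced(T0, dt, n_steps, T2, dT2, Is, tair, rho, cs, ea, patm,
                    k1, k2, a1, a2, e1, e2, gbh1, gbh2, s1, s2,
                    gsw, sides, ratio_wh):
    """Integrate the reference-differenced budget; returns T1 at full steps.

    All signal arrays have shape (3, n_steps): stage-begin, midpoint,
    stage-end values of each step.
    """
    out = np.empty(n_steps + 1)
    T = T0
    out[0] = T
    for i in range(n_steps):
        q1 = _diff_rhs(T, T2[0, i], dT2[0, i], Is[0, i], tair[0, i],
                       rho[0, i], cs[0, i], ea[0, i], patm[0, i],
                       k1, k2, a1, a2, e1, e2, gbh1, gbh2, s1, s2,
                       gsw[0, i], sides, ratio_wh)
        q2 = _diff_rhs(T + 0.5 * dt * q1, T2[1, i], dT2[1, i], Is[1, i],
                       tair[1, i], rho[1, i], cs[1, i], ea[1, i], patm[1, i],
                       k1, k2, a1, a2, e1, e2, gbh1, gbh2, s1, s2,
                       gsw[1, i], sides, ratio_wh)
        q3 = _diff_rhs(T + 0.5 * dt * q2, T2[1, i], dT2[1, i], Is[1, i],
                       tair[1, i], rho[1, i], cs[1, i], ea[1, i], patm[1, i],
                       k1, k2, a1, a2, e1, e2, gbh1, gbh2, s1, s2,
                       gsw[1, i], sides, ratio_wh)
        q4 = _diff_rhs(T + dt * q3, T2[2, i], dT2[2, i], Is[2, i],
                       tair[2, i], rho[2, i], cs[2, i], ea[2, i], patm[2, i],
                       k1, k2, a1, a2, e1, e2, gbh1, gbh2, s1, s2,
                       gsw[2, i], sides, ratio_wh)
        T = T + dt / 6.0 * (q1 + 2.0 * q2 + 2.0 * q3 + q4)
        out[i + 1] = T
    return out


@njit(cache=True)
def _full_rhs(T, Is, tair, rho, cs, ea, patm, Ld,
              k, a, eps, gbh, s, gsw, sides, ratio_wh):
    lat = _latent_flux(T, rho, ea, patm, tair, gbh, gsw, sides, ratio_wh)
    return (
        s * a * Is
        - 2.0 * _THETA * eps * T ** 4
        + Ld
        - 2.0 * gbh * rho * cs * (T - tair)
        - lat
    ) / k


@njit(cache=True)
def rk4_full_budget(T0, dt, n_steps, Is, tair, rho, cs, ea, patm, Ld,
                    k, a, eps, gbh, s, gsw, sides, ratio_wh):
    """Integrate the single-object budget (forward simulation path)."""
    out = np.empty(n_steps + 1)
    T = T0
    out[0] = T
    for i in range(n_steps):
        q1 = _full_rhs(T, Is[0, i], tair[0, i], rho[0, i], cs[0, i],
                       ea[0, i], patm[0, i], Ld[0, i],
                       k, a, eps, gbh, s, gsw[0, i], sides, ratio_wh)
        q2 = _full_rhs(T + 0.5 * dt * q1, Is[1, i], tair[1, i], rho[1, i],
                       cs[1, i], ea[1, i], patm[1, i], Ld[1, i],
                       k, a, eps, gbh, s, gsw[1, i], sides, ratio_wh)
        q3 = _full_rhs(T + 0.5 * dt * q2, Is[1, i], tair[1, i], rho[1, i],
                       cs[1, i], ea[1, i], patm[1, i], Ld[1, i],
                       k, a, eps, gbh, s, gsw[1, i], sides, ratio_wh)
        q4 = _full_rhs(T + dt * q3, Is[2, i], tair[2, i], rho[2, i],
                       cs[2, i], ea[2, i], patm[2, i], Ld[2, i],
                       k, a, eps, gbh, s, gsw[2, i], sides, ratio_wh)
        T = T + dt / 6.0 * (q1 + 2.0 * q2 + 2.0 * q3 + q4)
        out[i + 1] = T
    return out
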