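"""Smooth, differentiable representations of noisy sensor traces.

The differenced energy-balance ODE needs the reference temperature and
each environmental variable as continuous functions of time with
derivatives. Raw thermography and sensor traces are noisy and discretely
sampled (typically every 3 s), so each channel is wrapped in a cubic
smoothing spline whose smoothing parameter is chosen by generalized
cross-validation when not supplied. Irradiance is the exception: a step
light schedule must stay a step, so PPFD uses a zero-order-hold
interpolant instead of a spline.

The *observed* temperature trace used as the fitting target is never
smoothed — the likelihood owns the measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

__all__ = [
    "Trace",
    "SmoothSignal",
    "StepSignal",
    "LinearSignal",
    "PiecewiseSmoothSignal",
    "StepResponseSignal",
    "EnvironmentTrace",
    "SmoothedEnvironment",
    "smooth",
    "average_duplicate_times",
]


def average_duplicate_times(t, y):
    """Collapse duplicated timestamps by averaging their values."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tu, inv = np.unique(t, return_inverse=True)
    if tu.size == t.size:
        return t, y
    sums = np.zeros(tu.size)
    counts = np.zeros(tu.size)
    np.add.at(sums, inv, y)
    np.add.at(counts, inv, 1.0)
    return tu, sums / counts


@dataclass
class Trace:
    """A time-stamped scalar channel (seconds from experiment start).

    Timestamps must be strictly increasing with at least 4 samples and
    no missing values. Use :func:`average_duplicate_times` upstream if
    an instrument emits duplicate timestamps.
    """

    t: np.ndarray
    y: np.ndarray
    channel: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if self.t.size < 4:
            raise ValueError(f"trace '{self.channel}' needs >= 4 samples, got {self.t.size}")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"trace '{self.channel}' timestamps must be strictly increasing")
        if np.any(~np.isfinite(self.y)) or np.any(~np.isfinite(self.t)):
            raise ValueError(f"trace '{self.channel}' contains non-finite values")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])


class SmoothSignal:
    """A smooth function of time with an analytic first derivative.

    Wraps a cubic (smoothing) spline. Evaluation outside the fitted
    domain raises instead of silently extrapolating.
    """

    def __init__(self, spline, domain, residual_sd=np.nan, channel=""):
        self._spl = spline
        self._dspl = spline.derivative(1)
        self.domain = (float(domain[0]), float(domain[1]))
        self.residual_sd = float(residual_sd)
        self.channel = channel

    def _check_domain(self, t):
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        tol = 1e-9 * max(1.0, hi - lo)
        if np.any(t < lo - tol) or np.any(t > hi + tol):
            raise ValueError(
                f"signal '{self.channel}' evaluated outside its domain "
                f"[{lo:.3f}, {hi:.3f}] s (no extrapolation)"
            )
        return np.clip(t, lo, hi)

    def value(self, t):
        return self._spl(self._check_domain(t))

    def derivative(self, t):
        return self._dspl(self._check_domain(t))

    __call__ = value


class StepSignal:
    """Zero-order-hold interpolant: piecewise constant, zero derivative.

    Used for channels that are step functions by construction (light
    schedules); a spline would ring at the switches.
    """

    def __init__(self, t, y, channel=""):
        self._t = np.asarray(t, dtype=float)
        self._y = np.asarray(y, dtype=float)
        self.domain = (float(self._t[0]), float(self._t[-1]))
        self.residual_sd = 0.0
        self.channel = channel

    def _check_domain(self, t):
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        tol = 1e-9 * max(1.0, hi - lo)
        if np.any(t < lo - tol) or np.any(t > hi + tol):
            raise ValueError(
                f"signal '{self.channel}' evaluated outside its domain "
                f"[{lo:.3f}, {hi:.3f}] s (no extrapolation)"
            )
        return np.clip(t, lo, hi)

    def value(self, t):
        t = self._check_domain(t)
        idx = np.clip(np.searchsorted(self._t, t, side="right") - 1, 0, self._t.size - 1)
        return self._y[idx]

    def derivative(self, t):
        t = self._check_domain(t)
        return np.zeros_like(np.asarray(t, dtype=float))

    __call__ = value


class LinearSignal:
    """Piecewise-linear interpolant with its (piecewise-constant)
    derivative; exact representation of drift specifications."""

    def __init__(self, t, y, channel=""):
        self._t = np.asarray(t, dtype=float)
        self._y = np.broadcast_to(np.asarray(y, dtype=float), self._t.shape).astype(float)
        self.domain = (float(self._t[0]), float(self._t[-1]))
        self.residual_sd = 0.0
        self.channel = channel
        with np.errstate(invalid="ignore"):
            self._slopes = np.diff(self._y) / np.diff(self._t)

    def _check_domain(self, t):
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        tol = 1e-9 * max(1.0, hi - lo)
        if np.any(t < lo - tol) or np.any(t > hi + tol):
            raise ValueError(
                f"signal '{self.channel}' evaluated outside its domain "
                f"[{lo:.3f}, {hi:.3f}] s (no extrapolation)"
            )
        return np.clip(t, lo, hi)

    def value(self, t):
        return np.interp(self._check_domain(t), self._t, self._y)

    def derivative(self, t):
        t = self._check_domain(t)
        idx = np.clip(np.searchsorted(self._t, t, side="right") - 1, 0,
                      self._slopes.size - 1)
        return self._slopes[idx]

    __call__ = value


def smooth(trace: Trace, smoothing: float | None = None) -> SmoothSignal:
    """Fit a cubic smoothing spline to a trace.

    Parameters
    ----------
    trace
        Input samples on their native (irregular) timestamps.
    smoothing
        Non-negative roughness penalty ``lam``. ``None`` (default)
        selects it by generalized cross-validation; ``0`` interpolates.

    Returns
    -------
    SmoothSignal
        Value/derivative over the trace's time span; ``residual_sd``
        reports the standard deviation of the fit residuals.
    """
    if smoothing is not None and smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    t, y = trace.t, trace.y
    if smoothing == 0 or t.size < 5:
        # exact cubic interpolation; GCV needs a few more points anyway
        spl = CubicSpline(t, y)
        resid_sd = 0.0
    else:
        spl = make_smoothing_spline(t, y, lam=smoothing)
        resid = y - spl(t)
        resid_sd = float(np.std(resid))
    return SmoothSignal(spl, (t[0], t[-1]), resid_sd, trace.channel)


class PiecewiseSmoothSignal:
    """Independent smoothing splines per protocol phase.

    A temperature trace under a step light protocol has genuine slope
    discontinuities at the switch times; a single spline rounds those
    corners and biases the derivative exactly where the kinetics are
    most informative. Given the (known) switch times, each phase is
    smoothed separately and the corner is preserved. At a switch time
    the right-hand (new-phase) branch is used, matching the
    zero-order-hold convention for the light signal.
    """

    def __init__(self, trace: Trace, breaks, smoothing: float | None = None):
        t, y = trace.t, trace.y
        breaks = [b for b in np.atleast_1d(np.asarray(breaks, dtype=float))
                  if t[0] < b < t[-1]]
        edges = np.concatenate(([t[0]], breaks, [t[-1]]))
        self._edges = edges
        self._segments = []
        resid = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (t >= lo - 1e-9) & (t <= hi + 1e-9)
            if m.sum() < 4:
                raise ValueError("each phase needs >= 4 samples to smooth")
            seg = smooth(Trace(t[m], y[m], trace.channel), smoothing)
            self._segments.append(seg)
            resid.append(seg.residual_sd)
        self.domain = (float(t[0]), float(t[-1]))
        self.residual_sd = float(np.mean(resid))
        self.channel = trace.channel

    def _segment_index(self, t):
        return np.clip(np.searchsorted(self._edges, t, side="right") - 1, 0,
                       len(self._segments) - 1)

    def _dispatch(self, t, attr):
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        tol = 1e-9 * max(1.0, hi - lo)
        if np.any(t < lo - tol) or np.any(t > hi + tol):
            raise ValueError(
                f"signal '{self.channel}' evaluated outside its domain "
                f"[{lo:.3f}, {hi:.3f}] s (no extrapolation)"
            )
        t = np.clip(t, lo, hi)
        idx = self._segment_index(t)
        out = np.empty_like(np.atleast_1d(t))
        t1 = np.atleast_1d(t)
        i1 = np.atleast_1d(idx)
        for j, seg in enumerate(self._segments):
            m = i1 == j
            if np.any(m):
                out[m] = getattr(seg, attr)(t1[m])
        return out.reshape(np.shape(t)) if np.ndim(t) else float(out[0])

    def value(self, t):
        return self._dispatch(t, "value")

    def derivative(self, t):
        return self._dispatch(t, "derivative")

    __call__ = value


class StepResponseSignal:
    """Physics-guided smoother for reference kinetics under a step
    protocol.

    Within each phase a passive reference is, to first order, a linear
    first-order system: its temperature follows
    ``a + b·t + c·exp(-t/τ)`` (exponential relaxation to the new
    radiative load plus the slow cabinet drift). That backbone is
    fitted per phase, and only the *residual* is given to a heavily
    penalized spline to absorb what the linearization misses. Compared
    with a generic GCV spline this transmits several times less of the
    camera noise into values and an order of magnitude less into
    derivatives — which matters because reference noise leaks into the
    differenced prediction scaled by k_ref/k_leaf.

    ``resid_smoothing`` is the roughness penalty of the residual
    spline (default 1e6, appropriate for a 3 s cadence); the fallback
    for a phase whose backbone fit fails is a plain GCV spline.
    """

    def __init__(self, trace: Trace, breaks, resid_smoothing: float = 1e6):
        from scipy.optimize import curve_fit

        t, y = trace.t, trace.y
        breaks = [b for b in np.atleast_1d(np.asarray(breaks, dtype=float))
                  if t[0] < b < t[-1]]
        edges = np.concatenate(([t[0]], breaks, [t[-1]]))
        self._edges = edges
        self._segments = []
        resid_sds = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (t >= lo - 1e-9) & (t <= hi + 1e-9)
            ts = t[m] - t[m][0]
            ys = y[m]
            if ts.size < 8:
                raise ValueError("each phase needs >= 8 samples")
            span = float(ys.max() - ys.min()) + 1.0
            try:
                popt, pcov = curve_fit(
                    self._backbone, ts, ys,
                    p0=[ys[-1], 0.0, ys[0] - ys[-1], 60.0],
                    bounds=([ys.min() - 10.0, -0.05, -3 * span, 3.0],
                            [ys.max() + 10.0, 0.05, 3 * span, 5e3]),
                    maxfev=20000)
            except (RuntimeError, ValueError):
                popt = pcov = None
            if popt is None:
                spl = make_smoothing_spline(ts, ys, lam=None)
                resid = ys - spl(ts)
                self._segments.append((float(t[m][0]), None, None, spl))
            else:
                resid = ys - self._backbone(ts, *popt)
                spl = make_smoothing_spline(ts, resid, lam=resid_smoothing)
                resid = resid - spl(ts)
                self._segments.append((float(t[m][0]), popt, pcov, spl))
            resid_sds.append(float(np.std(resid)))
        self.domain = (float(t[0]), float(t[-1]))
        self.residual_sd = float(np.mean(resid_sds))
        self.channel = trace.channel
        self._dsplines = [seg[3].derivative(1) for seg in self._segments]

    @staticmethod
    def _backbone(t, a, b, c, tau):
        return a + b * t + c * np.exp(-t / tau)

    @staticmethod
    def _backbone_deriv(t, a, b, c, tau):
        return b - c / tau * np.exp(-t / tau)

    def _check_domain(self, t):
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        tol = 1e-9 * max(1.0, hi - lo)
        if np.any(t < lo - tol) or np.any(t > hi + tol):
            raise ValueError(
                f"signal '{self.channel}' evaluated outside its domain "
                f"[{lo:.3f}, {hi:.3f}] s (no extrapolation)"
            )
        return np.clip(t, lo, hi)

    def _dispatch(self, t, want_derivative):
        t = self._check_domain(t)
        t1 = np.atleast_1d(t)
        idx = np.clip(np.searchsorted(self._edges, t1, side="right") - 1, 0,
                      len(self._segments) - 1)
        out = np.empty_like(t1)
        for j, (t0, popt, _pcov, spl) in enumerate(self._segments):
            m = idx == j
            if not np.any(m):
                continue
            ts = t1[m] - t0
            if want_derivative:
                v = self._dsplines[j](ts)
                if popt is not None:
                    v = v + self._backbone_deriv(ts, *popt)
            else:
                v = spl(ts)
                if popt is not None:
                    v = v + self._backbone(ts, *popt)
            out[m] = v
        return out.reshape(np.shape(t)) if np.ndim(t) else float(out[0])

    def coefficient_modes(self, t):
        """1-SD perturbation modes of the fitted backbone on grid ``t``.

        Eigen-directions of each phase's coefficient covariance,
        scaled to one standard deviation, returned as (values,
        derivatives) arrays of shape (n_modes, *t.shape). These are
        the dominant uncertainty of the de-noised reference and can be
        marginalized over in a fit.
        """
        t = self._check_domain(t)
        t1 = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.clip(np.searchsorted(self._edges, t1, side="right") - 1, 0,
                      len(self._segments) - 1)
        vals, ders = [], []
        for j, (t0, popt, pcov, _spl) in enumerate(self._segments):
            if popt is None or pcov is None or not np.all(np.isfinite(pcov)):
                continue
            m = idx == j
            if not np.any(m):
                continue
            ts = t1[m] - t0
            a, b, c, tau = popt
            ex = np.exp(-ts / tau)
            # jacobians of value and derivative w.r.t. (a, b, c, tau)
            jv = np.stack([np.ones_like(ts), ts, ex, c * ts / tau ** 2 * ex])
            jd = np.stack([np.zeros_like(ts), np.ones_like(ts), -ex / tau,
                           c / tau ** 2 * ex * (1.0 - ts / tau)])
            w, V = np.linalg.eigh(0.5 * (pcov + pcov.T))
            for wi, vi in zip(w, V.T):
                if wi <= 0:
                    continue
                dv = np.zeros(t1.shape)
                dd = np.zeros(t1.shape)
                dv[m] = np.sqrt(wi) * (vi @ jv)
                dd[m] = np.sqrt(wi) * (vi @ jd)
                vals.append(dv)
                ders.append(dd)
        if not vals:
            return (np.zeros((0,) + t1.shape), np.zeros((0,) + t1.shape))
        return (np.stack(vals).reshape((-1,) + np.shape(t)),
                np.stack(ders).reshape((-1,) + np.shape(t)))

    def value(self, t):
        return self._dispatch(t, False)

    def derivative(self, t):
        return self._dispatch(t, True)

    __call__ = value


@dataclass
class EnvironmentTrace:
    """Synchronized environmental drivers on a common time base.

    ``ppfd`` in µmol m⁻² s⁻¹, ``t_air`` in kelvin, ``rh`` as a fraction,
    ``p_atm`` in Pa.
    """

    t: np.ndarray
    ppfd: np.ndarray
    t_air: np.ndarray
    rh: np.ndarray
    p_atm: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for name in ("ppfd", "t_air", "rh", "p_atm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                arr = np.broadcast_to(arr, self.t.shape).astype(float)
            setattr(self, name, arr)
        if self.t.size < 4:
            raise ValueError("environment trace needs >= 4 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("environment timestamps must be strictly increasing")

    def smoothed(self, smoothing: float | None = None) -> "SmoothedEnvironment":
        """Smooth the slowly drifting channels; hold PPFD as a step."""
        return SmoothedEnvironment(
            ppfd=StepSignal(self.t, self.ppfd, "PPFD"),
            t_air=smooth(Trace(self.t, self.t_air, "T_air"), smoothing),
            rh=smooth(Trace(self.t, self.rh, "RH"), smoothing),
            p_atm=smooth(Trace(self.t, self.p_atm, "P_atm"), smoothing),
        )


@dataclass
class SmoothedEnvironment:
    """Differentiable view of an :class:`EnvironmentTrace`."""

    ppfd: StepSignal
    t_air: SmoothSignal
    rh: SmoothSignal
    p_atm: SmoothSignal

    @property
    def domain(self) -> tuple[float, float]:
        lo = max(s.domain[0] for s in (self.ppfd, self.t_air, self.rh, self.p_atm))
        hi = min(s.domain[1] for s in (self.ppfd, self.t_air, self.rh, self.p_atm))
        return lo, hi
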