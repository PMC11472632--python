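"""Half-life kinetics fitting of whole-cell current segments.

Activation and deactivation of the photoswitch-gated current are fitted
with mono-exponential half-life functions, sustained-illumination
inactivation with a bi-exponential, all by unconstrained Nelder-Mead
simplex minimisation of the summed square of residuals (SSE):

    rising:    f(t) = a * exp(+ln2 * t / tau_H) + c
    decaying:  f(t) = a * exp(-ln2 * t / tau_H) + c
    biphasic:  f(t) = a1 * exp(-ln2 * t / tau_H1)
                    + a2 * exp(-ln2 * t / tau_H2) + c

tau_H is a half-life: the fitted component doubles (rising) or halves
(decaying) every tau_H seconds.  Before fitting, each segment is normalised
to a dimensionless signal and its time axis shifted to start at zero:

* activation — the median current before the UV onset maps to 0 and 30% of
  the maximal activated current to +1; the fit window ends at the +1
  crossing so the emerging inactivation does not bias the rise.
* deactivation — the median before the blue onset maps to +1, the median of
  the fully deactivated tail to 0.
* inactivation — the peak current maps to +1, the median of the steady
  state late in the sustained UV period to 0.

Fits run on the current magnitude; inward (negative) currents are the
default and outward deflections are handled by a direction flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import minimize

from .recordings import LightEvent, Trace

LN2 = math.log(2.0)


class FitError(ValueError):
    """A segment cannot be prepared or fitted."""


@dataclass(frozen=True)
class FitOptions:
    """Simplex-optimiser settings and per-kind start points.

    Tolerances mirror the reference routine's joint criterion: convergence
    requires both the simplex spread (tol_x) and the SSE spread (tol_fun)
    to be satisfied; otherwise the iteration/evaluation caps end the search
    with ``converged=False``.

    Start-point half-lives are stored in seconds.  The canonical start
    values (activation tau 1, deactivation tau 7, inactivation 0.02 / 3.8)
    are interpreted on each kind's natural time scale — milliseconds for
    activation/deactivation, whose observed half-lives are 5-200 ms, and
    seconds for inactivation (0.3-190 s).  Second-scale activation and
    deactivation starts sit so far from the data that the simplex falls
    into a flat large-tau valley.
    """

    max_fun_evals: int = 5000
    max_iter: int = 10000
    tol_x: float = 1e-10
    tol_fun: float = 1e-6
    init_activation: tuple = (0.01, 1e-3, 0.01)  # a, tau_H (1 ms), c
    init_deactivation: tuple = (0.7, 7e-3, 0.1)  # a, tau_H (7 ms), c
    init_inactivation: tuple = (1.0, 0.02, 1.0, 3.8, 0.1)  # a1, tau1, a2, tau2, c
    indistinct_tau_ratio: float = 3.0

    def __post_init__(self) -> None:
        if self.tol_x <= 0 or self.tol_fun <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_fun_evals < 1 or self.max_iter < 1:
            raise ValueError("iteration caps must be >= 1")


@dataclass
class NormalizedSegment:
    """Zero-shifted, dimensionless segment prepared for fitting."""

    t: np.ndarray  # seconds, t[0] == 0, strictly increasing
    y: np.ndarray
    kind: str  # activation / deactivation / inactivation / custom
    normalization: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.y = np.asarray(self.y, float)
        if self.t.size != self.y.size or self.t.size == 0:
            raise ValueError("t and y must be non-empty and equal length")
        if self.t[0] != 0.0 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must start at 0 and be strictly increasing")


@dataclass
class MonoFit:
    a: float
    tau_half: float  # seconds (minutes for thermal relaxation fits)
    c: float
    sse: float
    n_evals: int
    converged: bool
    direction: str  # "rising" or "decaying"
    flags: list = field(default_factory=list)

    def model(self, t) -> np.ndarray:
        sign = 1.0 if self.direction == "rising" else -1.0
        return self.a * np.exp(sign * LN2 * np.asarray(t) / self.tau_half) + self.c


@dataclass
class BiFit:
    a1: float
    tau_half_fast: float
    a2: float
    tau_half_slow: float
    c: float
    sse: float
    n_evals: int
    converged: bool
    flags: list = field(default_factory=list)

    def model(self, t) -> np.ndarray:
        t = np.asarray(t)
        return (
            self.a1 * np.exp(-LN2 * t / self.tau_half_fast)
            + self.a2 * np.exp(-LN2 * t / self.tau_half_slow)
            + self.c
        )


# ---------------------------------------------------------------------------
# segment preparation
# ---------------------------------------------------------------------------


def _magnitude(trace: Trace, direction: str) -> np.ndarray:
    """Signed current mapped so channel opening increases the magnitude."""
    if direction == "inward":
        return -trace.current_pA
    if direction == "outward":
        return trace.current_pA.copy()
    raise ValueError("direction must be 'inward' or 'outward'")


def _event_times(trace: Trace, schedule: Sequence[LightEvent], kind: str) -> list[float]:
    """Trace-relative onset times of events of the given wavelength class."""
    out = []
    for ev in schedule:
        rel = ev.time_s - trace.t0_s
        if -1e-12 <= rel <= trace.duration_s and ev.kind == kind:
            out.append(max(rel, 0.0))
    return out


def _smooth(m: np.ndarray, size: int) -> np.ndarray:
    if size <= 1:
        return m
    return median_filter(m, size=size, mode="nearest")


def prepare_activation(
    trace: Trace,
    schedule: Sequence[LightEvent],
    fraction: float = 0.30,
    baseline_window_s: float = 1.0,
    smooth_samples: int = 11,
    direction: str = "inward",
    noise_k: float = 5.0,
) -> NormalizedSegment:
    """Normalise the light-on rise: baseline -> 0, ``fraction`` of peak -> +1.

    The fit window runs from the UV onset to the first sample at or above
    +1, which excludes the interfering inactivation that follows the peak.
    """
    if not 0.2 <= fraction <= 0.5:
        raise ValueError("fraction must lie in [0.2, 0.5]")
    uv_times = _event_times(trace, schedule, "uv")
    if not uv_times:
        raise FitError("no UV onset within the trace")
    t_uv = uv_times[0]
    t = trace.times()
    m = _magnitude(trace, direction)
    i_on = int(np.searchsorted(t, t_uv - 1e-12))
    base_mask = (t >= t_uv - baseline_window_s) & (t < t_uv)
    if not np.any(base_mask):
        raise FitError("no samples in the pre-UV baseline window")
    baseline = float(np.median(m[base_mask]))
    noise_sd = float(np.std(m[base_mask]))
    m = m - baseline

    sm = _smooth(m, smooth_samples)
    post = sm[i_on:]
    if post.size < 3:
        raise FitError("trace ends at the UV onset")
    m_pk = float(np.max(post))
    if m_pk <= noise_k * noise_sd or m_pk <= 0.0:
        raise FitError("no activation detected above the baseline noise")
    divisor = fraction * m_pk
    y_full = m[i_on:] / divisor
    above = np.nonzero(y_full >= 1.0)[0]
    i_end = int(above[0]) if above.size else y_full.size - 1
    if i_end < 2:
        raise FitError("activation rise spans fewer than 3 samples")
    t_seg = t[i_on : i_on + i_end + 1]
    return NormalizedSegment(
        t=t_seg - t_seg[0],
        y=y_full[: i_end + 1],
        kind="activation",
        normalization={
            "baseline_pA": baseline,
            "peak_pA": m_pk,
            "divisor_pA": divisor,
            "window_s": (float(t_seg[0]), float(t_seg[-1])),
        },
    )


def prepare_deactivation(
    trace: Trace,
    schedule: Sequence[LightEvent],
    pre_window_s: float = 1.0,
    tail_fraction: float = 0.1,
    direction: str = "inward",
) -> NormalizedSegment:
    """Normalise the light-off decay: pre-blue median -> +1, settled tail -> 0."""
    uv_times = _event_times(trace, schedule, "uv")
    blue_times = [
        tb for tb in _event_times(trace, schedule, "blue") if uv_times and tb > uv_times[0]
    ]
    if not blue_times:
        raise FitError("no blue onset after UV within the trace")
    t_b = blue_times[0]
    t = trace.times()
    m = _magnitude(trace, direction)
    i_off = int(np.searchsorted(t, t_b - 1e-12))
    pre_mask = (t >= t_b - pre_window_s) & (t < t_b)
    if not np.any(pre_mask):
        raise FitError("no samples in the pre-deactivation window")
    m_pre = float(np.median(m[pre_mask]))
    seg = m[i_off:]
    if seg.size < 3:
        raise FitError("trace ends at the blue onset")
    n_tail = max(1, int(round(tail_fraction * seg.size)))
    m_end = float(np.median(seg[-n_tail:]))
    amp = m_pre - m_end
    noise_sd = float(np.std(m[pre_mask]))
    if abs(amp) <= max(2.0 * noise_sd, 1e-12):
        raise FitError("no deactivation amplitude")
    y = (seg - m_end) / amp
    t_seg = t[i_off:]
    return NormalizedSegment(
        t=t_seg - t_seg[0],
        y=y,
        kind="deactivation",
        normalization={
            "pre_median_pA": m_pre,
            "end_median_pA": m_end,
            "divisor_pA": amp,
            "window_s": (float(t_seg[0]), float(t_seg[-1])),
        },
    )


def prepare_inactivation(
    trace: Trace,
    schedule: Sequence[LightEvent],
    steady_fraction: float = 0.1,
    smooth_samples: int = 11,
    direction: str = "inward",
    min_uv_multiple_of_tau2: float = 5.0,
    tau2_guess_s: float = 3.8,
) -> NormalizedSegment:
    """Normalise the sustained-UV decline: peak -> +1, steady state -> 0.

    The steady-state level is the median of the last ``steady_fraction`` of
    the UV period; the window runs from the peak to the end of the UV
    period.  A too-short UV period is flagged, not rejected.
    """
    uv_times = _event_times(trace, schedule, "uv")
    if not uv_times:
        raise FitError("no UV onset within the trace")
    t_u = uv_times[0]
    blue_after = [tb for tb in _event_times(trace, schedule, "blue") if tb > t_u]
    t_end = blue_after[0] if blue_after else trace.duration_s
    t = trace.times()
    m = _magnitude(trace, direction)
    i_on = int(np.searchsorted(t, t_u - 1e-12))
    i_end = int(np.searchsorted(t, t_end - 1e-12))
    uv_span = t_end - t_u
    if i_end - i_on < 5:
        raise FitError("UV period too short")
    sm = _smooth(m, smooth_samples)
    i_pk = i_on + int(np.argmax(sm[i_on:i_end]))
    if i_end - i_pk < 3:
        raise FitError("UV light switched off before the current peak")
    flags = []
    if uv_span < min_uv_multiple_of_tau2 * tau2_guess_s:
        flags.append("uv_period_short_for_steady_state")
    n_ss = max(1, int(round(steady_fraction * (i_end - i_on))))
    m_ss = float(np.median(m[i_end - n_ss : i_end]))
    m_pk = float(m[i_pk])
    amp = m_pk - m_ss
    if amp <= 0:
        raise FitError("no inactivation amplitude")
    y = (m[i_pk:i_end] - m_ss) / amp
    t_seg = t[i_pk:i_end]
    return NormalizedSegment(
        t=t_seg - t_seg[0],
        y=y,
        kind="inactivation",
        normalization={
            "peak_pA": m_pk,
            "steady_state_pA": m_ss,
            "divisor_pA": amp,
            "window_s": (float(t_seg[0]), float(t_seg[-1])),
        },
        flags=flags,
    )


# ---------------------------------------------------------------------------
# simplex fitting
# ---------------------------------------------------------------------------

_EXP_CLIP = 700.0  # exp argument beyond which the model is treated as huge


def _mono_sse(x: np.ndarray, t: np.ndarray, y: np.ndarray, sign: float) -> float:
    a, tau, c = x
    if tau == 0.0:
        return np.inf
    # positive exponents are clipped so a runaway simplex vertex yields a
    # large finite penalty instead of an overflow
    arg = np.minimum(sign * LN2 * t / tau, _EXP_CLIP)
    r = a * np.exp(arg) + c - y
    return float(r @ r)


def _bi_sse(x: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    a1, tau1, a2, tau2, c = x
    if tau1 == 0.0 or tau2 == 0.0:
        return np.inf
    arg1 = np.minimum(-LN2 * t / tau1, _EXP_CLIP)
    arg2 = np.minimum(-LN2 * t / tau2, _EXP_CLIP)
    r = a1 * np.exp(arg1) + a2 * np.exp(arg2) + c - y
    return float(r @ r)


def _simplex(fun, x0, options: FitOptions):
    with np.errstate(over="ignore", invalid="ignore"):
        return minimize(
            fun,
            np.asarray(x0, float),
            method="Nelder-Mead",
            options={
                "maxfev": options.max_fun_evals,
                "maxiter": options.max_iter,
                "xatol": options.tol_x,
                "fatol": options.tol_fun,
            },
        )


def _tau_degenerate(tau: float, t: np.ndarray) -> bool:
    """Half-life far off the segment's own time scale (runaway simplex)."""
    span = float(t[-1])
    dt = span / max(t.size - 1, 1)
    return not (0.01 * dt <= abs(tau) <= 100.0 * span)


def fit_mono(
    segment: NormalizedSegment,
    direction: str | None = None,
    options: FitOptions | None = None,
    initial: tuple | None = None,
) -> MonoFit:
    """Nelder-Mead mono-exponential half-life fit of a prepared segment.

    ``direction`` defaults from the segment kind (activation -> rising,
    otherwise decaying).  The search is unconstrained; a sign-flipped
    half-life is reflected to positive and flagged.
    """
    options = options or FitOptions()
    if direction is None:
        direction = "rising" if segment.kind == "activation" else "decaying"
    if direction not in ("rising", "decaying"):
        raise ValueError("direction must be 'rising' or 'decaying'")
    sign = 1.0 if direction == "rising" else -1.0
    if initial is None:
        initial = (
            options.init_activation if direction == "rising" else options.init_deactivation
        )
    fun = lambda x: _mono_sse(x, segment.t, segment.y, sign)
    res = _simplex(fun, initial, options)
    flags = list(segment.flags)
    if _tau_degenerate(res.x[1], segment.t):
        # the fixed start point lost the segment's time scale; restart the
        # simplex from a data-driven guess and keep the better SSE
        span = float(segment.t[-1])
        y0, y1 = float(segment.y[0]), float(segment.y[-1])
        if sign > 0:
            x1 = ((y1 - y0) / 3.0, span / 2.0, y0)
        else:
            x1 = (y0 - y1, span / 4.0, y1)
        res2 = _simplex(fun, x1, options)
        if res2.fun < res.fun:
            res = res2
        flags.append("restarted_from_data_scale")
    a, tau, c = res.x
    if tau < 0:
        tau = -tau
        flags.append("tau_sign_flipped")
    return MonoFit(
        a=float(a),
        tau_half=float(tau),
        c=float(c),
        sse=float(res.fun),
        n_evals=int(res.nfev),
        converged=bool(res.success),
        direction=direction,
        flags=flags,
    )


def fit_bi(
    segment: NormalizedSegment,
    options: FitOptions | None = None,
    initial: tuple | None = None,
) -> BiFit:
    """Nelder-Mead bi-exponential fit; output ordered fast <= slow.

    Nearly equal half-lives (ratio below ``options.indistinct_tau_ratio``)
    are flagged as indistinct but still reported.
    """
    options = options or FitOptions()
    if initial is None:
        initial = options.init_inactivation
    fun = lambda x: _bi_sse(x, segment.t, segment.y)
    res = _simplex(fun, initial, options)
    flags = list(segment.flags)
    if _tau_degenerate(res.x[1], segment.t) or _tau_degenerate(res.x[3], segment.t):
        span = float(segment.t[-1])
        y0, y1 = float(segment.y[0]), float(segment.y[-1])
        x1 = ((y0 - y1) / 2.0, span / 50.0, (y0 - y1) / 2.0, span / 5.0, y1)
        res2 = _simplex(fun, x1, options)
        if res2.fun < res.fun:
            res = res2
        flags.append("restarted_from_data_scale")
    a1, tau1, a2, tau2, c = res.x
    if tau1 < 0 or tau2 < 0:
        tau1, tau2 = abs(tau1), abs(tau2)
        flags.append("tau_sign_flipped")
    if tau1 > tau2:
        a1, a2 = a2, a1
        tau1, tau2 = tau2, tau1
    if tau1 > 0 and tau2 / tau1 < options.indistinct_tau_ratio:
        flags.append("components_indistinct")
    return BiFit(
        a1=float(a1),
        tau_half_fast=float(tau1),
        a2=float(a2),
        tau_half_slow=float(tau2),
        c=float(c),
        sse=float(res.fun),
        n_evals=int(res.nfev),
        converged=bool(res.success),
        flags=flags,
    )


def fit_thermal_relaxation(
    t_min: np.ndarray,
    absorbance: np.ndarray,
    options: FitOptions | None = None,
) -> MonoFit:
    """Half-life of the thermal cis->trans absorbance return, in minutes.

    The late-time absorbance estimates the relaxed (trans) level; the gap to
    it decays mono-exponentially and is fitted with a data-driven start
    point (amplitude from the first sample, half-life a quarter of the
    span).  ``tau_half`` of the returned fit is in minutes.
    """
    t_min = np.asarray(t_min, float)
    absorbance = np.asarray(absorbance, float)
    if t_min.size != absorbance.size or t_min.size < 5:
        raise FitError("need matching t/absorbance arrays with >= 5 points")
    n_tail = max(1, t_min.size // 10)
    A_inf = float(np.median(absorbance[-n_tail:]))
    y = A_inf - absorbance
    scale = max(abs(A_inf), float(np.max(np.abs(absorbance))), 1e-30)
    if float(np.max(np.abs(y))) <= 1e-9 * scale:
        raise FitError("no relaxation amplitude")
    seg = NormalizedSegment(t=t_min - t_min[0], y=y, kind="thermal")
    span = float(seg.t[-1]) or 1.0
    return fit_mono(
        seg,
        direction="decaying",
        options=options,
        initial=(float(y[0]), span / 4.0, 0.0),
    )


def estimate_pss_from_absorbance(
    A_dark: float, A_pss: float, eps: float = 0.02
) -> tuple[float, float]:
    """Photostationary state from band-maximum absorbances.

    Assumes the cis isomer contributes negligibly at the trans band maximum,
    so the PSS-to-dark absorbance ratio is directly the trans fraction.
    Returns ``(percent_trans, percent_cis)``.
    """
    if A_dark <= 0:
        raise ValueError("dark-adapted absorbance must be > 0")
    if A_pss < 0 or A_pss > A_dark * (1.0 + eps):
        raise ValueError("PSS absorbance outside [0, A_dark * (1 + eps)]")
    pct_trans = 100.0 * min(A_pss / A_dark, 1.0)
    return pct_trans, 100.0 - pct_trans
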