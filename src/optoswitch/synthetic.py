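"""Seeded generator of synthetic whole-cell recordings.

The generator emulates the statistical structure the analysis stages assume:
photoswitch-driven gating of a cation-channel population observed as
whole-cell current at a constant holding potential or through repetitive
voltage ramps, plus UV-vis absorbance relaxation time courses for the
thermal cis->trans return of the photoswitch.

The gating model is phenomenological.  On UV onset the open fraction g(t)
rises along an accelerating exponential ``a * (2**(dt/tau_act) - 1)`` and is
capped at 1; under sustained UV it then decays biphasically (fast + slow
half-lives) toward a residual plateau; on blue onset it deactivates to zero
with a single half-life.  These are exactly the functional forms the fit
routine assumes, so noiseless generator output is an exact-recovery oracle
for the fitting stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .recordings import (
    LightEvent,
    RampProtocol,
    Recording,
    Trace,
    ramp_voltage_at,
    validate_schedule,
)

LN2 = math.log(2.0)

# span of the accelerating rise before the cap is hit, in units of tau_act;
# 3.33 tau puts the 30%-of-peak point well inside the rise segment
DEFAULT_RISE_SPAN = 3.33


@dataclass(frozen=True)
class GatingParams:
    """Half-life parameters of the photoswitch-driven gating model.

    All half-lives in seconds.  ``frac_fast`` is the amplitude share of the
    fast inactivation component; ``residual_c`` the non-inactivating plateau
    of the open fraction.  ``peak_cd_pApF`` is the current density at the
    +100 mV reference potential when g = 1.
    """

    tau_act_s: float = 0.0058
    tau_deact_s: float = 0.0084
    tau_inact_fast_s: float = 0.3
    tau_inact_slow_s: float = 13.1
    frac_fast: float = 0.5
    residual_c: float = 0.0
    peak_cd_pApF: float = 100.0
    baseline_cd_pApF: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_act_s", "tau_deact_s", "tau_inact_fast_s", "tau_inact_slow_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.tau_inact_fast_s < self.tau_inact_slow_s:
            raise ValueError("tau_inact_fast_s must be < tau_inact_slow_s")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise ValueError("frac_fast must be in [0, 1]")
        if not 0.0 <= self.residual_c < 1.0:
            raise ValueError("residual_c must be in [0, 1)")


@dataclass(frozen=True)
class IVTemplate:
    """Relative current-density-voltage shape.

    Monotone-cubic interpolation through control points per branch, anchored
    at (-100, inward), (0, 0) and (+100, outward).  Evaluation is rescaled so
    the value at +100 mV is 1; the inward/outward magnitude ratio is set by
    the control points (``rectification`` = |d(+100)| / |d(-100)|).
    """

    points_mV: tuple = (-100.0, -50.0, 0.0, 50.0, 100.0)
    points_rel: tuple = (-1.0, -0.45, 0.0, 0.45, 1.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.points_mV, float)
        d = np.asarray(self.points_rel, float)
        if v.size != d.size or v.size < 3:
            raise ValueError("need matching control points (>= 3)")
        if np.any(np.diff(v) <= 0):
            raise ValueError("control voltages must be ascending")
        if 0.0 not in v or d[np.where(v == 0.0)[0][0]] != 0.0:
            raise ValueError("template must anchor density 0 at 0 mV")
        if np.any(np.sign(d) != np.sign(v)):
            raise ValueError("density must carry the sign of the voltage")

    def __call__(self, voltage_mV) -> np.ndarray:
        from scipy.interpolate import PchipInterpolator

        v = np.asarray(self.points_mV, float)
        d = np.asarray(self.points_rel, float)
        interp = PchipInterpolator(v, d / d[-1])
        return interp(np.asarray(voltage_mV, float))

    @property
    def rectification(self) -> float:
        """|outward density at +100| / |inward density at -100|."""
        d = np.asarray(self.points_rel, float)
        return abs(d[-1] / d[0])


def outward_rectifying_template(ratio: float = 3.0) -> IVTemplate:
    """Pronounced outward rectification (outward:inward = ``ratio``:1)."""
    return IVTemplate(
        points_mV=(-100.0, -50.0, 0.0, 50.0, 100.0),
        points_rel=(-1.0 / ratio, -0.35 / ratio, 0.0, 0.4, 1.0),
    )


def near_symmetric_template() -> IVTemplate:
    """Almost symmetrical inward and outward branches."""
    return IVTemplate()


def _require_alternating(schedule: Sequence[LightEvent]) -> None:
    validate_schedule(schedule)
    if not schedule:
        raise ValueError("empty light schedule")
    if schedule[0].kind != "blue":
        raise ValueError("schedule must start with blue light (g = 0 baseline)")


def gating_timecourse(
    params: GatingParams,
    schedule: Sequence[LightEvent],
    fs: float,
    duration_s: float,
    rise_span: float = DEFAULT_RISE_SPAN,
) -> np.ndarray:
    """Dimensionless open fraction g(t) in [0, 1] on a uniform time grid.

    Piecewise composition: accelerating-exponential rise capped at 1 on UV,
    biphasic decay toward ``residual_c`` under sustained UV, mono-exponential
    deactivation to 0 on blue.
    """
    _require_alternating(schedule)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    g = np.zeros(n)

    a_rise = 1.0 / (2.0**rise_span - 1.0)
    bounds = [e.time_s for e in schedule] + [duration_s + 1.0 / fs]
    g_entry = 0.0
    for ev, t_lo, t_hi in zip(schedule, bounds[:-1], bounds[1:]):
        mask = (t >= t_lo) & (t < t_hi)
        if not np.any(mask):
            continue
        dt = t[mask] - t_lo
        if ev.kind == "blue":
            seg = g_entry * 2.0 ** (-dt / params.tau_deact_s)
        else:  # UV: rise, then biphasic inactivation after the cap
            span = rise_span * params.tau_act_s
            rise = g_entry + (1.0 - g_entry) * a_rise * (
                2.0 ** (np.minimum(dt, span) / params.tau_act_s) - 1.0
            )
            c = params.residual_c
            f = params.frac_fast
            ddt = dt - span
            decay = (1.0 - c) * (
                f * 2.0 ** (-ddt / params.tau_inact_fast_s)
                + (1.0 - f) * 2.0 ** (-ddt / params.tau_inact_slow_s)
            ) + c
            seg = np.where(dt < span, np.minimum(rise, 1.0), decay)
        g[mask] = seg
        # entry value for the next segment = g at its onset (continuity)
        t_next = t_hi
        dt_end = t_next - t_lo
        if ev.kind == "blue":
            g_entry = g_entry * 2.0 ** (-dt_end / params.tau_deact_s)
        else:
            span = rise_span * params.tau_act_s
            if dt_end < span:
                g_entry = min(
                    g_entry
                    + (1.0 - g_entry)
                    * a_rise
                    * (2.0 ** (dt_end / params.tau_act_s) - 1.0),
                    1.0,
                )
            else:
                c = params.residual_c
                f = params.frac_fast
                ddt = dt_end - span
                g_entry = (1.0 - c) * (
                    f * 2.0 ** (-ddt / params.tau_inact_fast_s)
                    + (1.0 - f) * 2.0 ** (-ddt / params.tau_inact_slow_s)
                ) + c
    return np.clip(g, 0.0, 1.0)


def simulate_holding_trace(
    params: GatingParams,
    schedule: Sequence[LightEvent],
    duration_s: float,
    capacitance_pF: float = 10.0,
    template: IVTemplate | None = None,
    fs: float = 2000.0,
    holding_mV: float = -60.0,
    noise_sd_pA: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    rise_span: float = DEFAULT_RISE_SPAN,
) -> Trace:
    """Whole-cell current trace at a constant holding potential.

    ``I(t) = C * (baseline_cd + g(t) * cd(holding)) + N(0, noise_sd)`` with
    cd(holding) from the I-V template scaled by the peak current density.
    A seed is mandatory whenever noise is requested.
    """
    if noise_sd_pA > 0 and seed is None:
        raise ValueError("a seed is mandatory when noise_sd_pA > 0")
    template = template or near_symmetric_template()
    g = gating_timecourse(params, schedule, fs, duration_s, rise_span=rise_span)
    cd_hold = params.peak_cd_pApF * float(template(holding_mV))
    current = capacitance_pF * (params.baseline_cd_pApF + g * cd_hold)
    if noise_sd_pA > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd_pA, size=current.size)
    return Trace(
        sampling_Hz=fs,
        current_pA=current,
        mode="holding",
        holding_mV=holding_mV,
        name="holding",
    )


def simulate_ramp_session(
    params: GatingParams,
    template: IVTemplate,
    protocol: RampProtocol,
    schedule: Sequence[LightEvent],
    duration_s: float,
    capacitance_pF: float = 10.0,
    noise_sd_pA: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    apply_filter: bool = False,
    rise_span: float = DEFAULT_RISE_SPAN,
) -> list[Trace]:
    """Repetitive ramp sweeps; sweep k starts at k / repetition_Hz.

    Each sweep's current is ``C * (baseline_cd + g(t) * peak_cd *
    template(V(t)))`` plus optional Gaussian noise; ``apply_filter`` adds a
    4th-order low-pass at the protocol's nominal filter cutoff.
    """
    if noise_sd_pA > 0 and seed is None:
        raise ValueError("a seed is mandatory when noise_sd_pA > 0")
    _require_alternating(schedule)
    rng = np.random.default_rng(seed) if noise_sd_pA > 0 else None
    n_sweeps = int(duration_s * protocol.repetition_Hz)
    fs = protocol.acquisition_Hz
    n_per_sweep = int(round(protocol.sweep_s * fs))
    t_in_sweep = np.arange(n_per_sweep) / fs
    volts = ramp_voltage_at(protocol, t_in_sweep)
    shape = template(volts)
    g_full = gating_timecourse(params, schedule, fs, duration_s, rise_span=rise_span)

    sweeps = []
    for k in range(n_sweeps):
        t0 = k / protocol.repetition_Hz
        i0 = int(round(t0 * fs))
        g = g_full[i0 : i0 + n_per_sweep]
        if g.size < n_per_sweep:
            break
        current = capacitance_pF * (
            params.baseline_cd_pApF + g * params.peak_cd_pApF * shape
        )
        if rng is not None:
            current = current + rng.normal(0.0, noise_sd_pA, size=current.size)
        if apply_filter:
            from scipy.signal import butter, filtfilt

            b, a = butter(4, protocol.filter_Hz / (fs / 2.0))
            current = filtfilt(b, a, current)
        sweeps.append(
            Trace(
                sampling_Hz=fs,
                current_pA=current,
                mode="ramp",
                holding_mV=None,
                protocol=protocol,
                sweep_index=k,
                t0_s=t0,
                name=f"sweep{k:05d}",
            )
        )
    return sweeps


@dataclass(frozen=True)
class CohortSpec:
    """Log-normal population of cells for group-level simulations.

    ``gsd`` entries are geometric standard deviations (1.0 = no spread);
    draws for the bounded fields ``frac_fast`` and ``residual_c`` are clipped
    to their domains.
    """

    n_cells: int
    params_median: GatingParams = field(default_factory=GatingParams)
    params_gsd: dict = field(default_factory=dict)
    capacitance_median_pF: float = 10.0
    capacitance_gsd: float = 1.3
    noise_sd_pA: float = 5.0
    seed: int = 0
    compound: str = "OptoDArG"
    light_source: str = "LED"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.capacitance_median_pF <= 0:
            raise ValueError("capacitance median must be > 0")


_LOGNORMAL_FIELDS = (
    "tau_act_s",
    "tau_deact_s",
    "tau_inact_fast_s",
    "tau_inact_slow_s",
    "frac_fast",
    "residual_c",
    "peak_cd_pApF",
)


def _draw_params(spec: CohortSpec, rng: np.random.Generator) -> GatingParams:
    med = spec.params_median
    values = {}
    for name in _LOGNORMAL_FIELDS:
        m = getattr(med, name)
        gsd = float(spec.params_gsd.get(name, 1.0))
        if m == 0.0 or gsd == 1.0:
            values[name] = m
        else:
            values[name] = m * math.exp(rng.normal(0.0, math.log(gsd)))
    values["frac_fast"] = min(max(values["frac_fast"], 0.0), 1.0)
    values["residual_c"] = min(max(values["residual_c"], 0.0), 0.999)
    if values["tau_inact_fast_s"] >= values["tau_inact_slow_s"]:
        values["tau_inact_fast_s"] = values["tau_inact_slow_s"] / 3.0
    return replace(med, **values)


def simulate_cohort(
    spec: CohortSpec,
    schedule: Sequence[LightEvent],
    duration_s: float,
    template: IVTemplate | None = None,
    protocol: RampProtocol | None = None,
    fs: float = 2000.0,
) -> tuple[list[Recording], pd.DataFrame]:
    """Draw ``n_cells`` recordings plus a manifest of true parameters.

    Each cell gets its own seed spawned from the master seed, a holding-mode
    kinetics trace and, when a protocol is given, a ramp-sweep session.
    """
    template = template or near_symmetric_template()
    master = np.random.SeedSequence(spec.seed)
    cell_seeds = master.spawn(spec.n_cells)
    recordings, rows = [], []
    for i, ss in enumerate(cell_seeds):
        rng = np.random.default_rng(ss)
        params = _draw_params(spec, rng)
        cap = spec.capacitance_median_pF
        if spec.capacitance_gsd != 1.0:
            cap *= math.exp(rng.normal(0.0, math.log(spec.capacitance_gsd)))
        trace_seed = ss.spawn(2)
        traces = [
            simulate_holding_trace(
                params,
                schedule,
                duration_s,
                capacitance_pF=cap,
                template=template,
                fs=fs,
                noise_sd_pA=spec.noise_sd_pA,
                seed=trace_seed[0] if spec.noise_sd_pA > 0 else None,
            )
        ]
        if protocol is not None:
            traces += simulate_ramp_session(
                params,
                template,
                protocol,
                schedule,
                duration_s,
                capacitance_pF=cap,
                noise_sd_pA=spec.noise_sd_pA,
                seed=trace_seed[1] if spec.noise_sd_pA > 0 else None,
            )
        cell_id = f"{spec.compound}-{spec.light_source}-{i:03d}"
        recordings.append(
            Recording(
                cell_id=cell_id,
                capacitance_pF=cap,
                compound=spec.compound,
                light_source=spec.light_source,
                traces=traces,
                schedule=list(schedule),
                meta={"seed": str(ss.entropy)},
            )
        )
        rows.append(
            {
                "cell_id": cell_id,
                "capacitance_pF": cap,
                **{name: getattr(params, name) for name in _LOGNORMAL_FIELDS},
                "baseline_cd_pApF": params.baseline_cd_pApF,
            }
        )
    return recordings, pd.DataFrame(rows)


def simulate_absorbance_relaxation(
    tau_half_min: float,
    A_cis: float,
    A_trans: float,
    duration_min: float,
    step_min: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Thermal cis->trans relaxation of the absorbance at the band maximum.

    ``A(t) = A_trans - (A_trans - A_cis) * 2**(-t / tau_half)`` sampled every
    ``step_min`` minutes.
    """
    if tau_half_min <= 0:
        raise ValueError("tau_half_min must be > 0")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is mandatory when noise_sd > 0")
    t = np.arange(0.0, duration_min + step_min / 2.0, step_min)
    A = A_trans - (A_trans - A_cis) * 2.0 ** (-t / tau_half_min)
    if noise_sd > 0:
        A = A + np.random.default_rng(seed).normal(0.0, noise_sd, size=A.size)
    return t, A
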