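"""Domain model for whole-cell patch-clamp recordings.

Containers for light schedules, voltage-ramp protocols, current traces and
whole recordings, plus the on-disk formats (an HDF5 container and a
CSV-per-trace text dialect) and the current-density / voltage-mapping
utilities the analysis stages build on.

Conventions
-----------
* Time is in seconds everywhere inside the package; milliseconds and minutes
  appear only at report boundaries.
* Current is in pA, capacitance in pF, so current density is pA/pF.
* Inward current is negative (standard electrophysiology sign convention).
* The liquid junction potential is carried as metadata only; recordings are
  assumed to have been corrected at acquisition time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np


class SchemaError(ValueError):
    """A recording container violates the expected layout or invariants."""


# wavelength classes used for photoswitching: UV stabilises the active cis
# isomer, blue the inactive trans isomer
UV_NM = 365.0
BLUE_NM = 445.0


def wavelength_class(nm: float) -> str:
    """Classify a wavelength as 'uv' (~365 nm) or 'blue' (~445 nm)."""
    if 330.0 <= nm <= 400.0:
        return "uv"
    if 400.0 < nm <= 470.0:
        return "blue"
    raise ValueError(f"wavelength {nm} nm outside the UV/blue switching bands")


@dataclass(frozen=True)
class LightEvent:
    """Switch of the illumination at ``time_s`` (seconds from trace start)."""

    time_s: float
    wavelength_nm: float
    intensity_pct: float = 100.0

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError("light event time must be >= 0")
        wavelength_class(self.wavelength_nm)  # validates band
        if not 0.0 < self.intensity_pct <= 100.0:
            raise ValueError("intensity must be in (0, 100] percent")

    @property
    def kind(self) -> str:
        return wavelength_class(self.wavelength_nm)


def validate_schedule(events: Sequence[LightEvent]) -> None:
    """Check ordering and UV/blue alternation of a light schedule."""
    times = [e.time_s for e in events]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise SchemaError("light events must be strictly ascending in time")
    kinds = [e.kind for e in events]
    if any(k1 == k2 for k1, k2 in zip(kinds, kinds[1:])):
        raise SchemaError("consecutive light events must alternate UV/blue")


@dataclass(frozen=True)
class RampProtocol:
    """Repetitive hold / linear-ramp / hold command-voltage protocol.

    The default values are the slow 2 Hz dialect (50 ms at -100 mV, 400 ms
    ramp to +100 mV, 50 ms at +100 mV, acquired at 5 kHz after a 2.5 kHz
    anti-alias filter).  ``fast_protocol`` gives the 50 Hz dialect.
    """

    pre_hold_mV: float = -100.0
    pre_hold_ms: float = 50.0
    ramp_start_mV: float = -100.0
    ramp_end_mV: float = 100.0
    ramp_ms: float = 400.0
    post_hold_mV: float = 100.0
    post_hold_ms: float = 50.0
    repetition_Hz: float = 2.0
    acquisition_Hz: float = 5000.0
    filter_Hz: float = 2500.0

    def __post_init__(self) -> None:
        for name in ("pre_hold_ms", "ramp_ms", "post_hold_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        period_ms = 1000.0 / self.repetition_Hz
        if period_ms < self.sweep_ms - 1e-9:
            raise ValueError("repetition period shorter than one sweep")
        # Nyquist: the acquisition rate must resolve the anti-alias band
        if not self.acquisition_Hz > 2.0 * self.filter_Hz - 1e-9:
            raise ValueError("acquisition_Hz must exceed 2 x filter_Hz")

    @property
    def sweep_ms(self) -> float:
        return self.pre_hold_ms + self.ramp_ms + self.post_hold_ms

    @property
    def sweep_s(self) -> float:
        return self.sweep_ms / 1000.0


def fast_protocol() -> RampProtocol:
    """The 50 Hz dialect: 7 ms hold, 10 ms ramp, 3 ms hold."""
    return RampProtocol(
        pre_hold_ms=7.0, ramp_ms=10.0, post_hold_ms=3.0, repetition_Hz=50.0
    )


def ramp_voltage_at(protocol: RampProtocol, time_in_sweep_s: float) -> float:
    """Command voltage (mV) at ``time_in_sweep_s`` within one sweep.

    Piecewise linear with the half-open convention: the ramp occupies
    [pre_hold, pre_hold + ramp); the first post-hold instant already sits at
    the ramp end voltage.
    """
    t_ms = np.asarray(time_in_sweep_s, dtype=float) * 1000.0
    scalar = t_ms.ndim == 0
    t_ms = np.atleast_1d(t_ms)
    if np.any(t_ms < 0) or np.any(t_ms >= protocol.sweep_ms):
        raise ValueError("time outside the sweep duration")
    ramp_lo = protocol.pre_hold_ms
    ramp_hi = ramp_lo + protocol.ramp_ms
    frac = (t_ms - ramp_lo) / protocol.ramp_ms
    v = np.where(
        t_ms < ramp_lo,
        protocol.pre_hold_mV,
        np.where(
            t_ms < ramp_hi,
            protocol.ramp_start_mV
            + (protocol.ramp_end_mV - protocol.ramp_start_mV) * frac,
            protocol.post_hold_mV,
        ),
    )
    return float(v[0]) if scalar else v


@dataclass
class Trace:
    """Uniformly sampled current time series (pA)."""

    sampling_Hz: float
    current_pA: np.ndarray
    mode: str = "holding"  # "holding" or "ramp"
    holding_mV: float | None = -60.0
    protocol: RampProtocol | None = None
    sweep_index: int | None = None
    t0_s: float = 0.0
    name: str = "trace"

    def __post_init__(self) -> None:
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.sampling_Hz <= 0:
            raise ValueError("sampling_Hz must be > 0")
        if not np.all(np.isfinite(self.current_pA)):
            raise ValueError("trace samples must be finite")
        if self.mode not in ("holding", "ramp"):
            raise ValueError("mode must be 'holding' or 'ramp'")
        if self.mode == "ramp" and self.protocol is None:
            raise ValueError("ramp traces need a RampProtocol")

    @property
    def n_samples(self) -> int:
        return int(self.current_pA.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_Hz

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the trace start."""
        return np.arange(self.n_samples) / self.sampling_Hz


@dataclass
class Recording:
    """One cell: metadata, traces and the light schedule."""

    cell_id: str
    capacitance_pF: float
    compound: str = "OptoDArG"
    light_source: str = "LED"
    intensity_pct: float = 100.0
    junction_potential_mV: float = 4.0
    traces: list[Trace] = field(default_factory=list)
    schedule: list[LightEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.capacitance_pF <= 0:
            raise ValueError("capacitance_pF must be > 0")
        validate_schedule(self.schedule)
        if self.traces and self.schedule:
            span = max(tr.t0_s + tr.duration_s for tr in self.traces)
            if any(ev.time_s > span + 1e-9 for ev in self.schedule):
                raise SchemaError("light event outside the recorded time span")


@dataclass
class IVCurve:
    """Current density (pA/pF) on an ascending voltage grid (mV)."""

    voltage_mV: np.ndarray
    density_pApF: np.ndarray
    sweep_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.density_pApF = np.asarray(self.density_pApF, dtype=float)
        if self.voltage_mV.size != self.density_pApF.size:
            raise ValueError("voltage and density arrays must match in length")
        if np.any(np.diff(self.voltage_mV) <= 0):
            raise ValueError("voltage grid must be strictly ascending")


def to_current_density(trace: Trace, capacitance_pF: float) -> Trace:
    """Divide each current sample by the membrane capacitance (-> pA/pF).

    Returned as a new Trace whose samples carry pA/pF; all other metadata is
    preserved.
    """
    if capacitance_pF <= 0:
        raise ValueError("capacitance_pF must be > 0")
    out = replace(trace, current_pA=trace.current_pA / capacitance_pF)
    return out


def extract_iv(
    sweep: Trace,
    protocol: RampProtocol | None = None,
    capacitance_pF: float = 1.0,
    bin_mV: float = 1.0,
) -> IVCurve:
    """Current-density-voltage relation of one ramp sweep.

    Ramp-segment samples are mapped to command voltages, converted to
    density, and averaged into regular voltage bins (default 1 mV; closed at
    the ramp start, half-open elsewhere).  The grid reports bin centres.
    """
    protocol = protocol or sweep.protocol
    if protocol is None:
        raise ValueError("no ramp protocol available")
    if capacitance_pF <= 0:
        raise ValueError("capacitance_pF must be > 0")
    t = sweep.times()
    ramp_lo = protocol.pre_hold_ms / 1000.0
    ramp_hi = ramp_lo + protocol.ramp_ms / 1000.0
    in_ramp = (t >= ramp_lo) & (t < ramp_hi)
    if not np.any(in_ramp):
        raise ValueError("sweep contains no ramp-segment samples")
    v = ramp_voltage_at(protocol, t[in_ramp])
    cd = sweep.current_pA[in_ramp] / capacitance_pF

    v_lo = min(protocol.ramp_start_mV, protocol.ramp_end_mV)
    v_hi = max(protocol.ramp_start_mV, protocol.ramp_end_mV)
    edges = np.arange(v_lo, v_hi + bin_mV / 2, bin_mV)
    idx = np.clip(np.digitize(v, edges) - 1, 0, edges.size - 2)
    counts = np.bincount(idx, minlength=edges.size - 1)
    if np.any(counts == 0):
        raise ValueError(
            "empty voltage bins at this sampling rate; use a coarser bin_mV"
        )
    sums = np.bincount(idx, weights=cd, minlength=edges.size - 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return IVCurve(
        voltage_mV=centers,
        density_pApF=sums / counts,
        sweep_id=f"{sweep.name}:{sweep.sweep_index}",
    )


def extract_plateau_cd(
    sweep: Trace,
    protocol: RampProtocol | None = None,
    capacitance_pF: float = 1.0,
    settle_fraction: float = 0.2,
) -> tuple[float, float]:
    """Median current densities over the two hold segments of a ramp sweep.

    Returns ``(cd at pre-hold voltage, cd at post-hold voltage)`` — for the
    standard protocols the plateaus at -100 and +100 mV.  The first
    ``settle_fraction`` of each hold is excluded to avoid capacitive
    transients.
    """
    protocol = protocol or sweep.protocol
    if protocol is None:
        raise ValueError("no ramp protocol available")
    if capacitance_pF <= 0:
        raise ValueError("capacitance_pF must be > 0")
    if not 0.0 <= settle_fraction < 1.0:
        raise ValueError("settle_fraction must be in [0, 1)")
    t = sweep.times()
    pre_hi = protocol.pre_hold_ms / 1000.0
    post_lo = (protocol.pre_hold_ms + protocol.ramp_ms) / 1000.0
    post_hi = protocol.sweep_s
    pre_mask = (t >= settle_fraction * pre_hi) & (t < pre_hi)
    post_mask = (t >= post_lo + settle_fraction * (post_hi - post_lo)) & (t < post_hi)
    if not np.any(pre_mask) or not np.any(post_mask):
        raise ValueError("hold segment shorter than the settle margin")
    cd = sweep.current_pA / capacitance_pF
    return float(np.median(cd[pre_mask])), float(np.median(cd[post_mask]))


# ---------------------------------------------------------------------------
# on-disk containers
# ---------------------------------------------------------------------------

_META_FIELDS = (
    "cell_id",
    "capacitance_pF",
    "compound",
    "light_source",
    "intensity_pct",
    "junction_potential_mV",
)


def _trace_attrs(tr: Trace) -> dict:
    d = {
        "sampling_Hz": tr.sampling_Hz,
        "mode": tr.mode,
        "t0_s": tr.t0_s,
    }
    if tr.mode == "holding":
        d["holding_mV"] = tr.holding_mV
    else:
        p = tr.protocol
        d.update(
            sweep_index=-1 if tr.sweep_index is None else tr.sweep_index,
            pre_hold_mV=p.pre_hold_mV,
            pre_hold_ms=p.pre_hold_ms,
            ramp_start_mV=p.ramp_start_mV,
            ramp_end_mV=p.ramp_end_mV,
            ramp_ms=p.ramp_ms,
            post_hold_mV=p.post_hold_mV,
            post_hold_ms=p.post_hold_ms,
            repetition_Hz=p.repetition_Hz,
            acquisition_Hz=p.acquisition_Hz,
            filter_Hz=p.filter_Hz,
        )
    return d


def _trace_from_attrs(name: str, attrs: dict, samples: np.ndarray) -> Trace:
    mode = attrs["mode"]
    if isinstance(mode, bytes):
        mode = mode.decode()
    if mode == "holding":
        return Trace(
            sampling_Hz=float(attrs["sampling_Hz"]),
            current_pA=samples,
            mode="holding",
            holding_mV=float(attrs.get("holding_mV", -60.0)),
            t0_s=float(attrs.get("t0_s", 0.0)),
            name=name,
        )
    proto = RampProtocol(
        pre_hold_mV=float(attrs["pre_hold_mV"]),
        pre_hold_ms=float(attrs["pre_hold_ms"]),
        ramp_start_mV=float(attrs["ramp_start_mV"]),
        ramp_end_mV=float(attrs["ramp_end_mV"]),
        ramp_ms=float(attrs["ramp_ms"]),
        post_hold_mV=float(attrs["post_hold_mV"]),
        post_hold_ms=float(attrs["post_hold_ms"]),
        repetition_Hz=float(attrs["repetition_Hz"]),
        acquisition_Hz=float(attrs["acquisition_Hz"]),
        filter_Hz=float(attrs["filter_Hz"]),
    )
    sweep_index = int(attrs.get("sweep_index", -1))
    return Trace(
        sampling_Hz=float(attrs["sampling_Hz"]),
        current_pA=samples,
        mode="ramp",
        holding_mV=None,
        protocol=proto,
        sweep_index=None if sweep_index < 0 else sweep_index,
        t0_s=float(attrs.get("t0_s", 0.0)),
        name=name,
    )


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording container.

    ``.h5``/``.hdf5`` paths get the hierarchical binary layout; any other
    path is treated as a directory holding ``recording.json`` (metadata +
    light schedule) and one ``<trace>.csv`` (time_s, current_pA) per trace.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            meta = f.create_group("meta")
            for k in _META_FIELDS:
                meta.attrs[k] = getattr(rec, k)
            sched = np.array(
                [(e.time_s, e.wavelength_nm, e.intensity_pct) for e in rec.schedule],
                dtype=[("time_s", "f8"), ("wavelength_nm", "f8"), ("intensity_pct", "f8")],
            )
            f.create_dataset("schedule", data=sched)
            traces = f.create_group("traces")
            for tr in rec.traces:
                ds = traces.create_dataset(tr.name, data=tr.current_pA, dtype="f8")
                for k, v in _trace_attrs(tr).items():
                    ds.attrs[k] = v
        return path

    path.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "meta": {k: getattr(rec, k) for k in _META_FIELDS},
        "schedule": [
            {"time_s": e.time_s, "wavelength_nm": e.wavelength_nm, "intensity_pct": e.intensity_pct}
            for e in rec.schedule
        ],
        "traces": {tr.name: _trace_attrs(tr) for tr in rec.traces},
    }
    (path / "recording.json").write_text(json.dumps(sidecar, indent=1))
    for tr in rec.traces:
        t = tr.times()
        with open(path / f"{tr.name}.csv", "w") as fh:
            fh.write("time_s,current_pA\n")
            for ti, ci in zip(t, tr.current_pA):
                fh.write(f"{ti:.9g},{ci:.17g}\n")
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a container written by :func:`write_recording`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "meta" not in f:
                raise SchemaError("missing /meta group")
            meta = dict(f["meta"].attrs)
            for k in _META_FIELDS:
                if k not in meta:
                    raise SchemaError(f"missing mandatory field '{k}'")
            sched = f["schedule"][()] if "schedule" in f else np.empty(0)
            events = [
                LightEvent(float(r["time_s"]), float(r["wavelength_nm"]), float(r["intensity_pct"]))
                for r in sched
            ]
            traces = []
            for name in sorted(f.get("traces", {}), key=str):
                ds = f["traces"][name]
                traces.append(_trace_from_attrs(name, dict(ds.attrs), ds[()]))
        cid = meta["cell_id"]
        if isinstance(cid, bytes):
            cid = cid.decode()
        rec = Recording(
            cell_id=str(cid),
            capacitance_pF=float(meta["capacitance_pF"]),
            compound=str(meta["compound"]),
            light_source=str(meta["light_source"]),
            intensity_pct=float(meta["intensity_pct"]),
            junction_potential_mV=float(meta["junction_potential_mV"]),
            traces=traces,
            schedule=events,
        )
        return rec

    sidecar_path = path / "recording.json"
    if not sidecar_path.exists():
        raise SchemaError("missing recording.json sidecar")
    sidecar = json.loads(sidecar_path.read_text())
    meta = sidecar.get("meta", {})
    for k in _META_FIELDS:
        if k not in meta:
            raise SchemaError(f"missing mandatory field '{k}'")
    events = [
        LightEvent(e["time_s"], e["wavelength_nm"], e.get("intensity_pct", 100.0))
        for e in sidecar.get("schedule", [])
    ]
    traces = []
    for name in sorted(sidecar.get("traces", {})):
        attrs = sidecar["traces"][name]
        csv_path = path / f"{name}.csv"
        if not csv_path.exists():
            raise SchemaError(f"missing trace file '{name}.csv'")
        data = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
        traces.append(_trace_from_attrs(name, attrs, data[:, 1]))
    return Recording(
        cell_id=str(meta["cell_id"]),
        capacitance_pF=float(meta["capacitance_pF"]),
        compound=str(meta["compound"]),
        light_source=str(meta["light_source"]),
        intensity_pct=float(meta["intensity_pct"]),
        junction_potential_mV=float(meta["junction_potential_mV"]),
        traces=traces,
        schedule=events,
    )
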