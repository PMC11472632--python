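import numpy as np
import pytest

from optoswitch.recordings import LightEvent, RampProtocol, Recording, Trace, fast_protocol
from optoswitch.synthetic import GatingParams


@pytest.fixture
def slow_protocol() -> RampProtocol:
    return RampProtocol()


@pytest.fixture
def fast_proto() -> RampProtocol:
    return fast_protocol()


@pytest.fixture
def led_params() -> GatingParams:
    """OptoDArG-like kinetics under a high-power LED."""
    return GatingParams(
        tau_act_s=0.0058,
        tau_deact_s=0.0084,
        tau_inact_fast_s=0.3,
        tau_inact_slow_s=13.1,
        frac_fast=0.5,
        residual_c=0.0,
        peak_cd_pApF=100.0,
    )


@pytest.fixture
def switch_schedule() -> list[LightEvent]:
    """Blue baseline, UV on at 1 s, blue again at 3 s."""
    return [LightEvent(0.0, 445.0), LightEvent(1.0, 365.0), LightEvent(3.0, 445.0)]


def ohmic_sweep(protocol: RampProtocol, g_pApF_per_mV: float = 1.0,
                capacitance_pF: float = 10.0) -> Trace:
    """Sweep of a pure ohmic conductor: I = C * g * V(t)."""
    from optoswitch.recordings import ramp_voltage_at

    fs = protocol.acquisition_Hz
    t = np.arange(int(round(protocol.sweep_s * fs))) / fs
    v = ramp_voltage_at(protocol, t)
    return Trace(
        sampling_Hz=fs,
        current_pA=capacitance_pF * g_pApF_per_mV * v,
        mode="ramp",
        holding_mV=None,
        protocol=protocol,
        sweep_index=0,
    )


@pytest.fixture
def small_recording(switch_schedule) -> Recording:
    rng = np.random.default_rng(42)
    tr = Trace(sampling_Hz=2000.0, current_pA=rng.normal(0, 1, 8000), name="holding")
    return Recording(
        cell_id="cell-000",
        capacitance_pF=12.5,
        compound="OptoDArG",
        light_source="LED",
        traces=[tr],
        schedule=switch_schedule,
    )
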