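"""Segment preparation, simplex fitting, thermal relaxation and PSS."""

import numpy as np
import pytest

from optoswitch.kinetics import (
    FitError,
    FitOptions,
    NormalizedSegment,
    estimate_pss_from_absorbance,
    fit_bi,
    fit_mono,
    fit_thermal_relaxation,
    prepare_activation,
    prepare_deactivation,
    prepare_inactivation,
    _mono_sse,
)
from optoswitch.recordings import LightEvent, Trace
from optoswitch.synthetic import (
    GatingParams,
    simulate_absorbance_relaxation,
    simulate_holding_trace,
)

BLUE, UV = 445.0, 365.0
LN2 = np.log(2.0)


def mono_segment(tau, direction, a=1.0, c=0.0, span=None, fs=2000.0, kind="custom"):
    span = span if span is not None else 8 * tau
    t = np.arange(int(span * fs)) / fs
    sign = 1.0 if direction == "rising" else -1.0
    y = a * np.exp(sign * LN2 * t / tau) + c
    return NormalizedSegment(t=t, y=y, kind=kind)


class TestPrepareActivation:
    def test_thirty_percent_normalization(self):
        # inward trace: baseline 0 pA, linear run-up to a -100 pA peak;
        # a sample at -15 pA must map to y = 0.5 by the 30% rule
        fs = 1000.0
        sched = [LightEvent(0.0, BLUE), LightEvent(1.0, UV)]
        current = np.zeros(3000)
        current[1000:2000] = -np.linspace(0, 100, 1000)
        current[2000:] = -100.0
        tr = Trace(sampling_Hz=fs, current_pA=current)
        seg = prepare_activation(tr, sched, smooth_samples=1)
        assert seg.normalization["divisor_pA"] == pytest.approx(30.0)
        i15 = np.argmin(np.abs(-current[1000:] - 15.0))
        assert seg.y[i15] == pytest.approx(0.5, abs=2e-2)
        # window stops at the first sample reaching +1 (30 pA magnitude)
        assert seg.y[-1] >= 1.0 and np.all(seg.y[:-1] < 1.0)
        assert seg.t[0] == 0.0

    def test_no_uv_event_is_error(self):
        tr = Trace(sampling_Hz=1000.0, current_pA=np.zeros(1000))
        with pytest.raises(FitError, match="UV"):
            prepare_activation(tr, [LightEvent(0.0, BLUE)])

    def test_no_rise_above_noise_is_error(self):
        rng = np.random.default_rng(0)
        tr = Trace(sampling_Hz=1000.0, current_pA=rng.normal(0, 1, 3000))
        sched = [LightEvent(0.0, BLUE), LightEvent(1.0, UV)]
        with pytest.raises(FitError, match="no activation"):
            prepare_activation(tr, sched)

    def test_window_ends_at_closed_form_crossing(self, led_params):
        # noiseless generator: magnitude crosses 0.3*peak where
        # a*(2**(t/tau) - 1) = 0.3, i.e. t = tau * log2(1 + 0.3/a)
        sched = [LightEvent(0.0, BLUE), LightEvent(1.0, UV)]
        tr = simulate_holding_trace(led_params, sched, duration_s=3.0)
        seg = prepare_activation(tr, sched)
        a = 1.0 / (2.0**3.33 - 1.0)
        t_cross = led_params.tau_act_s * np.log2(1.0 + 0.3 / a)
        assert seg.t[-1] == pytest.approx(t_cross, abs=2.0 / 2000.0)


class TestPrepareDeactivation:
    @pytest.mark.parametrize("m_end, sample, expected", [(0.0, 50.0, 0.5),
                                                         (20.0, 60.0, 0.5)])
    def test_affine_mapping(self, m_end, sample, expected):
        fs = 1000.0
        sched = [LightEvent(0.0, BLUE), LightEvent(0.5, UV), LightEvent(1.0, BLUE)]
        current = np.concatenate([
            np.zeros(500), np.full(500, -100.0),
            np.full(250, -sample), np.full(250, -m_end),
        ])
        tr = Trace(sampling_Hz=fs, current_pA=current)
        seg = prepare_deactivation(tr, sched, pre_window_s=0.4, tail_fraction=0.2)
        assert seg.y[100] == pytest.approx(expected)

    def test_half_life_property_on_generator(self):
        p = GatingParams(tau_deact_s=0.0084, tau_inact_fast_s=100.0,
                         tau_inact_slow_s=1000.0)
        sched = [LightEvent(0.0, BLUE), LightEvent(1.0, UV), LightEvent(3.0, BLUE)]
        tr = simulate_holding_trace(p, sched, duration_s=3.3)
        seg = prepare_deactivation(tr, sched)
        i_half = int(round(0.0084 * 2000))
        assert seg.y[i_half] == pytest.approx(0.5, abs=0.02)

    def test_flat_trace_has_no_amplitude(self):
        sched = [LightEvent(0.0, BLUE), LightEvent(0.5, UV), LightEvent(1.0, BLUE)]
        tr = Trace(sampling_Hz=1000.0, current_pA=np.full(2000, -5.0))
        with pytest.raises(FitError, match="amplitude"):
            prepare_deactivation(tr, sched)


class TestPrepareInactivation:
    def test_peak_anchored_to_one(self, led_params):
        sched = [LightEvent(0.0, BLUE), LightEvent(1.0, UV)]
        tr = simulate_holding_trace(led_params, sched, duration_s=60.0)
        seg = prepare_inactivation(tr, sched)
        assert seg.y[0] == pytest.approx(1.0, abs=1e-9)
        assert seg.t[0] == 0.0

    def test_quarter_normalization(self):
        fs = 1000.0
        sched = [LightEvent(0.0, BLUE), LightEvent(1.0, UV)]
        current = np.concatenate([
            np.zeros(1000), -np.linspace(0, 100, 100),
            -np.linspace(100, 0, 2000), np.zeros(6900),
        ])
        tr = Trace(sampling_Hz=fs, current_pA=current)
        seg = prepare_inactivation(tr, sched, smooth_samples=1)
        i25 = np.argmin(np.abs(seg.y - 0.25))
        assert seg.y[i25] == pytest.approx(0.25, abs=0.01)

    def test_uv_off_before_peak_is_error(self, led_params):
        # blue returns while the current is still rising
        sched = [LightEvent(0.0, BLUE), LightEvent(1.0, UV),
                 LightEvent(1.0 + 0.010, BLUE)]  # rise span is ~19 ms
        tr = simulate_holding_trace(led_params, sched, duration_s=3.0)
        with pytest.raises(FitError, match="before the current peak"):
            prepare_inactivation(tr, sched)

    def test_short_uv_period_flagged(self, led_params):
        sched = [LightEvent(0.0, BLUE), LightEvent(1.0, UV), LightEvent(6.0, BLUE)]
        tr = simulate_holding_trace(led_params, sched, duration_s=7.0)
        seg = prepare_inactivation(tr, sched)
        assert "uv_period_short_for_steady_state" in seg.flags


class TestFitMono:
    def test_exact_rising_recovery(self):
        t = np.arange(0, 0.0166, 1 / 2000.0)
        y = 0.5 * 2.0 ** (t / 0.010) - 0.5
        seg = NormalizedSegment(t=t, y=y, kind="activation")
        fit = fit_mono(seg, direction="rising")
        assert fit.tau_half == pytest.approx(0.010, rel=1e-3)
        assert fit.converged

    def test_exact_decaying_recovery(self):
        seg = mono_segment(0.020, "decaying")
        fit = fit_mono(seg, direction="decaying")
        assert fit.tau_half == pytest.approx(0.020, rel=1e-3)
        assert fit.a == pytest.approx(1.0, abs=1e-3)
        assert fit.c == pytest.approx(0.0, abs=1e-3)

    def test_noisy_fit_matches_grid_search_oracle(self):
        # independent oracle: profile the SSE over a dense tau grid, solving
        # (a, c) by linear least squares at each tau
        rng = np.random.default_rng(12)
        tau_true, fs = 0.050, 2000.0
        t = np.arange(int(0.5 * fs)) / fs
        y = 2.0 ** (-t / tau_true) + rng.normal(0, 0.05, t.size)
        seg = NormalizedSegment(t=t, y=y, kind="deactivation")
        taus = np.linspace(0.5 * tau_true, 2.0 * tau_true, 2001)
        best_sse, best_tau = np.inf, None
        for tau in taus:
            X = np.column_stack([2.0 ** (-t / tau), np.ones_like(t)])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(res[0]) if res.size else float(np.sum((X @ beta - y) ** 2))
            if sse < best_sse:
                best_sse, best_tau = sse, tau
        fit = fit_mono(seg, direction="decaying")
        assert fit.tau_half == pytest.approx(best_tau, abs=2 * (taus[1] - taus[0]))
        assert fit.sse <= best_sse + 1e-9

    def test_sse_not_worse_than_start_point(self):
        rng = np.random.default_rng(5)
        t = np.arange(1000) / 2000.0
        y = 0.8 * 2.0 ** (-t / 0.03) + 0.1 + rng.normal(0, 0.05, t.size)
        seg = NormalizedSegment(t=t, y=y, kind="deactivation")
        opts = FitOptions()
        fit = fit_mono(seg, direction="decaying", options=opts)
        sse_start = _mono_sse(np.array(opts.init_deactivation), t, y, -1.0)
        assert fit.sse <= sse_start

    def test_half_life_semantics(self):
        seg = mono_segment(0.025, "decaying", a=0.9, c=0.05)
        fit = fit_mono(seg, direction="decaying")
        half = fit.model(fit.tau_half) - fit.c
        full = fit.model(0.0) - fit.c
        assert half == pytest.approx(full / 2.0, rel=1e-9)

    def test_scale_invariance_of_tau(self, led_params):
        # multiplying the raw current by k > 0 leaves tau unchanged
        sched = [LightEvent(0.0, BLUE), LightEvent(1.0, UV)]
        tr = simulate_holding_trace(led_params, sched, duration_s=3.0)
        taus = []
        for k in (1.0, 7.0):
            scaled = Trace(sampling_Hz=tr.sampling_Hz, current_pA=k * tr.current_pA)
            seg = prepare_activation(scaled, sched)
            taus.append(fit_mono(seg).tau_half)
        assert taus[0] == pytest.approx(taus[1], rel=1e-9)

    def test_time_origin_invariance(self, led_params):
        # prepending baseline shifts the trace in time but not the fit
        sched1 = [LightEvent(0.0, BLUE), LightEvent(1.0, UV)]
        sched2 = [LightEvent(0.0, BLUE), LightEvent(2.5, UV)]
        tr1 = simulate_holding_trace(led_params, sched1, duration_s=3.0)
        tr2 = simulate_holding_trace(led_params, sched2, duration_s=4.5)
        tau1 = fit_mono(prepare_activation(tr1, sched1)).tau_half
        tau2 = fit_mono(prepare_activation(tr2, sched2)).tau_half
        assert tau1 == pytest.approx(tau2, rel=1e-6)

    def test_noisy_recovery_calibration(self):
        # 200 seeded replicates at 5% noise: median tau within 5% of truth
        tau_true, fs = 0.0944, 2000.0
        p = GatingParams(tau_deact_s=tau_true, tau_inact_fast_s=100.0,
                         tau_inact_slow_s=1000.0, peak_cd_pApF=100.0)
        sched = [LightEvent(0.0, BLUE), LightEvent(0.5, UV), LightEvent(1.5, BLUE)]
        amplitude_pA = 10.0 * 100.0 * abs(
            float(__import__("optoswitch.synthetic", fromlist=["x"]).near_symmetric_template()(-60.0))
        )
        taus = []
        for seed in range(200):
            tr = simulate_holding_trace(p, sched, duration_s=2.5,
                                        noise_sd_pA=0.05 * amplitude_pA, seed=seed)
            seg = prepare_deactivation(tr, sched)
            taus.append(fit_mono(seg).tau_half)
        assert np.median(taus) == pytest.approx(tau_true, rel=0.05)


class TestFitBi:
    def test_recovers_fast_and_slow_pair(self):
        fs = 2000.0
        t = np.arange(int(60.0 * fs)) / fs
        y = 0.5 * 2.0 ** (-t / 0.3) + 0.5 * 2.0 ** (-t / 13.1)
        seg = NormalizedSegment(t=t, y=y, kind="inactivation")
        fit = fit_bi(seg)
        assert fit.tau_half_fast == pytest.approx(0.3, rel=0.01)
        assert fit.tau_half_slow == pytest.approx(13.1, rel=0.01)
        assert fit.tau_half_fast <= fit.tau_half_slow

    def test_single_exponential_input_flagged_degenerate(self):
        seg = mono_segment(1.0, "decaying", span=10.0, fs=200.0,
                           kind="inactivation")
        fit = fit_bi(seg)
        amp_dropped = min(abs(fit.a1), abs(fit.a2)) < 0.05
        taus_close = fit.tau_half_slow / max(fit.tau_half_fast, 1e-12) < 3.0
        assert amp_dropped or taus_close
        if taus_close:
            assert "components_indistinct" in fit.flags

    def test_amplitude_conservation_at_t0(self):
        fs = 2000.0
        t = np.arange(int(30.0 * fs)) / fs
        y = 0.3 * 2.0 ** (-t / 0.2) + 0.6 * 2.0 ** (-t / 5.0) + 0.1
        seg = NormalizedSegment(t=t, y=y, kind="inactivation")
        fit = fit_bi(seg)
        assert fit.a1 + fit.a2 + fit.c == pytest.approx(y[0], abs=1e-3)


class TestThermalRelaxation:
    def test_noiseless_recovery_within_0p1_percent(self):
        t, A = simulate_absorbance_relaxation(425.82, 0.25, 1.0, 2000.0)
        fit = fit_thermal_relaxation(t, A)
        assert fit.tau_half == pytest.approx(425.82, rel=1e-3)

    def test_flat_series_is_error(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(FitError, match="amplitude"):
            fit_thermal_relaxation(t, np.full(t.size, 0.7))

    def test_sampling_density_robustness(self):
        taus = []
        for step in (1.0, 0.5):
            t, A = simulate_absorbance_relaxation(425.82, 0.25, 1.0, 2000.0,
                                                  step_min=step)
            taus.append(fit_thermal_relaxation(t, A).tau_half)
        assert taus[0] == pytest.approx(taus[1], rel=1e-4)


class TestPSS:
    @pytest.mark.parametrize("ratio, trans, cis", [(0.93, 93.0, 7.0),
                                                   (0.90, 90.0, 10.0),
                                                   (1.0, 100.0, 0.0)])
    def test_ratio_maps_to_percentages(self, ratio, trans, cis):
        assert estimate_pss_from_absorbance(1.0, ratio) == (trans, cis)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_pss_from_absorbance(0.0, 0.5)
        with pytest.raises(ValueError):
            estimate_pss_from_absorbance(1.0, 1.5)
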