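import numpy as np
import pytest

from somnoresp import (CalibrationInfo, SignalTrace, compute_frequency,
                       compute_vt, detect_breaths, detect_sighs,
                       minute_ventilation, select_quiet_wake,
                       simulate_recording)
from somnoresp.breath import Breath, sigh_rate_per_hour
from somnoresp.simulate import sham_protocol


def _sine_trace(freq_hz=1.75, duration_s=60.0, fs=100.0, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return SignalTrace(amp * np.sin(2 * np.pi * freq_hz * t), fs,
                       label="airflow")


def _uniform_breaths(n=200, ibi=0.571, amp=1.0):
    out = [Breath(t_peak_s=i * ibi, t_trough_s=i * ibi + ibi / 2,
                  amplitude_units=amp, ibi_s=ibi) for i in range(n)]
    out[-1].ibi_s = float("nan")
    return out


class TestDetectBreaths:
    def test_sinusoid_count_matches_frequency(self):
        # 1.75 Hz = 105 cycles/min
        breaths = detect_breaths(_sine_trace(1.75, 60.0))
        assert abs(len(breaths) - 105) <= 1

    def test_flat_trace_yields_no_breaths(self):
        tr = SignalTrace(np.zeros(1000), 100.0)
        assert detect_breaths(tr) == []

    def test_count_invariant_to_amplitude_rescaling(self):
        a = detect_breaths(_sine_trace(amp=1.0))
        b = detect_breaths(_sine_trace(amp=250.0))
        assert len(a) == len(b)

    def test_count_matches_generator_truth(self):
        protocol = sham_protocol(duration_s=600.0, noise_sd=0.0,
                                 event_rate_per_h_sleep=0.0,
                                 sigh_rate_per_h=0.0,
                                 modulate_by_state=False)
        rec = simulate_recording(protocol, seed=3)
        breaths = detect_breaths(rec.airflow)
        assert len(breaths) == rec.truth.n_breaths

    def test_count_stable_under_10pct_noise(self):
        protocol = sham_protocol(duration_s=600.0,
                                 event_rate_per_h_sleep=0.0,
                                 sigh_rate_per_h=0.0)
        clean = simulate_recording(
            protocol.model_copy(update={"noise_sd": 0.0}), seed=3)
        noisy = simulate_recording(
            protocol.model_copy(update={"noise_sd": 0.1}), seed=3)
        n0 = len(detect_breaths(clean.airflow))
        n1 = len(detect_breaths(noisy.airflow))
        assert abs(n1 - n0) <= 0.01 * n0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_breaths(_sine_trace(duration_s=1.0))


class TestTidalVolume:
    def test_calibration_arithmetic(self):
        b = [Breath(0.0, 0.3, amplitude_units=2.0)]
        compute_vt(b, CalibrationInfo(ml_per_unit=0.5, body_mass_kg=0.4))
        assert b[0].vt_ml_per_kg == pytest.approx(2.5)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            CalibrationInfo(ml_per_unit=0.0, body_mass_kg=0.4)


class TestFrequency:
    def test_uniform_ibi(self):
        breaths = _uniform_breaths(ibi=0.571)
        _, f = compute_frequency(breaths)
        assert np.nanmean(f) == pytest.approx(60.0 / 0.571, abs=0.1)

    def test_single_breath_empty_series(self):
        starts, f = compute_frequency(_uniform_breaths(n=1))
        assert f.size == 0


class TestMinuteVentilation:
    def test_ve_equals_vt_times_f_exactly(self):
        # constant breathing at V_T 3.6 mL/kg, f 95/min
        ibi = 60.0 / 95.0
        breaths = _uniform_breaths(n=400, ibi=ibi)
        compute_vt(breaths, CalibrationInfo(3.6, 1.0))
        vent = minute_ventilation(breaths)
        ok = np.isfinite(vent.ve_ml_per_kg_per_min)
        np.testing.assert_allclose(vent.ve_ml_per_kg_per_min[ok],
                                   3.6 * 95.0, rtol=1e-9)
        win_ok = np.isfinite(vent.ve_windowed)
        np.testing.assert_allclose(vent.ve_windowed[win_ok], 342.0,
                                   rtol=1e-9)

    def test_ve_proportional_to_rate(self):
        fast = _uniform_breaths(n=100, ibi=0.3)
        slow = _uniform_breaths(n=100, ibi=0.6)
        for b in fast + slow:
            b.vt_ml_per_kg = 2.0
        ve_fast = minute_ventilation(fast).ve_ml_per_kg_per_min[0]
        ve_slow = minute_ventilation(slow).ve_ml_per_kg_per_min[0]
        assert ve_fast == pytest.approx(2 * ve_slow)

    def test_deep_event_suppresses_ve(self):
        """Injected apnoeic events (depth >= 0.95) must push in-event
        per-breath V_E below 5% of the preceding 60 s mean, checked by an
        independent windowed recomputation over the raw generated trace."""
        protocol = sham_protocol(duration_s=1200.0, noise_sd=0.0,
                                 sigh_rate_per_h=0.0,
                                 event_rate_per_h_sleep=8.0,
                                 apnoea_fraction=1.0)
        deep = []
        for seed in range(5):
            rec = simulate_recording(protocol, seed=seed)
            events = [e for e in rec.truth.injected_events
                      if e.depth >= 0.95]
            if not events:
                continue
            breaths = detect_breaths(rec.airflow,
                                     min_amplitude_fraction=0.02)
            compute_vt(breaths, CalibrationInfo(
                protocol.ml_per_unit, protocol.body_mass_kg))
            vent = minute_ventilation(breaths)
            t = vent.breath_times_s
            ve = vent.ve_ml_per_kg_per_min
            for e in events:
                inside = (t >= e.start_s) & (t < e.end_s) & np.isfinite(ve)
                before = ((t >= e.start_s - 60) & (t < e.start_s)
                          & np.isfinite(ve))
                assert inside.any() and before.any()
                assert np.min(ve[inside]) <= 0.05 * np.mean(ve[before])
                deep.append(e)
        assert deep, "generator placed no depth >= 0.95 events in 5 seeds"


class TestSighs:
    def test_constant_vt_no_sighs(self):
        breaths = _uniform_breaths(n=100)
        for b in breaths:
            b.vt_ml_per_kg = 2.0
        detect_sighs(breaths)
        assert not any(b.is_sigh for b in breaths)

    def test_single_tripled_breath_is_the_only_sigh(self):
        breaths = _uniform_breaths(n=100)
        for b in breaths:
            b.vt_ml_per_kg = 2.0
        breaths[50].vt_ml_per_kg = 6.0
        detect_sighs(breaths, k_sigh=2.0)
        assert [i for i, b in enumerate(breaths) if b.is_sigh] == [50]

    def test_too_few_breaths_rejected(self):
        with pytest.raises(ValueError):
            detect_sighs(_uniform_breaths(n=5))

    def test_recovered_rate_within_poisson_band(self, dta_recording,
                                                dta_analysis):
        from scipy.stats import poisson
        rate = dta_recording.truth.protocol.sigh_rate_per_h
        labels = np.asarray(dta_recording.truth.true_labels)
        quiet = dta_recording.truth.quiet_wake_epochs
        eligible = np.isin(labels, ("NREM", "REM")) | \
            ((labels == "WAKE") & quiet)
        hours = eligible.sum() * 5.0 / 3600.0
        lam = rate * hours
        lo, hi = poisson.ppf([0.025, 0.975], lam)
        detected = dta_analysis.summary.sigh_rate_per_h * hours
        assert lo <= detected <= hi


class TestQuietWake:
    def test_recording_opening_with_calm_wake_selected_at_zero(self):
        labels = ["WAKE"] * 60 + ["NREM"] * 60
        emg = np.array([5.0] * 30 + [20.0] * 30 + [2.0] * 60)
        iv = select_quiet_wake(labels, emg, window_s=60.0)
        assert iv is not None and iv.start_s == 0.0

    def test_all_nrem_not_found(self):
        labels = ["NREM"] * 100
        assert select_quiet_wake(labels, np.ones(100)) is None

    def test_scripted_calm_onset_recovered(self, dta_recording,
                                           dta_analysis):
        truth = dta_recording.truth
        iv = dta_analysis.quiet_wake
        assert iv is not None
        # scripted quiet-wake opening bout
        quiet = truth.quiet_wake_epochs
        labels = np.asarray(truth.true_labels)
        first = quiet & (labels == "WAKE")
        end = np.flatnonzero(~first[:len(labels)])[0] * 5.0
        overlap = max(0.0, min(iv.end_s, end) - max(iv.start_s, 0.0))
        assert overlap >= 0.8 * min(end, iv.end_s - iv.start_s)

    def test_denominator_requires_sleep_or_quiet_wake(self):
        breaths = _uniform_breaths(50)
        with pytest.raises(ValueError):
            sigh_rate_per_hour(breaths, [], np.array([]))
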