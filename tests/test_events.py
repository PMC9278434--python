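import numpy as np
import pytest

from somnoresp import (DesatCalibration, baseline_ventilation,
                       calibrate_min_event_duration, compute_summary,
                       detect_events)
from somnoresp.breath import VentilationSeries
from somnoresp.events import RespiratoryEvent, associate_arousals
from somnoresp.staging import Hypnogram
from somnoresp.validate import match_events

IBI = 0.5  # breath interval used by the constructed traces


def _vent_from_ve(ve, ibi=IBI):
    n = len(ve)
    t = np.arange(n) * ibi
    ve = np.asarray(ve, dtype=float)
    vt = ve * ibi / 60.0
    return VentilationSeries(t, vt, ve, np.array([0.0]),
                             np.array([60.0 / ibi]), np.array([np.nan]))


def _hyp(labels):
    return Hypnogram(list(labels), [])


def _nrem_hyp_for(vent):
    n_epochs = int(np.ceil((vent.breath_times_s[-1] + IBI) / 5.0))
    return _hyp(["NREM"] * n_epochs)


def _dips(base=340.0, n=1200, dips=()):
    """Constant ve with (start_index, n_breaths, depth) dips."""
    ve = np.full(n, base)
    for start, count, depth in dips:
        ve[start:start + count] = base * (1.0 - depth)
    return ve


class TestBaseline:
    def test_constant_ve_baseline_is_constant(self):
        vent = _vent_from_ve(_dips())
        base = baseline_ventilation(vent, _nrem_hyp_for(vent))
        np.testing.assert_allclose(base, 340.0, rtol=1e-9)

    def test_event_masking_leaves_baseline_unchanged(self):
        """A single deep 3 s event must not drag the rolling median down:
        compare against the baseline of the identical event-free trace."""
        clean = _vent_from_ve(_dips())
        dipped = _vent_from_ve(_dips(dips=[(600, 6, 0.95)]))
        b_clean = baseline_ventilation(clean, _nrem_hyp_for(clean))
        b_dip = baseline_ventilation(dipped, _nrem_hyp_for(dipped))
        np.testing.assert_allclose(b_dip, b_clean, rtol=0.01)

    def test_baseline_tracks_linear_drift(self):
        n = 1200
        ve = 340.0 + 0.5 * np.arange(n) * IBI  # slow upward drift
        vent = _vent_from_ve(ve)
        base = baseline_ventilation(vent, _nrem_hyp_for(vent))
        lag = base - ve
        # rolling median over the preceding 60 s lags by at most the window
        assert np.all(np.abs(lag[150:]) <= 0.5 * 60.0 + 1e-9)


class TestDetectEvents:
    def test_no_dips_no_events(self):
        vent = _vent_from_ve(_dips())
        hyp = _nrem_hyp_for(vent)
        base = baseline_ventilation(vent, hyp)
        assert detect_events(vent, base, hyp) == []

    def test_threshold_and_duration_semantics(self):
        """Four scripted dips: only the deep 3 s dip (apnoea) and the
        0.6-depth 3 s dip (hypopnoea) qualify; 1.5 s fails the duration
        rule and depth 0.3 fails the >50% rule."""
        dips = [(200, 6, 0.95),   # 3.0 s, depth 0.95 -> apnoea
                (400, 6, 0.60),   # 3.0 s, depth 0.60 -> hypopnoea
                (600, 3, 0.95),   # 1.5 s -> too short
                (800, 20, 0.30)]  # 10 s but only 30% reduction
        vent = _vent_from_ve(_dips(dips=dips))
        hyp = _nrem_hyp_for(vent)
        base = baseline_ventilation(vent, hyp)
        events = detect_events(vent, base, hyp)
        assert [e.kind for e in events] == ["apnoea", "hypopnoea"]
        assert all(e.state == "NREM" for e in events)
        assert events[0].duration_s == pytest.approx(3.0, abs=IBI)
        assert events[0].depth == pytest.approx(0.95, abs=0.02)

    def test_wake_onset_events_discarded(self):
        vent = _vent_from_ve(_dips(n=400, dips=[(100, 6, 0.95)]))
        n_epochs = int(np.ceil(400 * IBI / 5.0))
        hyp = _hyp(["WAKE"] * n_epochs)
        base = baseline_ventilation(vent, hyp)
        assert detect_events(vent, base, hyp) == []

    def test_invalid_thresholds_rejected(self):
        vent = _vent_from_ve(_dips(n=100))
        hyp = _nrem_hyp_for(vent)
        base = baseline_ventilation(vent, hyp)
        with pytest.raises(ValueError):
            detect_events(vent, base, hyp, hypopnoea_frac=0.5,
                          apnoea_frac=0.4)

    def test_more_permissive_threshold_never_fewer_events(self):
        dips = [(200, 6, 0.95), (400, 6, 0.45), (700, 8, 0.65)]
        vent = _vent_from_ve(_dips(dips=dips))
        hyp = _nrem_hyp_for(vent)
        base = baseline_ventilation(vent, hyp)
        n_strict = len(detect_events(vent, base, hyp, hypopnoea_frac=0.5))
        n_loose = len(detect_events(vent, base, hyp, hypopnoea_frac=0.4))
        assert n_loose >= n_strict

    def test_longer_min_duration_never_more_events(self):
        dips = [(200, 6, 0.95), (500, 4, 0.8)]
        vent = _vent_from_ve(_dips(dips=dips))
        hyp = _nrem_hyp_for(vent)
        base = baseline_ventilation(vent, hyp)
        n_short = len(detect_events(vent, base, hyp, min_duration_s=1.8))
        n_long = len(detect_events(vent, base, hyp, min_duration_s=2.6))
        assert n_long <= n_short

    def test_events_sorted_and_disjoint(self, dta_analysis):
        ev = dta_analysis.events
        for a, b in zip(ev[:-1], ev[1:]):
            assert a.start_s < b.start_s
            assert a.end_s <= b.start_s

    def test_kind_partition_matches_depth(self, dta_analysis):
        for e in dta_analysis.events:
            assert e.kind in ("apnoea", "hypopnoea")
            assert e.depth > 0.5


class TestSummary:
    def _events(self, n_nrem, n_rem, dur_nrem, dur_rem):
        ev = []
        t = 100.0
        for _ in range(n_nrem):
            ev.append(RespiratoryEvent(t, t + dur_nrem, "hypopnoea", 0.6,
                                       "NREM"))
            t += 30.0
        for _ in range(n_rem):
            ev.append(RespiratoryEvent(t, t + dur_rem, "hypopnoea", 0.6,
                                       "REM"))
            t += 30.0
        return ev

    def test_printed_per_state_rates_compose(self):
        """21 NREM + 9 REM events/h of total sleep with 47 + 27 s/h
        dyspnoeic must summarise to AHI 30, 74 s/h, and a ~70% NREM
        share."""
        hyp = _hyp(["NREM"] * 504 + ["REM"] * 216)  # exactly 1 h sleep
        events = self._events(21, 9, 47.0 / 21, 27.0 / 9)
        s = compute_summary(events, hyp)
        assert s.ahi_per_h_sleep["total"] == pytest.approx(30.0)
        assert s.ahi_per_h_sleep["NREM"] == pytest.approx(21.0)
        assert s.ahi_per_h_sleep["REM"] == pytest.approx(9.0)
        assert s.dyspnoea_s_per_h_sleep["total"] == pytest.approx(74.0)
        assert s.ahi_per_h_sleep["NREM"] / s.ahi_per_h_sleep["total"] \
            == pytest.approx(0.70)

    def test_30_events_in_one_hour_is_ahi_30(self):
        hyp = _hyp(["NREM"] * 720)
        events = self._events(30, 0, 2.5, 0)
        assert compute_summary(events, hyp).ahi_per_h_sleep["total"] \
            == pytest.approx(30.0)

    def test_zero_sleep_rejected(self):
        with pytest.raises(ValueError):
            compute_summary([], _hyp(["WAKE"] * 100))

    def test_conservation_on_pipeline_run(self, dta_analysis):
        s = dta_analysis.summary
        assert s.ahi_per_h_sleep["total"] == pytest.approx(
            s.ahi_per_h_sleep["NREM"] + s.ahi_per_h_sleep["REM"])
        assert s.dyspnoea_s_per_h_sleep["total"] == pytest.approx(
            s.dyspnoea_s_per_h_sleep["NREM"]
            + s.dyspnoea_s_per_h_sleep["REM"])


class TestArousals:
    def test_no_wake_transitions_no_flags(self):
        vent = _vent_from_ve(_dips(n=400))
        hyp = _hyp(["NREM"] * 40)
        base = baseline_ventilation(vent, hyp)
        ev = [RespiratoryEvent(50.0, 53.0, "apnoea", 0.95, "NREM")]
        associate_arousals(ev, hyp, vent, base)
        assert not ev[0].followed_by_arousal

    def test_scripted_awakening_latency(self):
        # event ends at 52 s; WAKE starts at epoch 11 -> 55 s
        vent = _vent_from_ve(_dips(n=400))
        hyp = _hyp(["NREM"] * 11 + ["WAKE"] * 29)
        base = baseline_ventilation(vent, hyp)
        ev = [RespiratoryEvent(49.0, 52.0, "apnoea", 0.95, "NREM")]
        associate_arousals(ev, hyp, vent, base)
        assert ev[0].followed_by_arousal
        assert ev[0].arousal_latency_s == pytest.approx(3.0)

    def test_scripted_hyperpnoea_classified(self, dta_recording,
                                            dta_analysis):
        """Events the generator scripted with post-event hyperpnoea before
        an awakening should mostly be classified as hyperpnoea-associated."""
        linked = [e for e in dta_recording.truth.injected_events
                  if e.arousal_linked]
        assert linked
        hits = 0
        matched = 0
        for inj in linked:
            det = [d for d in dta_analysis.events
                   if d.start_s < inj.end_s and d.end_s > inj.start_s]
            if not det:
                continue
            matched += 1
            if det[0].followed_by_arousal \
                    and det[0].arousal_kind == "hyperpnoea":
                hits += 1
        assert matched >= 0.8 * len(linked)
        assert hits >= 0.9 * matched


class TestDesatCalibration:
    def test_exact_line(self):
        cal = DesatCalibration(points=((0.0, 100.0), (10.0, 90.0)),
                               resting_spo2_percent=100.0,
                               desat_criterion_percent=4.0)
        assert calibrate_min_event_duration(cal) == pytest.approx(4.0)

    @pytest.mark.parametrize("slope", [0.2, 0.4, 1.1])
    def test_matches_closed_form_for_any_slope(self, slope):
        """For points on spo2 = 99 - slope*d the extrapolated duration is
        criterion/slope exactly."""
        pts = ((10.0, 99.0 - 10 * slope), (15.0, 99.0 - 15 * slope))
        cal = DesatCalibration(points=pts, resting_spo2_percent=99.0,
                               desat_criterion_percent=4.0)
        assert calibrate_min_event_duration(cal) == pytest.approx(
            4.0 / slope)

    def test_nonnegative_slope_rejected(self):
        cal = DesatCalibration(points=((10.0, 90.0), (15.0, 95.0)))
        with pytest.raises(ValueError, match="slope"):
            calibrate_min_event_duration(cal)

    def test_intercept_mismatch_warns(self):
        cal = DesatCalibration(points=((10.0, 85.0), (15.0, 80.0)),
                               resting_spo2_percent=99.0)
        with pytest.warns(UserWarning, match="intercept"):
            calibrate_min_event_duration(cal)

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            DesatCalibration(points=((10.0, 90.0), (10.0, 92.0)))


class TestGroundTruthRecovery:
    def test_detected_events_match_injected(self, dta_recording,
                                            dta_analysis):
        m, nd, ni = match_events(dta_analysis.events,
                                 dta_recording.truth.injected_events)
        assert m / ni >= 0.9       # sensitivity
        assert m / nd >= 0.9       # precision
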