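"""End-to-end analysis of one recording: signals in, summary out.

Chains the stages in their natural order — staging features, adaptive
thresholds, hypnogram; breath segmentation, calibration, sighs;
per-breath ventilation, masked baseline, event detection and arousal
association; quiet-wake resting parameters — and returns every
intermediate product so callers can inspect or re-use any stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breath import (Breath, QuietWakeInterval, VentilationSeries,
                     compute_vt, detect_breaths, detect_sighs,
                     minute_ventilation, select_quiet_wake,
                     sigh_rate_per_hour)
from .events import (RecordingSummary, RespiratoryEvent, associate_arousals,
                     baseline_ventilation, compute_summary, detect_events)
from .io import CalibrationInfo, PipelineConfig, SignalTrace
from .staging import (Hypnogram, classify_epochs, extract_features,
                      fit_thresholds)

__all__ = ["RecordingAnalysis", "analyze_recording", "resting_parameters"]


@dataclass
class RecordingAnalysis:
    hypnogram: Hypnogram
    breaths: list[Breath]
    vent: VentilationSeries
    baseline: np.ndarray
    events: list[RespiratoryEvent]
    summary: RecordingSummary
    quiet_wake: QuietWakeInterval | None


def resting_parameters(breaths: list[Breath],
                       interval: QuietWakeInterval) -> dict:
    """Resting f, V_T and V_E over a quiet-wakefulness interval.

    V_E is the product of the interval's mean V_T and mean f, matching how
    the per-animal products are formed before group averaging.
    """
    sel = [b for b in breaths
           if interval.start_s <= b.t_peak_s < interval.end_s
           and np.isfinite(b.ibi_s) and b.ibi_s > 0 and not b.is_sigh]
    if len(sel) < 2:
        return {"f_bpm": float("nan"), "vt_ml_per_kg": float("nan"),
                "ve_ml_per_kg_per_min": float("nan")}
    f = float(np.mean([60.0 / b.ibi_s for b in sel]))
    vt = float(np.mean([b.vt_ml_per_kg for b in sel]))
    return {"f_bpm": f, "vt_ml_per_kg": vt,
            "ve_ml_per_kg_per_min": vt * f}


def analyze_recording(airflow: SignalTrace, eeg: SignalTrace,
                      emg: SignalTrace, calibration: CalibrationInfo,
                      config: PipelineConfig | None = None,
                      min_amplitude_fraction: float = 0.2
                      ) -> RecordingAnalysis:
    """Run the full scoring pipeline on one recording."""
    cfg = config or PipelineConfig()

    feats = extract_features(
        eeg, emg, delta_band=cfg.delta_band_hz, theta_band=cfg.theta_band_hz,
        tau_s=cfg.smoothing_tau_s, epoch_len_s=cfg.epoch_len_s)
    hyp = classify_epochs(feats, fit_thresholds(feats))

    breaths = detect_breaths(airflow,
                             min_amplitude_fraction=min_amplitude_fraction)
    compute_vt(breaths, calibration)
    if len(breaths) >= 20:
        detect_sighs(breaths, k_sigh=cfg.k_sigh)
    vent = minute_ventilation(breaths)

    baseline = baseline_ventilation(vent, hyp,
                                    window_s=cfg.baseline_window_s,
                                    hypopnoea_frac=cfg.hypopnoea_frac)
    events = detect_events(vent, baseline, hyp,
                           hypopnoea_frac=cfg.hypopnoea_frac,
                           apnoea_frac=cfg.apnoea_frac,
                           min_duration_s=cfg.min_duration_s)
    associate_arousals(events, hyp, vent, baseline,
                       arousal_window_s=cfg.arousal_window_s)

    emg_rms = np.array([f.emg_rms for f in feats])
    quiet = select_quiet_wake(hyp.labels, emg_rms)
    resting = resting_parameters(breaths, quiet) if quiet else None
    try:
        sigh_rate = sigh_rate_per_hour(breaths, hyp.labels, emg_rms)
    except ValueError:
        sigh_rate = None

    summary = compute_summary(events, hyp, vent, breaths,
                              resting=resting, sigh_rate=sigh_rate)
    return RecordingAnalysis(hyp, breaths, vent, baseline, events, summary,
                             quiet)
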