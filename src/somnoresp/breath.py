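"""Breath segmentation and ventilation metrics from an airflow trace.

A breath is one inspiration peak followed by one end-expiration trough.
Tidal volume (V_T) is the peak-minus-trough signal amplitude converted to
mL via volumetric calibration and normalised to body mass (mL/kg).
Respiratory frequency (f) is breaths per minute from peak-to-peak
intervals averaged over 1 min windows, and minute ventilation is
V_E = V_T x f (mL/kg/min), evaluated both per breath (instantaneous rate
60/IBI) and on the 1 min grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import CalibrationInfo, SignalTrace

__all__ = [
    "Breath",
    "VentilationSeries",
    "detect_breaths",
    "compute_vt",
    "compute_frequency",
    "minute_ventilation",
    "detect_sighs",
    "sigh_rate_per_hour",
    "select_quiet_wake",
]

EPOCH_S = 5.0


@dataclass
class Breath:
    t_peak_s: float
    t_trough_s: float
    amplitude_units: float
    vt_ml_per_kg: float = float("nan")
    ibi_s: float = float("nan")  # peak-to-peak to the next breath
    is_sigh: bool = False


@dataclass
class VentilationSeries:
    """Per-breath ventilation plus the 1 min aggregate series."""

    breath_times_s: np.ndarray
    vt_ml_per_kg: np.ndarray
    ve_ml_per_kg_per_min: np.ndarray      # per breath: vt * 60/ibi
    window_starts_s: np.ndarray
    f_bpm: np.ndarray                     # per 1 min window (nan = missing)
    ve_windowed: np.ndarray               # mean vt * window f


def detect_breaths(airflow: SignalTrace,
                   min_amplitude_fraction: float = 0.2,
                   min_ibi_s: float = 0.25,
                   lowpass_hz: float = 5.0) -> list[Breath]:
    """Segment the airflow trace into breaths.

    The trace is zero-phase low-pass filtered before peak picking (rodent
    breathing lives well below 5 Hz).  Candidate inspiration peaks closer
    than ``min_ibi_s`` are suppressed, each peak is paired with the deepest
    trough before the next peak, and breaths with amplitude below
    ``min_amplitude_fraction`` times the 10 s rolling median amplitude are
    discarded as noise.  A flat trace yields an empty list.
    """
    if airflow.duration_s < 2.0:
        raise ValueError("airflow trace must be at least 2 s long")
    if airflow.rate_hz < 20.0:
        raise ValueError("airflow sampling rate must be >= 20 Hz")
    fs = airflow.rate_hz
    x = airflow.samples
    if np.ptp(x) == 0:
        return []
    if lowpass_hz and lowpass_hz < fs / 2:
        sos = sps.butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)

    scale = float(np.std(x))
    if scale == 0:
        return []
    distance = max(1, int(round(min_ibi_s * fs)))
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=0.02 * scale)
    if peaks.size < 1:
        return []

    # pair each peak with the deepest trough before the following peak
    breaths: list[Breath] = []
    bounds = np.append(peaks[1:], x.size)
    for p, b in zip(peaks, bounds):
        if b - p < 2:
            continue
        seg = x[p:b]
        ti = p + int(np.argmin(seg))
        amp = float(x[p] - x[ti])
        if amp <= 0:
            continue
        breaths.append(Breath(t_peak_s=airflow.start_time_s + p / fs,
                              t_trough_s=airflow.start_time_s + ti / fs,
                              amplitude_units=amp))
    if not breaths:
        return []

    # rolling-median amplitude gate (10 s window, centred)
    amps = pd.Series([b.amplitude_units for b in breaths])
    t = np.array([b.t_peak_s for b in breaths])
    med_ibi = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    win = max(3, int(round(10.0 / max(med_ibi, 1e-6))))
    roll = amps.rolling(win, center=True, min_periods=1).median().to_numpy()
    keep = amps.to_numpy() >= min_amplitude_fraction * roll
    breaths = [b for b, k in zip(breaths, keep) if k]

    for b0, b1 in zip(breaths[:-1], breaths[1:]):
        b0.ibi_s = b1.t_peak_s - b0.t_peak_s
    return breaths


def compute_vt(breaths: list[Breath],
               calibration: CalibrationInfo) -> list[Breath]:
    """Fill vt_ml_per_kg = amplitude x ml_per_unit / body_mass_kg."""
    k = calibration.ml_per_unit / calibration.body_mass_kg
    for b in breaths:
        b.vt_ml_per_kg = b.amplitude_units * k
    return breaths


def compute_frequency(breaths: list[Breath], window_s: float = 60.0,
                      t_end: float | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Breaths/min per window: mean of 60/IBI over breaths whose
    inspiration peak falls in the window.  Windows containing no complete
    breath are NaN."""
    if len(breaths) < 2:
        return np.array([]), np.array([])
    t = np.array([b.t_peak_s for b in breaths])
    ibi = np.array([b.ibi_s for b in breaths])
    valid = np.isfinite(ibi) & (ibi > 0)
    t0 = t[0]
    t1 = t_end if t_end is not None else t[-1]
    starts = np.arange(t0, t1, window_s)
    f = np.full(starts.size, np.nan)
    for i, s in enumerate(starts):
        m = valid & (t >= s) & (t < s + window_s)
        if m.any():
            f[i] = np.mean(60.0 / ibi[m])
    return starts, f


def minute_ventilation(breaths: list[Breath],
                       window_s: float = 60.0) -> VentilationSeries:
    """Per-breath and 1 min windowed minute ventilation (V_E = V_T x f)."""
    if not breaths:
        raise ValueError("no breaths")
    if not np.isfinite(breaths[0].vt_ml_per_kg):
        raise ValueError("tidal volumes not populated; run compute_vt first")
    t = np.array([b.t_peak_s for b in breaths])
    vt = np.array([b.vt_ml_per_kg for b in breaths])
    ibi = np.array([b.ibi_s for b in breaths])
    ve = np.where(np.isfinite(ibi) & (ibi > 0), vt * 60.0 / ibi, np.nan)

    starts, f = compute_frequency(breaths, window_s)
    ve_win = np.full_like(f, np.nan)
    for i, s in enumerate(starts):
        m = (t >= s) & (t < s + window_s)
        if m.any() and np.isfinite(f[i]):
            ve_win[i] = float(np.mean(vt[m])) * f[i]
    return VentilationSeries(t, vt, ve, starts, f, ve_win)


def detect_sighs(breaths: list[Breath], k_sigh: float = 2.0,
                 window_breaths: int = 60) -> list[Breath]:
    """Flag sighs: breaths whose V_T exceeds ``k_sigh`` times the rolling
    median V_T over a 60-breath window."""
    if len(breaths) < 20:
        raise ValueError("need at least 20 breaths for a stable baseline")
    vt = pd.Series([b.vt_ml_per_kg for b in breaths])
    if not np.all(np.isfinite(vt)):
        raise ValueError("tidal volumes not populated; run compute_vt first")
    roll = vt.rolling(window_breaths, center=True,
                      min_periods=10).median().to_numpy()
    flags = vt.to_numpy() > k_sigh * roll
    for b, fl in zip(breaths, flags):
        b.is_sigh = bool(fl)
    return breaths


def sigh_rate_per_hour(breaths: list[Breath], labels: list[str],
                       epoch_emg_rms: np.ndarray) -> float:
    """Sighs per hour of sleep + quiet wakefulness.

    Quiet wakefulness = WAKE epochs with EMG RMS below the WAKE median.
    Only sighs occurring inside the denominator epochs are counted.
    """
    labels = list(labels)
    lab = np.asarray(labels)
    wake = lab == "WAKE"
    if wake.any():
        wake_med = float(np.median(epoch_emg_rms[wake]))
        quiet = wake & (epoch_emg_rms < wake_med)
    else:
        quiet = np.zeros(lab.size, dtype=bool)
    in_denom = np.isin(lab, ("NREM", "REM")) | quiet
    hours = in_denom.sum() * EPOCH_S / 3600.0
    if hours == 0:
        raise ValueError("no sleep or quiet wakefulness in recording")
    count = 0
    for b in breaths:
        if not b.is_sigh:
            continue
        i = int(b.t_peak_s // EPOCH_S)
        if 0 <= i < in_denom.size and in_denom[i]:
            count += 1
    return count / hours


@dataclass(frozen=True)
class QuietWakeInterval:
    start_s: float
    end_s: float


def select_quiet_wake(labels: list[str], epoch_emg_rms: np.ndarray,
                      window_s: float = 60.0) -> QuietWakeInterval | None:
    """Earliest run of >= window_s contiguous WAKE epochs whose EMG RMS is
    below the WAKE median; resting respiratory parameters are read here.
    Returns None when no qualifying interval exists."""
    lab = np.asarray(list(labels))
    if not (lab == "WAKE").any():
        return None
    wake_med = float(np.median(epoch_emg_rms[lab == "WAKE"]))
    ok = (lab == "WAKE") & (epoch_emg_rms < wake_med)
    need = int(np.ceil(window_s / EPOCH_S))
    run = 0
    for i, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run >= need:
            # extend to the full contiguous run
            j = i + 1
            while j < ok.size and ok[j]:
                j += 1
            return QuietWakeInterval((i - run + 1) * EPOCH_S, j * EPOCH_S)
    return None
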