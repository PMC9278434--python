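"""EEG/EMG sleep staging into 5 s epochs of WAKE/NREM/REM/DOUBT.

Features per epoch: delta (0-4 Hz) and theta (6-10 Hz) band power from
zero-phase band-pass filtered EEG, exponentially smoothed with a 5 s time
constant and sampled at epoch midpoints; EMG root-mean-square with the
same 5 s time constant.  The delta filter's low edge is set to 0.5 Hz in
practice to keep DC and movement drift out of the band.

Classification is rule-based, applied in a fixed order: high EMG means
WAKE regardless of EEG; otherwise high delta means NREM; otherwise a high
theta:delta ratio with muscle atonia (EMG in the bottom decile) means REM;
anything else is DOUBT.  Thresholds adapt to each recording so staging is
invariant to amplifier gain.  The delta and EMG thresholds are placed in
the gap between the feature's value clusters: the quantile ladder of the
feature is scanned for its first substantial log-spaced jump (sleep
cluster below, wake cluster above for EMG; wake/REM below, NREM above
for delta) and the threshold is the geometric midpoint of that jump.
Scanning for the gap rather than fixing a percentile rank keeps staging
correct when the wake/sleep split varies between animals.  The
theta:delta threshold, whose REM cluster is too small to show up in a
quantile ladder, is the midpoint of two bracketing percentile anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import SignalTrace

__all__ = [
    "EpochFeatures",
    "Hypnogram",
    "StagingThresholds",
    "SleepStager",
    "extract_features",
    "fit_thresholds",
    "classify_epochs",
    "summarize_hypnogram",
]

EPOCH_S = 5.0
WAKE, NREM, REM, DOUBT = "WAKE", "NREM", "REM", "DOUBT"


@dataclass
class EpochFeatures:
    epoch_index: int
    delta_power: float   # uV^2
    theta_power: float   # uV^2
    td_ratio: float      # theta/delta
    emg_rms: float       # uV


@dataclass
class Hypnogram:
    labels: list[str]
    features: list[EpochFeatures]
    epoch_len_s: float = EPOCH_S

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": [f.epoch_index for f in self.features],
            "start_s": [f.epoch_index * self.epoch_len_s
                        for f in self.features],
            "label": self.labels,
            "delta_power": [f.delta_power for f in self.features],
            "theta_power": [f.theta_power for f in self.features],
            "td_ratio": [f.td_ratio for f in self.features],
            "emg_rms": [f.emg_rms for f in self.features],
        })


def _band_power_series(x: np.ndarray, fs: float,
                       band: tuple[float, float], tau_s: float) -> np.ndarray:
    """Squared band-pass signal smoothed by a first-order exponential
    filter with time constant tau."""
    lo, hi = band
    lo = max(lo, 0.5)  # keep DC out of the delta band
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    p = sps.sosfiltfilt(sos, x) ** 2
    alpha = 1.0 - np.exp(-1.0 / (tau_s * fs))
    return sps.lfilter([alpha], [1.0, -(1.0 - alpha)], p)


def extract_features(eeg: SignalTrace, emg: SignalTrace,
                     delta_band: tuple[float, float] = (0.0, 4.0),
                     theta_band: tuple[float, float] = (6.0, 10.0),
                     tau_s: float = 5.0,
                     epoch_len_s: float = EPOCH_S) -> list[EpochFeatures]:
    """Per-epoch delta/theta band power and EMG RMS (see module docstring).

    The EEG rate must resolve the theta band (Nyquist above its upper
    edge); the last partial epoch is dropped.
    """
    if eeg.duration_s < 2 * epoch_len_s or emg.duration_s < 2 * epoch_len_s:
        raise ValueError("need at least two epochs of signal")
    if eeg.rate_hz < 2 * theta_band[1]:
        raise ValueError(
            f"EEG rate {eeg.rate_hz} Hz cannot resolve theta up to "
            f"{theta_band[1]} Hz")
    n_epochs = int(min(eeg.duration_s, emg.duration_s) // epoch_len_s)

    delta = _band_power_series(eeg.samples, eeg.rate_hz, delta_band, tau_s)
    theta = _band_power_series(eeg.samples, eeg.rate_hz, theta_band, tau_s)
    alpha = 1.0 - np.exp(-1.0 / (tau_s * emg.rate_hz))
    emg_p = sps.lfilter([alpha], [1.0, -(1.0 - alpha)], emg.samples ** 2)

    feats = []
    for i in range(n_epochs):
        mid_e = min(int((i + 0.5) * epoch_len_s * eeg.rate_hz),
                    delta.size - 1)
        mid_m = min(int((i + 0.5) * epoch_len_s * emg.rate_hz),
                    emg_p.size - 1)
        d = float(delta[mid_e])
        t = float(theta[mid_e])
        feats.append(EpochFeatures(
            epoch_index=i,
            delta_power=d,
            theta_power=t,
            td_ratio=t / d if d > 0 else float("inf"),
            emg_rms=float(np.sqrt(max(emg_p[mid_m], 0.0))),
        ))
    return feats


@dataclass(frozen=True)
class StagingThresholds:
    delta_hi: float
    emg_hi: float
    td_hi: float
    emg_atonia: float  # bottom-decile EMG bound used by the REM rule


def _cluster_gap_threshold(values: np.ndarray, lo_pct: float, hi_pct: float,
                           min_rel_gap: float = 0.5) -> float:
    """Threshold between a feature's value clusters.

    Scans the quantile ladder between ``lo_pct`` and ``hi_pct`` (2.5-point
    steps) for jumps in log-value and returns the geometric midpoint of
    the first jump at least ``min_rel_gap`` of the largest one.  Taking
    the first substantial jump (not the largest) matters for EMG, where
    the quiet/active wake split can open a second, higher gap; the
    boundary wanted is the lowest one, sleep vs any wakefulness.
    """
    qs = np.arange(lo_pct, hi_pct + 1e-9, 2.5)
    v = np.percentile(values, qs)
    v = np.maximum(v, np.max(v) * 1e-12)
    gaps = np.diff(np.log(v))
    gmax = float(np.max(gaps))
    if gmax <= 0:
        return float(np.sqrt(v[0] * v[-1]))
    k = int(np.flatnonzero(gaps >= min_rel_gap * gmax)[0])
    return float(np.sqrt(v[k] * v[k + 1]))


class SleepStager:
    """Adaptive rule-based sleep stager (fit thresholds, then predict).

    ``delta_range`` and ``emg_range`` bound the quantile ladders scanned
    for those features' cluster gaps; ``td_anchors`` are the percentile
    pair whose midpoint becomes the theta:delta threshold;
    ``atonia_percentile`` sets the EMG bound of the REM rule.  Defaults
    assume sleep and wake each occupy very roughly half the recording
    with a small REM share, which holds for the 3 h light-phase sessions
    this pipeline targets.
    """

    def __init__(self, delta_range=(35.0, 85.0), emg_range=(30.0, 85.0),
                 td_anchors=(50.0, 98.0), atonia_percentile: float = 10.0):
        self.delta_range = delta_range
        self.emg_range = emg_range
        self.td_anchors = td_anchors
        self.atonia_percentile = atonia_percentile

    def fit(self, features: list[EpochFeatures]) -> "SleepStager":
        if len(features) < 60:
            raise ValueError("need >= 60 epochs (5 min) to fit thresholds")
        delta = np.array([f.delta_power for f in features])
        emg = np.array([f.emg_rms for f in features])
        td = np.array([f.td_ratio for f in features])
        td = td[np.isfinite(td)]
        for name, v in (("delta_power", delta), ("emg_rms", emg),
                        ("td_ratio", td)):
            if v.size == 0 or np.ptp(v) == 0:
                raise ValueError(f"degenerate (constant) feature {name}")

        lo, hi = np.percentile(td, self.td_anchors)
        self.thresholds_ = StagingThresholds(
            delta_hi=_cluster_gap_threshold(delta, *self.delta_range),
            emg_hi=_cluster_gap_threshold(emg, *self.emg_range),
            td_hi=float((lo + hi) / 2.0),
            emg_atonia=float(np.percentile(emg, self.atonia_percentile)),
        )
        return self

    def predict(self, features: list[EpochFeatures]) -> list[str]:
        th = self.thresholds_
        labels = []
        for f in features:
            if f.emg_rms > th.emg_hi:
                labels.append(WAKE)
            elif f.delta_power > th.delta_hi:
                labels.append(NREM)
            elif f.td_ratio > th.td_hi and f.emg_rms <= th.emg_atonia:
                labels.append(REM)
            else:
                labels.append(DOUBT)
        return labels


def fit_thresholds(features: list[EpochFeatures],
                   **stager_kwargs) -> StagingThresholds:
    return SleepStager(**stager_kwargs).fit(features).thresholds_


def classify_epochs(features: list[EpochFeatures],
                    thresholds: StagingThresholds) -> Hypnogram:
    stager = SleepStager()
    stager.thresholds_ = thresholds
    return Hypnogram(stager.predict(features), features)


def stage_recording(eeg: SignalTrace, emg: SignalTrace,
                    **stager_kwargs) -> Hypnogram:
    """Convenience: features -> fitted thresholds -> hypnogram."""
    feats = extract_features(eeg, emg)
    return classify_epochs(feats, fit_thresholds(feats, **stager_kwargs))


def summarize_hypnogram(hypnogram: Hypnogram) -> dict:
    """State fractions over scored (non-DOUBT) epochs, total sleep hours
    (NREM + REM only) and per-state bout statistics."""
    labels = np.asarray(hypnogram.labels)
    if labels.size == 0:
        raise ValueError("empty hypnogram")
    scored = labels != DOUBT
    if not scored.any():
        raise ValueError("all epochs are DOUBT; nothing to summarise")
    n_scored = int(scored.sum())
    fractions = {s: float((labels == s).sum() / n_scored)
                 for s in (WAKE, NREM, REM)}
    sleep_hours = float(np.isin(labels, (NREM, REM)).sum()
                        * hypnogram.epoch_len_s / 3600.0)

    bouts: dict[str, list[int]] = {WAKE: [], NREM: [], REM: []}
    i = 0
    while i < labels.size:
        j = i
        while j < labels.size and labels[j] == labels[i]:
            j += 1
        if labels[i] in bouts:
            bouts[labels[i]].append(j - i)
        i = j
    bout_stats = {
        s: {"n_bouts": len(v),
            "mean_bout_s": float(np.mean(v) * hypnogram.epoch_len_s)
            if v else float("nan")}
        for s, v in bouts.items()}
    return {
        "fractions": fractions,
        "sleep_hours": sleep_hours,
        "doubt_fraction": float((~scored).sum() / labels.size),
        "bouts": bout_stats,
    }
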