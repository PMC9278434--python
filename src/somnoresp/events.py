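"""Apnoea/hypopnoea detection on the per-breath ventilation series.

A respiratory disturbance is a reduction in minute ventilation by more
than 50% (hypopnoea) or more than 90% (apnoea) of the local baseline,
sustained for at least 1.8 s, during sleep.  Ventilation is evaluated
breath by breath (ve_i = vt_i x 60/ibi_i) so events a few breaths long are
resolvable; the baseline is a rolling median over the preceding 60 s with
candidate events masked out (two passes), making it robust to the events
themselves.

The apnoea-hypopnoea index (AHI) and per-state dyspnoea durations are all
normalised by TOTAL sleep hours (NREM + REM, excluding DOUBT), including
when reported per sleep state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .breath import Breath, VentilationSeries
from .staging import Hypnogram

__all__ = [
    "RespiratoryEvent",
    "RecordingSummary",
    "DesatCalibration",
    "baseline_ventilation",
    "detect_events",
    "compute_summary",
    "associate_arousals",
    "calibrate_min_event_duration",
]

EPOCH_S = 5.0
WAKE, NREM, REM, DOUBT = "WAKE", "NREM", "REM", "DOUBT"
SLEEP = (NREM, REM)


@dataclass
class RespiratoryEvent:
    start_s: float
    end_s: float
    kind: str                     # "apnoea" | "hypopnoea"
    depth: float                  # max fractional V_E reduction, (0, 1]
    state: str                    # sleep state of the onset epoch
    followed_by_arousal: bool = False
    arousal_latency_s: float | None = None
    arousal_kind: str | None = None  # "hyperpnoea" | "coincident"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class RecordingSummary:
    ahi_per_h_sleep: dict        # {"total", "NREM", "REM"}
    dyspnoea_s_per_h_sleep: dict
    mean_event_duration_s: dict
    sleep_hours: float
    state_fractions: dict
    resting: dict | None = None  # {"f_bpm", "vt_ml_per_kg", "ve_..."}
    sigh_rate_per_h: float | None = None


def _label_at(hypnogram: Hypnogram, t: float) -> str:
    i = int(t // hypnogram.epoch_len_s)
    i = min(max(i, 0), len(hypnogram.labels) - 1)
    lab = hypnogram.labels[i]
    if lab != DOUBT:
        return lab
    # DOUBT means "could not classify", not "awake": inherit the nearest
    # scored epoch's state for event assignment
    for off in range(1, len(hypnogram.labels)):
        for j in (i - off, i + off):
            if 0 <= j < len(hypnogram.labels) \
                    and hypnogram.labels[j] != DOUBT:
                return hypnogram.labels[j]
    return lab


def _rolling_median_prev(t: np.ndarray, v: np.ndarray, mask: np.ndarray,
                         window_s: float) -> np.ndarray:
    """Median of masked-in values over the preceding ``window_s`` at each
    breath; the first window falls back to the median of the first
    window_s of (masked) data."""
    out = np.empty(t.size)
    start_med_m = mask & (t <= t[0] + window_s)
    start_med = float(np.median(v[start_med_m])) if start_med_m.any() \
        else float(np.median(v))
    j0 = 0
    for i in range(t.size):
        while t[j0] < t[i] - window_s:
            j0 += 1
        m = mask[j0:i + 1]
        if t[i] - t[0] < window_s or not m.any():
            out[i] = start_med
        else:
            out[i] = float(np.median(v[j0:i + 1][m]))
    return out


def baseline_ventilation(vent: VentilationSeries, hypnogram: Hypnogram,
                         window_s: float = 60.0,
                         hypopnoea_frac: float = 0.5) -> np.ndarray:
    """Baseline V_E at each breath: rolling median over the preceding
    window, computed in two passes — a provisional pass flags candidate
    event breaths (below (1 - hypopnoea_frac) x provisional baseline),
    which are masked out of the final pass so deep events do not drag the
    reference down."""
    t = vent.breath_times_s
    ve = vent.ve_ml_per_kg_per_min
    finite = np.isfinite(ve)
    v = np.where(finite, ve, np.nanmedian(ve))
    base0 = _rolling_median_prev(t, v, finite, window_s)
    in_event = finite & (v < (1.0 - hypopnoea_frac) * base0)
    return _rolling_median_prev(t, v, finite & ~in_event, window_s)


def detect_events(vent: VentilationSeries, baseline: np.ndarray,
                  hypnogram: Hypnogram, hypopnoea_frac: float = 0.5,
                  apnoea_frac: float = 0.9, min_duration_s: float = 1.8
                  ) -> list[RespiratoryEvent]:
    """Maximal runs of breaths with ve below (1 - hypopnoea_frac) x
    baseline, kept if they last >= min_duration_s and start during sleep.

    A run's interval spans from its first low breath to the first
    recovered breath (each breath owns [t_i, t_next)).  Runs separated by
    less than one typical breath are merged before the duration test.
    kind = apnoea iff ve stays below (1 - apnoea_frac) x baseline for
    >= min_duration_s somewhere within the run; depth = 1 - min(ve)/base.
    Events whose onset epoch is not a sleep state are discarded.
    """
    if not (0.0 < hypopnoea_frac < apnoea_frac <= 1.0):
        raise ValueError("need 0 < hypopnoea_frac < apnoea_frac <= 1")
    t = vent.breath_times_s
    ve = vent.ve_ml_per_kg_per_min
    n = t.size
    if n < 2:
        return []
    # each breath covers [t_i, t_{i+1}); the last gets the median IBI
    med_ibi = float(np.median(np.diff(t)))
    t_next = np.append(t[1:], t[-1] + med_ibi)
    low = np.isfinite(ve) & (ve < (1.0 - hypopnoea_frac) * baseline)

    # maximal runs of low breaths
    runs = []
    i = 0
    while i < n:
        if low[i]:
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs separated by less than one typical breath
    merged = []
    for r in runs:
        if merged and t[r[0]] - t_next[merged[-1][1]] < med_ibi:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)

    events = []
    for i, j in merged:
        start, end = float(t[i]), float(t_next[j])
        if end - start < min_duration_s:
            continue
        state = _label_at(hypnogram, start)
        if state not in SLEEP:
            continue
        seg_ve = ve[i:j + 1]
        seg_base = baseline[i:j + 1]
        depth = float(1.0 - np.nanmin(seg_ve / seg_base))
        # apnoea: deep criterion sustained >= min_duration_s within the run
        deep = seg_ve < (1.0 - apnoea_frac) * seg_base
        kind = "hypopnoea"
        k = 0
        while k <= j - i:
            if deep[k]:
                m = k
                while m + 1 <= j - i and deep[m + 1]:
                    m += 1
                if t_next[i + m] - t[i + k] >= min_duration_s:
                    kind = "apnoea"
                    break
                k = m + 1
            else:
                k += 1
        events.append(RespiratoryEvent(start, end, kind,
                                       min(depth, 1.0), state))
    return events


def compute_summary(events: list[RespiratoryEvent], hypnogram: Hypnogram,
                    vent: VentilationSeries | None = None,
                    breaths: list[Breath] | None = None,
                    resting: dict | None = None,
                    sigh_rate: float | None = None) -> RecordingSummary:
    """Per-recording AHI and dyspnoea summary.

    All rates — total and per sleep state — use total sleep hours
    (NREM + REM epochs, DOUBT excluded) as the denominator.
    """
    labels = np.asarray(hypnogram.labels)
    sleep_epochs = np.isin(labels, SLEEP)
    sleep_hours = float(sleep_epochs.sum() * hypnogram.epoch_len_s / 3600.0)
    if sleep_hours == 0:
        raise ValueError("no sleep in hypnogram; AHI undefined")

    counts = {s: sum(1 for e in events if e.state == s) for s in SLEEP}
    secs = {s: sum(e.duration_s for e in events if e.state == s)
            for s in SLEEP}
    durs = {s: [e.duration_s for e in events if e.state == s] for s in SLEEP}

    ahi = {s: counts[s] / sleep_hours for s in SLEEP}
    ahi["total"] = len(events) / sleep_hours
    assert abs(ahi["total"] - ahi[NREM] - ahi[REM]) < 1e-9
    dys = {s: secs[s] / sleep_hours for s in SLEEP}
    dys["total"] = sum(e.duration_s for e in events) / sleep_hours
    assert abs(dys["total"] - dys[NREM] - dys[REM]) < 1e-9

    scored = labels != DOUBT
    n_scored = int(scored.sum())
    fractions = {s: float((labels == s).sum() / n_scored)
                 for s in (WAKE, NREM, REM)}
    mean_dur = {s: float(np.mean(durs[s])) if durs[s] else float("nan")
                for s in SLEEP}
    mean_dur["total"] = (float(np.mean([e.duration_s for e in events]))
                         if events else float("nan"))
    return RecordingSummary(
        ahi_per_h_sleep=ahi,
        dyspnoea_s_per_h_sleep=dys,
        mean_event_duration_s=mean_dur,
        sleep_hours=sleep_hours,
        state_fractions=fractions,
        resting=resting,
        sigh_rate_per_h=sigh_rate,
    )


def associate_arousals(events: list[RespiratoryEvent], hypnogram: Hypnogram,
                       vent: VentilationSeries, baseline: np.ndarray,
                       arousal_window_s: float = 15.0
                       ) -> list[RespiratoryEvent]:
    """Flag events followed by an arousal (sleep -> WAKE transition) within
    ``arousal_window_s`` of event end.

    An arousal is a transition into WAKE from sleep; intervening DOUBT
    epochs are skipped (an unclassifiable epoch between sleep and
    wakefulness is still an awakening from sleep).  The arousal is
    classified "hyperpnoea" when mean ve either in the 5 s before the
    awakening or in the 5 s after event end exceeds 1.2 x baseline (a
    recovery overshoot; the second window covers awakenings the stager
    registers an epoch late), or "coincident" when the awakening epoch
    contains the event end.
    """
    labels = hypnogram.labels
    eplen = hypnogram.epoch_len_s
    arousal_times = []
    for i in range(1, len(labels)):
        if labels[i] != WAKE:
            continue
        j = i - 1
        while j >= 0 and labels[j] == DOUBT:
            j -= 1
        if j >= 0 and labels[j] in SLEEP:
            arousal_times.append(i * eplen)
    t = vent.breath_times_s
    ve = vent.ve_ml_per_kg_per_min
    for e in events:
        after = [a for a in arousal_times
                 if e.end_s <= a <= e.end_s + arousal_window_s]
        # an awakening inside the event's final epoch also counts
        containing = [a for a in arousal_times
                      if a - eplen <= e.end_s < a + eplen]
        cand = sorted(set(after) | set(containing))
        if not cand:
            continue
        a = cand[0]
        e.followed_by_arousal = True
        e.arousal_latency_s = max(0.0, a - e.end_s)
        windows = [(a - 5.0, a), (e.end_s, e.end_s + 5.0)]
        hyper = False
        for w0, w1 in windows:
            m = (t >= w0) & (t < w1) & np.isfinite(ve)
            if m.any():
                base = float(np.median(baseline[m]))
                if base > 0 and float(np.mean(ve[m])) > 1.2 * base:
                    hyper = True
                    break
        if hyper:
            e.arousal_kind = "hyperpnoea"
            continue
        ep_of_end = int(e.end_s // eplen)
        ep_of_arousal = int(a // eplen)
        e.arousal_kind = ("coincident"
                          if ep_of_end in (ep_of_arousal, ep_of_arousal - 1)
                          else "other")
    return events


@dataclass(frozen=True)
class DesatCalibration:
    """SpO2 vs apnoea-duration points used to extrapolate the shortest
    event that would desaturate by the clinical criterion."""

    points: tuple[tuple[float, float], ...]  # (duration_s, spo2_percent)
    resting_spo2_percent: float = 99.0
    desat_criterion_percent: float = 4.0

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("need >= 2 calibration points")
        durs = [d for d, _ in self.points]
        if len(set(durs)) < 2:
            raise ValueError("calibration points need distinct durations")
        if any(not (0 < s <= 100) for _, s in self.points):
            raise ValueError("SpO2 must be in (0, 100]")


def calibrate_min_event_duration(cal: DesatCalibration) -> float:
    """Least-squares line spo2 = a + b*duration through the calibration
    points; returns the duration at which saturation falls
    ``desat_criterion`` below resting.  The slope must be negative."""
    d = np.array([p[0] for p in cal.points])
    s = np.array([p[1] for p in cal.points])
    b, a = np.polyfit(d, s, 1)
    if b >= 0:
        raise ValueError("calibration line must have negative slope")
    if abs(a - cal.resting_spo2_percent) > 1.0:
        import warnings
        warnings.warn(
            f"fitted intercept {a:.2f}% differs from resting SpO2 "
            f"{cal.resting_spo2_percent}% by more than 1 point",
            stacklevel=2)
    target = cal.resting_spo2_percent - cal.desat_criterion_percent
    return float((target - a) / b)
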