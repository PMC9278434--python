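"""Recovery metrics against generator ground truth.

These helpers score a pipeline run against what the synthetic generator
actually injected: epoch-level staging accuracy (with the epoch on each
side of every true state transition excluded, since 5 s smoothing makes
those genuinely ambiguous), event sensitivity/precision by interval
overlap, and absolute errors of AHI and REM fraction.
"""

from __future__ import annotations

import numpy as np

from .events import RespiratoryEvent
from .simulate import GroundTruth

__all__ = [
    "epoch_accuracy",
    "match_events",
    "event_recovery",
    "rem_fraction_error",
    "recomputed_event_depth",
]


def recomputed_event_depth(recording) -> list[float]:
    """Measured V_E reduction of each injected event, re-derived from the
    raw airflow via breath detection and the event-detection baseline.

    Uses a permissive breath-amplitude gate so the tiny breaths inside
    deep events are retained (meaningful on low-noise recordings).
    """
    from .breath import compute_vt, detect_breaths, minute_ventilation
    from .events import baseline_ventilation
    from .io import CalibrationInfo
    from .staging import Hypnogram

    protocol = recording.truth.protocol
    breaths = detect_breaths(recording.airflow, min_amplitude_fraction=0.02)
    compute_vt(breaths, CalibrationInfo(protocol.ml_per_unit,
                                        protocol.body_mass_kg))
    vent = minute_ventilation(breaths)
    hyp = Hypnogram(list(recording.truth.true_labels), [])
    base = baseline_ventilation(vent, hyp)
    t = vent.breath_times_s
    ve = vent.ve_ml_per_kg_per_min
    out = []
    for e in recording.truth.injected_events:
        inside = (t >= e.start_s) & (t < e.end_s) & np.isfinite(ve)
        if not inside.any():
            out.append(1.0)  # breaths fully suppressed: total reduction
            continue
        out.append(float(1.0 - np.min(ve[inside] / base[inside])))
    return out


def epoch_accuracy(true_labels: list[str], pred_labels: list[str],
                   exclude_transition_adjacent: bool = True) -> float:
    """Fraction of epochs where predicted label equals the scripted one."""
    n = min(len(true_labels), len(pred_labels))
    t = np.asarray(true_labels[:n])
    p = np.asarray(pred_labels[:n])
    mask = np.ones(n, dtype=bool)
    if exclude_transition_adjacent:
        change = np.flatnonzero(t[1:] != t[:-1])  # transition between i,i+1
        mask[change] = False
        mask[change + 1] = False
    if not mask.any():
        return float("nan")
    return float((t[mask] == p[mask]).mean())


def match_events(detected: list[RespiratoryEvent],
                 injected) -> tuple[int, int, int]:
    """Greedy one-to-one interval-overlap matching.

    Returns (n_matched, n_detected, n_injected).  ``injected`` is a list
    of objects with start_s/end_s (generator InjectedEvent records).
    """
    used = [False] * len(injected)
    matched = 0
    for d in detected:
        for k, inj in enumerate(injected):
            if used[k]:
                continue
            if d.start_s < inj.end_s and d.end_s > inj.start_s:
                used[k] = True
                matched += 1
                break
    return matched, len(detected), len(injected)


def event_recovery(detected: list[RespiratoryEvent],
                   truth: GroundTruth) -> dict:
    """Sensitivity, precision and AHI error of detected vs injected."""
    m, nd, ni = match_events(detected, truth.injected_events)
    sleep_hours = sum(1 for l in truth.true_labels
                      if l in ("NREM", "REM")) * 5.0 / 3600.0
    return {
        "sensitivity": m / ni if ni else float("nan"),
        "precision": m / nd if nd else float("nan"),
        "n_detected": nd,
        "n_injected": ni,
        "detected_ahi": nd / sleep_hours if sleep_hours else float("nan"),
        "injected_ahi": ni / sleep_hours if sleep_hours else float("nan"),
    }


def rem_fraction_error(true_labels: list[str],
                       pred_labels: list[str]) -> float:
    """|detected - scripted| REM fraction (detected over scored epochs)."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels[:t.size])
    true_frac = (t == "REM").mean()
    scored = p != "DOUBT"
    if not scored.any():
        return float("nan")
    pred_frac = (p[scored] == "REM").mean()
    return float(abs(pred_frac - true_frac))
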