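"""Synthetic plethysmography recordings with known ground truth.

The generator emulates a 3 h rodent whole-body plethysmography session with
simultaneous EEG/EMG: a scripted WAKE/NREM/REM architecture, a per-breath
airflow waveform whose rate and amplitude are state-modulated, injected
ventilation-reduction events (apnoeas/hypopnoeas) confined to sleep, sighs,
and band-structured EEG with state-dependent muscle tone.  Everything
injected is recorded in a :class:`GroundTruth` so downstream detectors can
be validated by recovery rather than by eye.

Sleep architecture is a semi-Markov chain with exponential bout dwell
times; REM is entered only from NREM.  Transition probabilities are solved
at run time from the requested long-run state fractions and mean dwell
times, so the scripted fractions converge to the protocol's.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import signal as sps

from .io import SignalTrace, write_timeseries_csv, write_edf

EPOCH_S = 5.0

WAKE, NREM, REM, DOUBT = "WAKE", "NREM", "REM", "DOUBT"

# Per-state EEG component amplitudes, uV RMS: (delta, theta, broadband).
# NREM is delta-dominated, REM theta-dominated with muscle atonia; chosen
# at contrasts typical of rodent cortical screw recordings.
EEG_GAINS = {WAKE: (20.0, 22.0, 25.0), NREM: (70.0, 18.0, 18.0),
             REM: (12.0, 45.0, 12.0)}
# EMG RMS, uV: active wake, quiet wake, NREM, REM (atonia).
EMG_RMS = {"active": 40.0, "quiet": 18.0, NREM: 7.0, REM: 1.5}

# Breathing modulation relative to quiet wakefulness.
STATE_BREATH = {WAKE: (1.0, 1.0), NREM: (0.92, 1.05), REM: (1.06, 0.90)}

HYPERPNOEA_GAIN = 1.5     # amplitude factor of post-event recovery breaths
HYPERPNOEA_LEAD_S = 5.5   # event end precedes the scripted awakening by this
SIGH_GAIN = 2.5           # a sigh is one augmented breath


class PlacementError(RuntimeError):
    """Raised when injected events cannot be placed without overlap."""


class SimulationProtocol(BaseModel):
    """Generator settings for one synthetic recording.

    Defaults are the "sham" operating point of the rat model this package
    was built around: ~3 h sessions, resting frequency ~95 breaths/min,
    tidal volume ~3.6 mL/kg, sleep occupying about half the recording with
    a small REM share, and a low background event rate.
    """

    model_config = ConfigDict(extra="forbid")

    duration_s: float = 10800.0
    sample_rate_hz: float = 100.0
    resting_f_bpm: float = 95.0
    resting_vt_ml_per_kg: float = 3.6
    body_mass_kg: float = 0.40
    ml_per_unit: float = 1.0
    state_fractions: dict[str, float] = {WAKE: 0.46, NREM: 0.48, REM: 0.06}
    state_dwell_s: dict[str, float] = {WAKE: 150.0, NREM: 140.0, REM: 55.0}
    event_rate_per_h_sleep: float = 9.0
    apnoea_fraction: float = 0.4
    rem_event_fraction: float = 0.3
    rem_arousal_fraction: float = 0.5
    event_duration_s: tuple[float, float] = (1.9, 2.7)
    sigh_rate_per_h: float = 13.0
    noise_sd: float = 0.1
    line_noise_hz: float | None = None
    breath_jitter_cv: float = 0.03
    modulate_by_state: bool = True
    quiet_wake_onset_s: float = 120.0
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SimulationProtocol":
        fr = self.state_fractions
        if set(fr) != {WAKE, NREM, REM}:
            raise ValueError("state_fractions must map WAKE, NREM, REM")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("state_fractions must sum to 1")
        if any(v < 0 for v in fr.values()):
            raise ValueError("state fractions must be non-negative")
        if any(v == 1.0 for v in fr.values()) and any(
                0 < v < 1 for v in fr.values()):
            raise ValueError("a state fraction of 1.0 excludes all others")
        if fr[REM] > 0 and fr[NREM] == 0:
            raise ValueError("REM requires NREM (REM is entered from NREM)")
        if self.sample_rate_hz < 40.0:
            raise ValueError("sample_rate_hz must be >= 40 (4x theta edge)")
        for name in ("duration_s", "resting_f_bpm", "resting_vt_ml_per_kg",
                     "body_mass_kg", "ml_per_unit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("event_rate_per_h_sleep", "sigh_rate_per_h",
                     "noise_sd", "apnoea_fraction", "rem_event_fraction",
                     "rem_arousal_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.event_duration_s
        if not (0 < lo <= hi):
            raise ValueError("event_duration_s must satisfy 0 < min <= max")
        return self


def sham_protocol(**overrides) -> SimulationProtocol:
    """Sham-operated preset: f 95, V_T 3.6 mL/kg, AHI ~9/h."""
    return SimulationProtocol(**overrides)


def dta_protocol(**overrides) -> SimulationProtocol:
    """Lesioned ("DTA") preset: f 105, V_T 2.3 mL/kg, AHI ~30/h, REM 4%."""
    base = dict(
        resting_f_bpm=105.0,
        resting_vt_ml_per_kg=2.3,
        state_fractions={WAKE: 0.52, NREM: 0.44, REM: 0.04},
        state_dwell_s={WAKE: 185.0, NREM: 140.0, REM: 50.0},
        event_rate_per_h_sleep=30.0,
        sigh_rate_per_h=14.0,
    )
    base.update(overrides)
    return SimulationProtocol(**base)


PRESETS = {"sham": sham_protocol, "dta": dta_protocol}


@dataclass
class InjectedEvent:
    start_s: float
    end_s: float
    depth: float
    state: str
    arousal_linked: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class GroundTruth:
    """Everything the generator injected, for recovery testing."""

    true_labels: list[str]
    quiet_wake_epochs: np.ndarray  # bool per epoch
    injected_events: list[InjectedEvent]
    injected_sighs: list[float]
    n_breaths: int
    protocol: SimulationProtocol

    def to_json(self, path: str | Path) -> None:
        doc = {
            "true_labels": self.true_labels,
            "quiet_wake_epochs": self.quiet_wake_epochs.astype(int).tolist(),
            "injected_events": [
                {"start_s": e.start_s, "end_s": e.end_s, "depth": e.depth,
                 "state": e.state, "arousal_linked": e.arousal_linked}
                for e in self.injected_events],
            "injected_sighs": list(self.injected_sighs),
            "n_breaths": self.n_breaths,
            "protocol": self.protocol.model_dump(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))


@dataclass
class SyntheticRecording:
    airflow: SignalTrace
    eeg: SignalTrace
    emg: SignalTrace
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_timeseries_csv(self.airflow, out / "airflow.csv")
        write_edf([self.eeg], out / "eeg.edf")
        write_edf([self.emg], out / "emg.edf")
        self.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# Sleep architecture
# ---------------------------------------------------------------------------

def _transition_matrix(fractions: dict[str, float],
                       dwell: dict[str, float]) -> dict[str, dict[str, float]]:
    """Solve semi-Markov transition probabilities so long-run time-in-state
    matches ``fractions`` given mean bout ``dwell`` times.

    Structure: WAKE->NREM; NREM->{WAKE, REM}; REM->{WAKE, NREM}.  Balance of
    bout visit rates pi_i = fractions_i / dwell_i gives the two free
    probabilities in closed form.
    """
    pi = {s: fractions[s] / dwell[s] for s in (WAKE, NREM, REM)
          if fractions[s] > 0}
    if REM not in pi:
        return {WAKE: {NREM: 1.0}, NREM: {WAKE: 1.0}}
    a_nr = pi[REM] / pi[NREM]
    a_rw = 1.0 + (pi[WAKE] - pi[NREM]) / pi[REM]
    if not (0.0 <= a_nr <= 1.0 and 0.0 <= a_rw <= 1.0):
        raise ValueError(
            "state_fractions and state_dwell_s are jointly infeasible for a "
            "WAKE->NREM->REM architecture; adjust mean dwell times")
    return {
        WAKE: {NREM: 1.0},
        NREM: {REM: a_nr, WAKE: 1.0 - a_nr},
        REM: {WAKE: a_rw, NREM: 1.0 - a_rw},
    }


def _script_architecture(protocol: SimulationProtocol, seed: int
                         ) -> tuple[list[str], np.ndarray]:
    """Labels per 5 s epoch plus a quiet-wake flag per epoch.

    The recording opens with a quiet-WAKE bout (if WAKE occurs at all) so
    that resting respiratory parameters can be measured at the start, as in
    the experimental protocol; later WAKE bouts are quiet or active with
    equal probability.
    """
    rng = np.random.default_rng(seed)
    n_epochs = int(protocol.duration_s // EPOCH_S)
    fr = protocol.state_fractions

    active = [s for s in (WAKE, NREM, REM) if fr[s] > 0]
    if len(active) == 1:
        labels = [active[0]] * n_epochs
        quiet = np.zeros(n_epochs, dtype=bool)
        if active[0] == WAKE:
            quiet[:] = True
        return labels, quiet

    trans = _transition_matrix(fr, protocol.state_dwell_s)
    labels: list[str] = []
    quiet = np.zeros(n_epochs, dtype=bool)
    state = WAKE if fr[WAKE] > 0 else NREM
    first_wake = True
    while len(labels) < n_epochs:
        mean_dwell = protocol.state_dwell_s[state]
        dwell = rng.exponential(mean_dwell)
        if state == WAKE and first_wake:
            dwell = max(dwell, protocol.quiet_wake_onset_s)
        n = max(1, int(round(dwell / EPOCH_S)))
        if state == WAKE:
            is_quiet = True if first_wake else bool(rng.random() < 0.5)
            quiet[len(labels):len(labels) + n] = is_quiet
            first_wake = False
        labels.extend([state] * n)
        nxt = trans.get(state, {})
        if not nxt:
            break
        states, probs = zip(*nxt.items())
        state = str(rng.choice(states, p=probs))
    return labels[:n_epochs], quiet[:n_epochs]


def script_hypnogram(protocol: SimulationProtocol, seed: int | None = None
                     ) -> list[str]:
    """Scripted state sequence at 5 s epoch resolution."""
    if seed is None:
        seed = protocol.seed
    labels, _ = _script_architecture(protocol, seed)
    return labels


def _bouts(labels: Sequence[str]) -> list[tuple[str, float, float]]:
    """(state, start_s, end_s) runs of a label sequence."""
    out = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        out.append((labels[i], i * EPOCH_S, j * EPOCH_S))
        i = j
    return out


# ---------------------------------------------------------------------------
# Event and sigh placement
# ---------------------------------------------------------------------------

def _place_events(protocol: SimulationProtocol, labels: list[str],
                  rng: np.random.Generator) -> list[InjectedEvent]:
    sleep_hours = sum(1 for l in labels if l in (NREM, REM)) * EPOCH_S / 3600
    n_events = int(round(protocol.event_rate_per_h_sleep * sleep_hours))
    if n_events == 0:
        return []

    bouts = _bouts(labels)
    margin = 2.0            # keep events clear of bout edges
    min_sep = 4.0           # and of each other
    lo, hi = protocol.event_duration_s

    def draw_depth() -> float:
        # Depths clear of the 0.9 scoring boundary so injected kind is
        # unambiguous: apnoeas >90% reduction, hypopnoeas 55-88%.
        if rng.random() < protocol.apnoea_fraction:
            return float(rng.uniform(0.92, 1.0))
        return float(rng.uniform(0.55, 0.88))

    def draw_duration(state: str) -> float:
        d = float(rng.uniform(lo, hi))
        return d * 1.25 if state == REM else d

    events: list[InjectedEvent] = []

    def overlaps(s: float, e: float) -> bool:
        return any(ev.start_s - min_sep < e and ev.end_s + min_sep > s
                   for ev in events)

    # Arousal-linked REM events sit at the tail of REM bouts that the
    # architecture already terminates into WAKE, leaving room for the
    # post-event hyperpnoea that precedes the awakening.
    n_rem = int(round(n_events * protocol.rem_event_fraction))
    rem_wake_bouts = [
        (s0, s1) for k, (st, s0, s1) in enumerate(bouts)
        if st == REM and k + 1 < len(bouts) and bouts[k + 1][0] == WAKE]
    rng.shuffle(rem_wake_bouts)
    n_linked = int(round(n_rem * protocol.rem_arousal_fraction))
    for s0, s1 in rem_wake_bouts[:n_linked]:
        dur = draw_duration(REM)
        end = s1 - HYPERPNOEA_LEAD_S
        start = end - dur
        if start < s0 + margin or overlaps(start, end):
            continue
        events.append(InjectedEvent(start, end, draw_depth(), REM,
                                    arousal_linked=True))

    targets = [REM] * (n_rem - sum(e.state == REM for e in events))
    targets += [NREM] * (n_events - n_rem)
    def try_place(state: str, bout_states: tuple[str, ...],
                  n_tries: int) -> bool:
        cand = [(st, s0, s1) for st, s0, s1 in bouts if st in bout_states]
        if not cand:
            return False
        lengths = np.array([s1 - s0 for _, s0, s1 in cand])
        for _ in range(n_tries):
            dur = draw_duration(state)
            ok = lengths > dur + 2 * margin
            if not ok.any():
                return False
            w = np.where(ok, lengths, 0.0)
            k = rng.choice(len(cand), p=w / w.sum())
            st, s0, s1 = cand[k]
            start = float(rng.uniform(s0 + margin, s1 - margin - dur))
            if not overlaps(start, start + dur):
                events.append(InjectedEvent(start, start + dur,
                                            draw_depth(), st))
                return True
        return False

    for state in targets:
        # prefer the requested state's bouts; if they are saturated the
        # event spills into any sleep bout rather than being dropped
        if not (try_place(state, (state,), 200)
                or try_place(state, (NREM, REM), 200)):
            raise PlacementError(
                f"could not place {n_events} events of rate "
                f"{protocol.event_rate_per_h_sleep}/h without overlap")
    events.sort(key=lambda e: e.start_s)
    return events


def _place_sighs(protocol: SimulationProtocol, labels: list[str],
                 quiet: np.ndarray, events: list[InjectedEvent],
                 rng: np.random.Generator) -> list[float]:
    eligible = [i for i, l in enumerate(labels)
                if l in (NREM, REM) or (l == WAKE and quiet[i])]
    if not eligible:
        return []
    hours = len(eligible) * EPOCH_S / 3600
    n = rng.poisson(protocol.sigh_rate_per_h * hours)
    times: list[float] = []
    guard = 5.0
    for _ in range(int(n)):
        for _ in range(100):
            ep = int(rng.choice(eligible))
            t = ep * EPOCH_S + float(rng.uniform(0.5, EPOCH_S - 0.5))
            near_event = any(e.start_s - guard < t < e.end_s + guard
                             for e in events)
            near_sigh = any(abs(t - s) < guard for s in times)
            if not near_event and not near_sigh:
                times.append(t)
                break
    return sorted(times)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _state_at(labels: list[str], t: float) -> str:
    i = min(int(t // EPOCH_S), len(labels) - 1)
    return labels[i]


def _synth_airflow(protocol: SimulationProtocol, labels: list[str],
                   events: list[InjectedEvent], sighs: list[float],
                   rng: np.random.Generator) -> tuple[np.ndarray, int]:
    fs = protocol.sample_rate_hz
    n = int(round(protocol.duration_s * fs))
    flow = np.zeros(n)
    amp_rest = (protocol.resting_vt_ml_per_kg * protocol.body_mass_kg
                / protocol.ml_per_unit)
    hyper = [(e.end_s, e.end_s + HYPERPNOEA_LEAD_S) for e in events
             if e.arousal_linked]
    sigh_q = list(sighs)

    t = 0.0
    n_breaths = 0
    while t < protocol.duration_s:
        state = _state_at(labels, t)
        f_fac, a_fac = STATE_BREATH[state] if protocol.modulate_by_state \
            else (1.0, 1.0)
        cv = protocol.breath_jitter_cv * (2.0 if state == REM else 1.0)
        period = 60.0 / (protocol.resting_f_bpm * f_fac)
        period *= max(0.5, 1.0 + cv * rng.standard_normal())
        amp = amp_rest * a_fac * (1.0 + cv * rng.standard_normal())

        peak_t = t + period / 4
        for e in events:
            if e.start_s <= peak_t < e.end_s:
                amp *= (1.0 - e.depth)
                break
        else:
            if any(h0 <= peak_t < h1 for h0, h1 in hyper):
                amp *= HYPERPNOEA_GAIN
            elif sigh_q and t <= sigh_q[0] < t + period:
                amp *= SIGH_GAIN
                sigh_q.pop(0)

        i0 = int(round(t * fs))
        i1 = min(int(round((t + period) * fs)), n)
        if i1 > i0:
            tau = (np.arange(i0, i1) / fs - t) / period
            flow[i0:i1] = (amp / 2.0) * np.sin(2 * np.pi * tau)
        # a breath counts only when its expiration trough (at 3T/4) lies
        # inside the trace; a cut-off final cycle is not a scoreable breath
        if t + 0.75 * period < protocol.duration_s:
            n_breaths += 1
        t += period

    if protocol.noise_sd > 0:
        flow += rng.normal(0.0, protocol.noise_sd * amp_rest, size=n)
    return flow, n_breaths


def _unit_band_noise(n: int, fs: float, band: tuple[float, float] | None,
                     rng: np.random.Generator) -> np.ndarray:
    x = rng.standard_normal(n)
    if band is not None:
        sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def _synth_eeg_emg(protocol: SimulationProtocol, labels: list[str],
                   quiet: np.ndarray, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    fs = protocol.sample_rate_hz
    n = int(round(protocol.duration_s * fs))
    delta = _unit_band_noise(n, fs, (0.5, 4.0), rng)
    theta = _unit_band_noise(n, fs, (6.0, 10.0), rng)
    broad = _unit_band_noise(n, fs, None, rng)
    emg_w = _unit_band_noise(n, fs, None, rng)

    g_d = np.empty(n)
    g_t = np.empty(n)
    g_b = np.empty(n)
    g_m = np.empty(n)
    spe = int(round(EPOCH_S * fs))  # samples per epoch
    for i, lab in enumerate(labels):
        sl = slice(i * spe, min((i + 1) * spe, n))
        gd, gt, gb = EEG_GAINS[lab]
        g_d[sl], g_t[sl], g_b[sl] = gd, gt, gb
        if lab == WAKE:
            g_m[sl] = EMG_RMS["quiet"] if quiet[i] else EMG_RMS["active"]
        else:
            g_m[sl] = EMG_RMS[lab]
    tail = slice(len(labels) * spe, n)
    if tail.start < n:  # past the last full epoch: hold the final state
        g_d[tail], g_t[tail], g_b[tail] = EEG_GAINS[labels[-1]]
        g_m[tail] = g_m[tail.start - 1]

    eeg = g_d * delta + g_t * theta + g_b * broad
    emg = g_m * emg_w
    if protocol.line_noise_hz:
        tt = np.arange(n) / fs
        line = 10.0 * np.sin(2 * np.pi * protocol.line_noise_hz * tt)
        eeg += line
        emg += line
    return eeg, emg


def simulate_recording(protocol: SimulationProtocol,
                       seed: int | None = None) -> SyntheticRecording:
    """Generate airflow + EEG + EMG with full ground truth."""
    if seed is None:
        seed = protocol.seed
    labels, quiet = _script_architecture(protocol, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5eed]))
    events = _place_events(protocol, labels, rng)
    sighs = _place_sighs(protocol, labels, quiet, events, rng)
    flow, n_breaths = _synth_airflow(protocol, labels, events, sighs, rng)
    eeg, emg = _synth_eeg_emg(protocol, labels, quiet, rng)
    truth = GroundTruth(labels, quiet, events, sighs, n_breaths, protocol)
    fs = protocol.sample_rate_hz
    return SyntheticRecording(
        airflow=SignalTrace(flow, fs, label="airflow", units="units"),
        eeg=SignalTrace(eeg, fs, label="EEG", units="uV"),
        emg=SignalTrace(emg, fs, label="EMG", units="uV"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Maze path prototypes
# ---------------------------------------------------------------------------

def simulate_maze_path(strategy: str, geometry, seed: int = 0,
                       n_exit_errors: int = 0, speed_cm_s: float = 20.0):
    """Prototype Barnes-maze trajectory following one search strategy.

    ``spatial``: straight approach to within two holes of the exit, staying
    inside the exit quadrant.  ``serial``: hole-by-hole progression along
    the perimeter into the exit.  ``random``: hops between distant holes
    with >= 2 open-field crossings.  ``n_exit_errors`` inserts abortive
    visits to the exit hole before the terminal one.
    """
    from .maze import MazeTrajectory

    if geometry.kind != "barnes":
        raise ValueError("simulate_maze_path requires a Barnes geometry")
    rng = np.random.default_rng(seed)
    holes = geometry.hole_positions()
    n_holes = len(holes)
    exit_i = geometry.exit_index
    center = np.asarray(geometry.center, dtype=float)
    dt = 0.1

    waypoints: list[np.ndarray] = []

    def hole_pt(i: int, pull: float = 0.0) -> np.ndarray:
        p = holes[i % n_holes]
        return p + pull * (center - p) / np.linalg.norm(center - p)

    if strategy == "spatial":
        k = int(rng.choice([-1, 1]))
        waypoints = [center, hole_pt(exit_i + k), hole_pt(exit_i)]
    elif strategy == "serial":
        step = int(rng.choice([-1, 1]))
        m = int(rng.integers(4, 8))
        start = exit_i - step * m
        waypoints = [hole_pt(start + step * j) for j in range(m + 1)]
    elif strategy == "random":
        far = [(exit_i + n_holes // 2 + int(rng.integers(-2, 3))) % n_holes
               for _ in range(2)]
        side = (exit_i + 2) % n_holes
        waypoints = [center, hole_pt(far[0]), center, hole_pt(side),
                     center, hole_pt(far[1]), center, hole_pt(exit_i)]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    if n_exit_errors > 0:
        retreat = hole_pt(exit_i, pull=20.0)
        tail = []
        for _ in range(n_exit_errors):
            tail += [hole_pt(exit_i), retreat]
        waypoints = waypoints[:-1] + tail + [hole_pt(exit_i)]

    pts = [waypoints[0]]
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        d = float(np.linalg.norm(b - a))
        n_seg = max(2, int(math.ceil(d / (speed_cm_s * dt))))
        for j in range(1, n_seg + 1):
            pts.append(a + (b - a) * j / n_seg)
        # brief dwell at each waypoint so hole visits register
        pts.extend([b] * 3)
    pos = np.asarray(pts)
    times = np.arange(len(pos)) * dt
    return MazeTrajectory(times_s=times, positions=pos, geometry=geometry)


def simulate_ymaze_path(arm_sequence: Sequence[str], geometry, seed: int = 0,
                        dwell_s: float = 2.0, speed_cm_s: float = 20.0):
    """Scripted Y-maze run: centre -> arm end -> centre for each arm label."""
    from .maze import MazeTrajectory

    if geometry.kind != "ymaze":
        raise ValueError("simulate_ymaze_path requires a Y-maze geometry")
    dt = 0.1
    center = np.zeros(2)
    pts = [center]
    for label in arm_sequence:
        tip = geometry.arm_tip(label)
        for target in (tip, center):
            a = pts[-1]
            d = float(np.linalg.norm(target - a))
            n_seg = max(2, int(math.ceil(d / (speed_cm_s * dt))))
            for j in range(1, n_seg + 1):
                pts.append(a + (target - a) * j / n_seg)
            pts.extend([target] * int(dwell_s / dt))
    pos = np.asarray(pts)
    times = np.arange(len(pos)) * dt
    return MazeTrajectory(times_s=times, positions=pos, geometry=geometry)
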