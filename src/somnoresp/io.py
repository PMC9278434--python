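"""File I/O and run configuration.

Airflow traces travel as plain CSV (``time_s,flow``) because plethysmograph
exports vary by vendor; EEG/EMG use EDF, the standard polysomnography
container.  EDF files are read through :mod:`mne`; writing uses a minimal
EDF header/record encoder because no installed library exports EDF.

All timestamps are seconds from recording start.  Epochs are 0-based,
half-open intervals ``[i*5, (i+1)*5)``.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "SignalTrace",
    "CalibrationInfo",
    "PipelineConfig",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_edf",
    "write_edf",
    "load_config",
]


@dataclass
class SignalTrace:
    """A uniformly sampled physiological channel (airflow, EEG, or EMG)."""

    samples: np.ndarray
    rate_hz: float
    start_time_s: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"non-finite samples in trace {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.samples.size) / self.rate_hz


@dataclass(frozen=True)
class CalibrationInfo:
    """Volumetric calibration: signal units -> mL, normalised to body mass."""

    ml_per_unit: float
    body_mass_kg: float

    def __post_init__(self) -> None:
        if self.ml_per_unit <= 0 or self.body_mass_kg <= 0:
            raise ValueError("ml_per_unit and body_mass_kg must be positive")


# ---------------------------------------------------------------------------
# CSV time series
# ---------------------------------------------------------------------------

def read_timeseries_csv(
    path: str | Path,
    time_col: str = "time_s",
    value_col: str = "flow",
    label: str = "",
    units: str = "",
    jitter_tol: float = 0.01,
) -> SignalTrace:
    """Read a two-column time series and infer the sampling rate.

    The time column must be strictly increasing and uniformly spaced to
    within ``jitter_tol`` (relative to the median step).
    """
    df = pd.read_csv(path)
    for col in (time_col, value_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    t = df[time_col].to_numpy(dtype=float)
    x = df[value_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in {path}")
    if t.size < 2:
        raise ValueError("need at least two samples to infer a rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > jitter_tol * med:
        raise ValueError("non-uniform sampling beyond tolerance")
    return SignalTrace(x, rate_hz=1.0 / med, start_time_s=float(t[0]),
                       label=label or value_col, units=units)


def write_timeseries_csv(trace: SignalTrace, path: str | Path,
                         time_col: str = "time_s",
                         value_col: str = "flow") -> None:
    pd.DataFrame({time_col: trace.times_s, value_col: trace.samples}).to_csv(
        path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(traces: Sequence[SignalTrace], path: str | Path,
              record_duration_s: float = 1.0) -> None:
    """Write channels to EDF (16-bit, one data record per second).

    All traces must share an integer number of samples per record.  Values
    are scaled to the per-channel physical min/max, so the roundtrip error
    is at most one 16-bit quantisation step.
    """
    path = Path(path)
    ns = len(traces)
    spr = []  # samples per record
    for tr in traces:
        n = tr.rate_hz * record_duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"rate {tr.rate_hz} Hz not integer per {record_duration_s}s record")
        spr.append(int(round(n)))
    n_records = min(int(tr.samples.size // s) for tr, s in zip(traces, spr))
    if n_records < 1:
        raise ValueError("traces shorter than one data record")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii", "replace")[:n]
        return b + b" " * (n - len(b))

    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate X X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8),
        pad("EDF", 44),
        pad(str(n_records), 8),
        pad(f"{record_duration_s:g}", 8),
        pad(str(ns), 4),
    ])

    phys_min, phys_max = [], []
    for tr in traces:
        lo, hi = float(np.min(tr.samples)), float(np.max(tr.samples))
        if hi <= lo:  # constant channel: give it a token span
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)

    def col(vals, n):
        return b"".join(pad(v, n) for v in vals)

    header += col([tr.label or f"ch{i}" for i, tr in enumerate(traces)], 16)
    header += col(["" for _ in traces], 80)  # transducer
    header += col([tr.units or "" for tr in traces], 8)
    header += col([f"{v:.6g}" for v in phys_min], 8)
    header += col([f"{v:.6g}" for v in phys_max], 8)
    header += col(["-32768" for _ in traces], 8)
    header += col(["32767" for _ in traces], 8)
    header += col(["" for _ in traces], 80)  # prefiltering
    header += col([str(s) for s in spr], 8)
    header += col(["" for _ in traces], 32)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        digitised = []
        for tr, lo, hi in zip(traces, phys_min, phys_max):
            gain = 65535.0 / (hi - lo)
            d = np.round((tr.samples - lo) * gain - 32768.0)
            digitised.append(np.clip(d, -32768, 32767).astype("<i2"))
        for r in range(n_records):
            for d, s in zip(digitised, spr):
                fh.write(d[r * s:(r + 1) * s].tobytes())


def read_edf(path: str | Path, channel: str) -> SignalTrace:
    """Read one channel from an EDF file, in its physical units."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise KeyError(
            f"channel {channel!r} not in {path} (has {raw.ch_names})")
    raw = raw.pick([channel])
    raw.load_data(verbose="error")
    data = raw.get_data()[0]
    # mne rescales channels it recognises (EEG/EMG) to SI volts; undo that
    # so samples come back in the units the EDF header declares.
    unit = _edf_physical_dimension(path, channel)
    kind = raw.get_channel_types()[0]
    if kind in ("eeg", "emg", "eog", "ecg") and unit.lower() in ("uv", "µv"):
        data = data * 1e6
    return SignalTrace(data, rate_hz=float(raw.info["sfreq"]),
                       label=channel, units=unit)


def _edf_physical_dimension(path: str | Path, channel: str) -> str:
    """Pull one channel's physical-dimension field from the EDF header."""
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        ns = int(hdr[252:256].decode("ascii").strip())
        sig = fh.read(256 * ns)
    labels = [sig[16 * i:16 * (i + 1)].decode("ascii").strip()
              for i in range(ns)]
    off = ns * (16 + 80)  # labels then transducer fields precede dimensions
    dims = [sig[off + 8 * i:off + 8 * (i + 1)].decode("ascii").strip()
            for i in range(ns)]
    for lab, dim in zip(labels, dims):
        if lab == channel:
            return dim
    return ""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class PipelineConfig(BaseModel):
    """Validated analysis thresholds and bands; defaults follow the scoring
    conventions of the source study (>50% / >90% ventilation reduction for
    at least 1.8 s; delta 0-4 Hz, theta 6-10 Hz; 5 s epochs and smoothing).
    """

    model_config = ConfigDict(extra="forbid")

    hypopnoea_frac: float = 0.50
    apnoea_frac: float = 0.90
    min_duration_s: float = 1.8
    delta_band_hz: tuple[float, float] = (0.0, 4.0)
    theta_band_hz: tuple[float, float] = (6.0, 10.0)
    epoch_len_s: float = 5.0
    smoothing_tau_s: float = 5.0
    baseline_window_s: float = 60.0
    k_sigh: float = 2.0
    arousal_window_s: float = 15.0

    @model_validator(mode="after")
    def _check_ranges(self) -> "PipelineConfig":
        if not (0.0 < self.hypopnoea_frac < self.apnoea_frac <= 1.0):
            raise ValueError(
                "need 0 < hypopnoea_frac < apnoea_frac <= 1, got "
                f"{self.hypopnoea_frac} / {self.apnoea_frac}")
        if self.min_duration_s <= 0 or self.epoch_len_s <= 0:
            raise ValueError("durations must be positive")
        for lo, hi in (self.delta_band_hz, self.theta_band_hz):
            if not (0 <= lo < hi):
                raise ValueError(f"invalid band ({lo}, {hi})")
        return self


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a JSON run configuration; unknown keys are rejected and missing
    keys are filled with the documented defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        doc = json.load(fh)
    return PipelineConfig(**doc)
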