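"""Barnes-maze and Y-maze trajectory scoring.

Inputs are pre-tracked single-point coordinates (video-tracking exports).
Barnes scoring counts hole visits, exit errors (visits to the escape hole
that did not end the trial) and classifies the search strategy as spatial,
serial or random.  Y-maze scoring detects arm entries via a
penetration-depth proxy for the two-paw rule and computes novel-arm
preference and discrimination ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BarnesGeometry",
    "YMazeGeometry",
    "MazeTrajectory",
    "detect_hole_visits",
    "count_exit_errors",
    "classify_search_strategy",
    "detect_arm_entries",
    "novelty_metrics",
    "occupancy_heatmap",
    "total_distance",
]

STRATEGIES = ("random", "serial", "spatial")


@dataclass(frozen=True)
class BarnesGeometry:
    """Circular maze with equally spaced perimeter holes.

    Defaults follow the standard rat apparatus: 122 cm diameter, 20 holes
    of 9 cm diameter (4.5 cm radius) on a ring just inside the rim.
    """

    radius_cm: float = 61.0
    n_holes: int = 20
    exit_index: int = 0
    hole_radius_cm: float = 4.5
    hole_ring_radius_cm: float | None = None
    center: tuple[float, float] = (0.0, 0.0)

    kind = "barnes"

    def __post_init__(self) -> None:
        if self.n_holes < 3:
            raise ValueError("need at least 3 holes")
        if not (0 <= self.exit_index < self.n_holes):
            raise ValueError("exit_index out of range")

    @property
    def ring_radius(self) -> float:
        return (self.hole_ring_radius_cm
                if self.hole_ring_radius_cm is not None
                else self.radius_cm - self.hole_radius_cm - 5.0)

    def hole_positions(self) -> np.ndarray:
        ang = 2 * np.pi * np.arange(self.n_holes) / self.n_holes
        c = np.asarray(self.center)
        return c + self.ring_radius * np.column_stack(
            [np.cos(ang), np.sin(ang)])

    def hole_angle(self, index: int) -> float:
        return 2 * np.pi * (index % self.n_holes) / self.n_holes


@dataclass(frozen=True)
class YMazeGeometry:
    """Three arms radiating from a centre at 120 degrees.

    ``arm_labels`` maps roles (entry / open / novel) to the arms in angular
    order starting at ``start_angle_deg``.
    """

    arm_length_cm: float = 50.0
    arm_width_cm: float = 10.0
    arm_labels: tuple[str, str, str] = ("entry", "open", "novel")
    start_angle_deg: float = 90.0

    kind = "ymaze"

    def __post_init__(self) -> None:
        if len(set(self.arm_labels)) != 3:
            raise ValueError("arm_labels must be three distinct labels")

    def arm_axes(self) -> dict[str, np.ndarray]:
        out = {}
        for i, lab in enumerate(self.arm_labels):
            a = math.radians(self.start_angle_deg + 120.0 * i)
            out[lab] = np.array([math.cos(a), math.sin(a)])
        return out

    def arm_tip(self, label: str) -> np.ndarray:
        return self.arm_axes()[label] * self.arm_length_cm


@dataclass
class MazeTrajectory:
    """Tracked positions (cm) at strictly increasing times (s)."""

    times_s: np.ndarray
    positions: np.ndarray  # (n, 2)
    geometry: BarnesGeometry | YMazeGeometry

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if self.times_s.size != self.positions.shape[0]:
            raise ValueError("times and positions length mismatch")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        tol = 5.0
        if self.geometry.kind == "barnes":
            r = np.linalg.norm(
                self.positions - np.asarray(self.geometry.center), axis=1)
            if np.any(r > self.geometry.radius_cm + tol):
                raise ValueError("positions outside maze bounds + 5 cm")
        else:
            r = np.linalg.norm(self.positions, axis=1)
            if np.any(r > self.geometry.arm_length_cm + tol):
                raise ValueError("positions outside maze bounds + 5 cm")

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


def total_distance(traj: MazeTrajectory) -> float:
    """Summed Euclidean path length, cm."""
    return float(np.sum(np.linalg.norm(np.diff(traj.positions, axis=0),
                                       axis=1)))


# ---------------------------------------------------------------------------
# Barnes maze
# ---------------------------------------------------------------------------

def detect_hole_visits(traj: MazeTrajectory) -> list[tuple[float, int]]:
    """Ordered (time, hole index) visits: a visit starts when the tracked
    point enters a hole's radius from outside it; consecutive samples in
    the same hole extend one visit."""
    geom = traj.geometry
    if geom.kind != "barnes":
        raise ValueError("detect_hole_visits requires a Barnes geometry")
    holes = geom.hole_positions()
    d = np.linalg.norm(traj.positions[:, None, :] - holes[None, :, :],
                       axis=2)
    inside = d <= geom.hole_radius_cm
    nearest = np.argmin(d, axis=1)
    visits: list[tuple[float, int]] = []
    current = -1
    for i in range(traj.times_s.size):
        if inside[i].any():
            h = int(nearest[i])
            if h != current:
                visits.append((float(traj.times_s[i]), h))
                current = h
        else:
            current = -1
    return visits


def count_exit_errors(visits: list[tuple[float, int]],
                      exit_index: int) -> int:
    """Visits to the exit hole that did not end the trial.  The terminal
    visit, when it is to the exit hole, is the successful escape."""
    idx = [h for _, h in visits]
    if not idx:
        return 0
    n_exit = sum(1 for h in idx if h == exit_index)
    return n_exit - 1 if idx[-1] == exit_index else n_exit


def _count_field_crossings(traj: MazeTrajectory,
                           core_fraction: float = 0.5) -> int:
    """Traversals of the open field: the path enters the inner disc
    (radius core_fraction x maze radius) and leaves on the other half
    (entry and exit points subtend more than 90 degrees)."""
    geom = traj.geometry
    c = np.asarray(geom.center)
    p = traj.positions - c
    r = np.linalg.norm(p, axis=1)
    core = r < core_fraction * geom.radius_cm
    crossings = 0
    i = 0
    n = r.size
    while i < n:
        if core[i]:
            j = i
            while j + 1 < n and core[j + 1]:
                j += 1
            entry = p[i - 1] if i > 0 else p[i]
            exit_ = p[j + 1] if j + 1 < n else p[j]
            if float(np.dot(entry, exit_)) < 0:
                crossings += 1
            i = j + 1
        else:
            i += 1
    return crossings


def classify_search_strategy(traj: MazeTrajectory,
                             visits: list[tuple[float, int]] | None = None,
                             exit_index: int | None = None,
                             detailed: bool = False):
    """Classify a Barnes trial as spatial, serial or random.

    spatial: the first hole visited is within two holes of the exit and
    the whole path stays inside the 90-degree quadrant centred on the
    exit.  serial: some run of >= 3 hole visits steps hole-by-hole in one
    direction.  random: >= 2 open-field crossings.  Precedence is
    spatial > serial > random; a trial matching none of the rules falls
    back to random (flagged in the detailed output).
    """
    geom = traj.geometry
    if visits is None:
        visits = detect_hole_visits(traj)
    if exit_index is None:
        exit_index = geom.exit_index
    n = geom.n_holes

    def circ_dist(a: int, b: int) -> int:
        d = abs(a - b) % n
        return min(d, n - d)

    # spatial
    spatial = False
    if visits:
        first_ok = circ_dist(visits[0][1], exit_index) <= 2
        c = np.asarray(geom.center)
        p = traj.positions - c
        r = np.linalg.norm(p, axis=1)
        ang = np.arctan2(p[:, 1], p[:, 0])
        exit_ang = geom.hole_angle(exit_index)
        dev = np.abs(np.angle(np.exp(1j * (ang - exit_ang))))
        outside = (r > 0.25 * geom.radius_cm) & (dev > np.pi / 4)
        spatial = first_ok and not outside.any()

    # serial
    idx = [h for _, h in visits]
    serial = False
    for k in range(len(idx) - 2):
        s1 = (idx[k + 1] - idx[k]) % n
        s2 = (idx[k + 2] - idx[k + 1]) % n
        if (s1, s2) in ((1, 1), (n - 1, n - 1)):
            serial = True
            break

    crossings = _count_field_crossings(traj)
    if spatial:
        label, fallback = "spatial", False
    elif serial:
        label, fallback = "serial", False
    elif crossings >= 2:
        label, fallback = "random", False
    else:
        label, fallback = "random", True
    if detailed:
        return label, {"spatial_rule": spatial, "serial_rule": serial,
                       "field_crossings": crossings, "fallback": fallback}
    return label


# ---------------------------------------------------------------------------
# Y maze
# ---------------------------------------------------------------------------

def _arm_penetration(geom: YMazeGeometry, p: np.ndarray) -> dict[str, float]:
    """Distance along each arm's axis, valid only inside the arm corridor."""
    out = {}
    for lab, u in geom.arm_axes().items():
        proj = float(np.dot(p, u))
        perp = abs(float(np.cross(np.append(u, 0), np.append(p, 0))[2]))
        if (0.0 <= proj <= geom.arm_length_cm + 5.0
                and perp <= geom.arm_width_cm / 2):
            out[lab] = proj
        else:
            out[lab] = -np.inf
    return out


def detect_arm_entries(traj: MazeTrajectory, d_entry_cm: float = 10.0,
                       d_exit_cm: float = 5.0) -> list[tuple[float, str]]:
    """Ordered (time, arm label) entries.

    An entry registers when the tracked point penetrates >= d_entry_cm
    into an arm (proxy for the two-paw rule); the animal must retreat to
    within d_exit_cm of the centre before a new entry can count
    (hysteresis against boundary oscillation).
    """
    geom = traj.geometry
    if geom.kind != "ymaze":
        raise ValueError("detect_arm_entries requires a Y-maze geometry")
    entries: list[tuple[float, str]] = []
    current: str | None = None
    for t, p in zip(traj.times_s, traj.positions):
        pen = _arm_penetration(geom, p)
        if current is None:
            best = max(pen, key=pen.get)
            if pen[best] >= d_entry_cm:
                entries.append((float(t), best))
                current = best
        else:
            if pen[current] < d_exit_cm:
                current = None
    return entries


def novelty_metrics(traj: MazeTrajectory,
                    entries: list[tuple[float, str]] | None = None,
                    novel: str = "novel", previously_open: str = "open",
                    entry_arm: str = "entry") -> dict:
    """Per-arm entries, dwell time and distance; novel-vs-open preference
    percentages and novel/all-arms discrimination ratios.

    A zero denominator yields NaN for that metric (flagged), never 0.
    """
    geom = traj.geometry
    if geom.kind != "ymaze":
        raise ValueError("novelty_metrics requires a Y-maze geometry")
    if entries is None:
        entries = detect_arm_entries(traj)
    labels = list(geom.arm_labels)
    n_entries = {lab: sum(1 for _, a in entries if a == lab)
                 for lab in labels}

    time_in = {lab: 0.0 for lab in labels}
    dist_in = {lab: 0.0 for lab in labels}
    t = traj.times_s
    pos = traj.positions
    for i in range(len(t) - 1):
        mid = (pos[i] + pos[i + 1]) / 2
        pen = _arm_penetration(geom, mid)
        best = max(pen, key=pen.get)
        if pen[best] > 0:
            time_in[best] += float(t[i + 1] - t[i])
            dist_in[best] += float(np.linalg.norm(pos[i + 1] - pos[i]))

    def pref(metric: dict) -> float:
        denom = metric[novel] + metric[previously_open]
        return 100.0 * metric[novel] / denom if denom > 0 else float("nan")

    def discr(metric: dict) -> float:
        denom = sum(metric[lab] for lab in labels)
        return metric[novel] / denom if denom > 0 else float("nan")

    metrics = {"entries": n_entries, "time_s": time_in,
               "distance_cm": dist_in}
    out = {
        "per_arm": metrics,
        "preference_percent": {k: pref(v) for k, v in metrics.items()},
        "discrimination_ratio": {k: discr(v) for k, v in metrics.items()},
        "total_distance_cm": total_distance(traj),
    }
    out["undefined_metrics"] = sorted(
        k for k, v in out["preference_percent"].items() if math.isnan(v))
    return out


# ---------------------------------------------------------------------------
# Heatmaps
# ---------------------------------------------------------------------------

def occupancy_heatmap(traj: MazeTrajectory, grid_cm: float = 5.0
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dwell-time grid (seconds per cell); cell values sum to the trial
    duration.  Returns (grid, x_edges, y_edges)."""
    if grid_cm <= 0:
        raise ValueError("grid_cm must be positive")
    pos = traj.positions
    t = traj.times_s
    x0, y0 = pos.min(axis=0)
    x1, y1 = pos.max(axis=0)
    nx = max(1, int(np.ceil((x1 - x0) / grid_cm)))
    ny = max(1, int(np.ceil((y1 - y0) / grid_cm)))
    xe = x0 + np.arange(nx + 1) * grid_cm
    ye = y0 + np.arange(ny + 1) * grid_cm
    grid = np.zeros((nx, ny))
    dt = np.diff(t)
    ix = np.clip(((pos[:-1, 0] - x0) / grid_cm).astype(int), 0, nx - 1)
    iy = np.clip(((pos[:-1, 1] - y0) / grid_cm).astype(int), 0, ny - 1)
    np.add.at(grid, (ix, iy), dt)
    return grid, xe, ye
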