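"""Group-level reporting conventions: normality-gated test selection and
the R70 spread statistic.

R70 is the range from the 15th to the 85th percentile of a sample — the
robust analogue of "+/- 1 SD covers 68%" used to summarise non-Gaussian
endpoints.  Percentiles use the nearest-rank (inverted CDF) convention,
i.e. the order statistic at rank ceil(q*n), so R70 of the integers
1..100 is exactly 85 - 15 = 70; the convention is recorded in output
metadata so values are reproducible.

Test selection mirrors the source study's convention: a Shapiro-Wilk test
on the control (sham) group gates between an unpaired t-test with
mean +/- SD summaries and a Kruskal-Wallis test with median + R70
summaries.  The named tests delegate to scipy; only the gate and R70 are
bespoke.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "r70",
    "shapiro_gate",
    "compare_groups",
    "weekly_table",
    "modified_z_outliers",
]

PERCENTILE_METHOD = "inverted_cdf"


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: tuple[float, ...]
    unit: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in group {self.label!r}")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class ComparisonResult:
    test_name: str                      # "unpaired-t" | "kruskal-wallis"
    statistic: float
    p_value: float
    group_summaries: dict               # label -> summary dict
    normality_p: dict                   # label -> Shapiro-Wilk p (control)
    percentile_method: str = PERCENTILE_METHOD


def r70(values) -> float:
    """85th minus 15th percentile (nearest-rank convention)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("r70 needs at least 2 values")
    lo, hi = np.percentile(v, [15, 85], method=PERCENTILE_METHOD)
    return float(hi - lo)


def shapiro_gate(control_values, alpha: float = 0.05) -> str:
    """'gaussian' iff Shapiro-Wilk p >= alpha on the control group.

    The gate is evaluated on the control group only, matching the
    reporting convention this package reproduces.
    """
    v = np.asarray(control_values, dtype=float)
    if not (3 <= v.size <= 5000):
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    _, p = sstats.shapiro(v)
    return "gaussian" if p >= alpha else "non-gaussian"


def _summary(values, style: str) -> dict:
    v = np.asarray(values, dtype=float)
    if style == "parametric":
        return {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
                "n": int(v.size)}
    return {"median": float(np.median(v)), "r70": r70(v), "n": int(v.size)}


def compare_groups(control: GroupSample, treated: GroupSample,
                   alpha: float = 0.05,
                   strict_gate: bool = False) -> ComparisonResult:
    """Two-group comparison with normality-gated test selection.

    Gaussian gate -> unpaired t-test, mean +/- SD summaries; otherwise
    Kruskal-Wallis, median + R70 summaries.  ``strict_gate`` additionally
    requires the treated group to pass normality.
    """
    for g in (control, treated):
        if g.n < 3:
            raise ValueError(f"group {g.label!r} needs >= 3 values")
    normality_p = {}
    _, p_ctrl = sstats.shapiro(np.asarray(control.values))
    normality_p[control.label] = float(p_ctrl)
    gaussian = p_ctrl >= alpha
    if strict_gate:
        _, p_trt = sstats.shapiro(np.asarray(treated.values))
        normality_p[treated.label] = float(p_trt)
        gaussian = gaussian and p_trt >= alpha

    if gaussian:
        stat, p = sstats.ttest_ind(control.values, treated.values)
        style, name = "parametric", "unpaired-t"
    else:
        stat, p = sstats.kruskal(control.values, treated.values)
        style, name = "nonparametric", "kruskal-wallis"
    return ComparisonResult(
        test_name=name, statistic=float(stat), p_value=float(p),
        group_summaries={control.label: _summary(control.values, style),
                         treated.label: _summary(treated.values, style)},
        normality_p=normality_p,
    )


def weekly_table(per_week: dict[int, dict[str, list[float]]]
                 ) -> pd.DataFrame:
    """Per-week medians and R70 of AHI count and dyspnoea duration.

    ``per_week`` maps week number -> {"count": [...], "duration": [...]}
    with one value per animal.  Single-animal weeks get R70 = 0.
    """
    if not per_week:
        raise ValueError("need at least one week")
    rows = []
    for week in sorted(per_week):
        d = per_week[week]
        row = {"week": week}
        for metric in ("count", "duration"):
            v = np.asarray(d.get(metric, []), dtype=float)
            if v.size == 0:
                row[f"median_{metric}"] = np.nan
                row[f"r70_{metric}"] = np.nan
            else:
                row[f"median_{metric}"] = float(np.median(v))
                row[f"r70_{metric}"] = r70(v) if v.size >= 2 else 0.0
            row[f"n_{metric}"] = int(v.size)
        rows.append(row)
    return pd.DataFrame(rows)


def modified_z_outliers(values, threshold: float = 3.5) -> np.ndarray:
    """Iglewicz-Hoaglin robust outlier flags: modified Z score
    0.6745 * (x - median) / MAD >= threshold.  Off by default in the
    pipeline; provided for the optional outlier-removal step."""
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return np.zeros(v.size, dtype=bool)
    return np.abs(0.6745 * (v - med) / mad) >= threshold
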