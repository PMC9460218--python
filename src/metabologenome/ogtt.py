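"""Oral glucose tolerance test (OGTT) curve metrics.

An OGTT samples blood glucose (mg/dL) and insulin (uU/mL) at fixed minutes
(0, 30, 60, 90, 120) after a 75 g oral glucose load. Glucose-tolerance
indices are areas under the sampled curve computed with the trapezoid rule:

* total AUC — trapezoid area of the curve over a window [a, b];
* incremental AUC (iAUC) — area *above the fasting (t = 0) value*. Two
  conventions are implemented: ``positive_only`` (default; only excursions
  above baseline count, with exact linear interpolation at baseline
  crossings — the Wolever convention common in glycemic-response work) and
  ``net`` (total AUC minus baseline x window length; may be negative).

Windows are closed intervals in minutes. The window start must coincide
with a sampled time; the end may fall between samples, in which case the
curve is linearly interpolated there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OGTTCurve",
    "total_auc",
    "incremental_auc",
    "fasting_value",
    "glucose_tolerance_indices",
    "INDEX_NAMES",
]

TIMEPOINTS = ("T1", "T2", "T3", "C1", "C2", "C3")

#: index names produced by :func:`glucose_tolerance_indices`
INDEX_NAMES = (
    "glucose_AUC_0_90",
    "glucose_AUC_0_120",
    "glucose_iAUC_0_90",
    "glucose_iAUC_0_120",
    "insulin_AUC_0_90",
    "insulin_AUC_0_120",
    "insulin_iAUC_0_90",
    "insulin_iAUC_0_120",
    "fasting_glucose",
    "fasting_insulin",
)


@dataclass(frozen=True)
class OGTTCurve:
    """One analyte's timed concentrations for one subject at one time point.

    ``times`` are minutes since the glucose load, strictly increasing and
    starting at 0; ``values`` are nonnegative concentrations of matching
    length. ``timepoint`` is one of T1..T3 (test period) / C1..C3 (control).
    """

    subject: str
    timepoint: str
    analyte: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D and equally long")
        if t.size < 2:
            raise ValueError("need at least two sampled times")
        if t[0] != 0:
            raise ValueError("first sampled time must be 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("values must be finite and nonnegative")


def _window_grid(curve: OGTTCurve, window: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Sampled times/values restricted to [start, end], interpolating the
    endpoint when it falls between samples."""
    start, end = float(window[0]), float(window[1])
    t, v = curve.times, curve.values
    if start not in t:
        raise ValueError(f"window start {start} is not a sampled time")
    if end <= start:
        raise ValueError("window end must exceed window start")
    if end > t[-1]:
        raise ValueError(f"window end {end} exceeds last sampled time {t[-1]}")
    inside = (t >= start) & (t <= end)
    tt = t[inside]
    vv = v[inside]
    if tt[-1] < end:
        tt = np.append(tt, end)
        vv = np.append(vv, np.interp(end, t, v))
    if tt.size < 2:
        raise ValueError("fewer than 2 points in window")
    return tt, vv


def total_auc(curve: OGTTCurve, window: Sequence[float] = (0, 120)) -> float:
    """Trapezoid-rule area under the curve over ``window`` (conc * min)."""
    tt, vv = _window_grid(curve, window)
    return float(np.trapezoid(vv, tt))


def incremental_auc(
    curve: OGTTCurve,
    window: Sequence[float] = (0, 120),
    convention: Literal["positive_only", "net"] = "positive_only",
) -> float:
    """Incremental (above-fasting) AUC over ``window``.

    Baseline is the value at t = 0. ``positive_only`` integrates only the
    part of the piecewise-linear curve above baseline, splitting segments
    exactly at baseline crossings; ``net`` subtracts baseline x window
    length from the total AUC and may be negative.
    """
    baseline = fasting_value(curve)
    tt, vv = _window_grid(curve, window)
    if convention == "net":
        return float(np.trapezoid(vv, tt) - baseline * (tt[-1] - tt[0]))
    if convention != "positive_only":
        raise ValueError(f"unknown iAUC convention: {convention!r}")
    d = vv - baseline
    area = 0.0
    for t0, t1, d0, d1 in zip(tt[:-1], tt[1:], d[:-1], d[1:]):
        if d0 >= 0 and d1 >= 0:
            area += 0.5 * (d0 + d1) * (t1 - t0)
        elif d0 <= 0 and d1 <= 0:
            continue
        else:
            tc = t0 + (t1 - t0) * d0 / (d0 - d1)  # baseline crossing
            if d0 > 0:
                area += 0.5 * d0 * (tc - t0)
            else:
                area += 0.5 * d1 * (t1 - tc)
    return float(area)


def fasting_value(curve: OGTTCurve) -> float:
    """Concentration at t = 0."""
    at_zero = np.nonzero(curve.times == 0)[0]
    if at_zero.size == 0:
        raise ValueError("curve has no t = 0 sample")
    return float(curve.values[at_zero[0]])


def curves_from_frame(ogtt: pd.DataFrame) -> list[OGTTCurve]:
    """Build :class:`OGTTCurve` objects from a long-format OGTT table with
    columns subject, timepoint, analyte, minute, value."""
    required = {"subject", "timepoint", "analyte", "minute", "value"}
    missing = required - set(ogtt.columns)
    if missing:
        raise ValueError(f"OGTT table missing columns: {sorted(missing)}")
    curves = []
    for (subject, timepoint, analyte), grp in ogtt.groupby(
        ["subject", "timepoint", "analyte"], sort=True
    ):
        grp = grp.sort_values("minute")
        curves.append(
            OGTTCurve(
                subject=str(subject),
                timepoint=str(timepoint),
                analyte=str(analyte),
                times=grp["minute"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
            )
        )
    return curves


def glucose_tolerance_indices(
    curves: Iterable[OGTTCurve],
    windows: Sequence[Sequence[float]] = ((0, 90), (0, 120)),
    iauc_convention: Literal["positive_only", "net"] = "positive_only",
) -> pd.DataFrame:
    """Compute the glucose-tolerance index panel for every curve.

    Returns a tidy frame with columns subject, timepoint, name, value where
    name runs over AUC/iAUC per analyte per window plus the fasting values
    (see :data:`INDEX_NAMES` for the default panel).
    """
    rows = []
    for c in curves:
        for a, b in windows:
            suffix = f"{int(a)}_{int(b)}"
            rows.append((c.subject, c.timepoint, f"{c.analyte}_AUC_{suffix}", total_auc(c, (a, b))))
            rows.append(
                (
                    c.subject,
                    c.timepoint,
                    f"{c.analyte}_iAUC_{suffix}",
                    incremental_auc(c, (a, b), iauc_convention),
                )
            )
        rows.append((c.subject, c.timepoint, f"fasting_{c.analyte}", fasting_value(c)))
    return pd.DataFrame(rows, columns=["subject", "timepoint", "name", "value"])
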