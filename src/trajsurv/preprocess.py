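"""Eligibility, capping, log-transform and landmark rules for marker tables.

Raw serum values are truncated at ten times the upper limit of each
marker's reference range before log-transformation, which tames the extreme
spikes these assays produce without discarding the record.  Eligibility for
trajectory modelling requires a preoperative value within the configured
window before surgery and a minimum number of postoperative values within
the feature horizon, per marker.  The landmark rule retains patients still
at risk at the landmark time; conditional predictions and their evaluation
are defined on that risk set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WEEKS_PER_MONTH = 52.0 / 12.0

#: upper limits of the reference ranges, in marker units
DEFAULT_LIMITS = {"CEA": 5.0, "CA19-9": 37.0, "CA125": 35.0}


@dataclass
class ReferenceLimits:
    limits: dict = field(default_factory=lambda: dict(DEFAULT_LIMITS))
    multiplier: float = 10.0

    def __post_init__(self):
        if any(v <= 0 for v in self.limits.values()):
            raise ValueError("reference limits must be positive")
        if self.multiplier <= 1:
            raise ValueError("cap multiplier must exceed 1")

    def cap(self, marker: str) -> float:
        return self.multiplier * self.limits[marker]


def cap_and_log(value, marker: str, limits: ReferenceLimits | None = None):
    """log(min(value, multiplier * reference limit)); natural log.

    Accepts scalars or arrays; rejects non-positive values and unknown
    markers.
    """
    limits = limits or ReferenceLimits()
    if marker not in limits.limits:
        raise KeyError(f"no reference limit configured for marker {marker!r}")
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        bad = np.asarray(arr <= 0).nonzero()
        raise ValueError(
            f"non-positive {marker} value(s) at position(s) {bad[0].tolist()}"
            if arr.ndim else f"non-positive {marker} value {value}")
    out = np.log(np.minimum(arr, limits.cap(marker)))
    return float(out) if np.ndim(value) == 0 else out


def process_measurements(measurements: pd.DataFrame,
                         limits: ReferenceLimits | None = None) -> pd.DataFrame:
    """Add a ``value_log`` column of capped, log-transformed values."""
    limits = limits or ReferenceLimits()
    if measurements.empty:
        raise ValueError("empty measurement table")
    unknown = set(measurements["marker"]) - set(limits.limits)
    if unknown:
        raise KeyError(f"no reference limit for marker(s) {sorted(unknown)}")
    bad = measurements[measurements["value"] <= 0]
    if len(bad):
        rec = bad.iloc[0]
        raise ValueError(
            f"non-positive value for patient {rec['patient_id']} marker "
            f"{rec['marker']} at t={rec['time_months']}")
    out = measurements.copy()
    caps = out["marker"].map(limits.cap)
    out["value_log"] = np.log(np.minimum(out["value"].to_numpy(),
                                         caps.to_numpy()))
    return out


def filter_eligible(measurements: pd.DataFrame, patients: pd.DataFrame,
                    preop_window_weeks: float = 4.0, min_postop: int = 2,
                    postop_horizon: float = 12.0, markers=None):
    """Apply the inclusion rule per marker.

    Keeps patients with >= 1 observation in [-window, 0) and >= ``min_postop``
    observations in (0, horizon] for *every* marker in ``markers`` (default:
    all markers present).  Returns (eligible ids, exclusion log) where the
    log records the first failed rule per excluded patient.
    """
    if measurements.empty or patients.empty:
        raise ValueError("empty input table")
    window = preop_window_weeks / WEEKS_PER_MONTH
    if markers is None:
        markers = sorted(measurements["marker"].unique())
    eligible = []
    exclusions = []
    grouped = {k: g for k, g in measurements.groupby(["patient_id", "marker"])}
    for pid in patients["patient_id"]:
        reason = None
        for m in markers:
            g = grouped.get((pid, m))
            t = g["time_months"].to_numpy() if g is not None else np.array([])
            if not np.any((t >= -window) & (t < 0)):
                reason = (m, "no preoperative measurement in window")
                break
            if np.sum((t > 0) & (t <= postop_horizon)) < min_postop:
                reason = (m, "insufficient postoperative measurements")
                break
        if reason is None:
            eligible.append(pid)
        else:
            exclusions.append((pid, reason[1], reason[0]))
    log = pd.DataFrame(exclusions, columns=["patient_id", "rule", "detail"])
    return eligible, log


def extract_anchor_values(measurements: pd.DataFrame,
                          preop_window_weeks: float = 4.0,
                          postop_horizon: float = 12.0) -> pd.DataFrame:
    """Preoperative and first-postoperative value per patient per marker.

    Preoperative = observation closest to surgery among times in
    [-window, 0); on an exact tie the later-recorded row wins.  First
    postoperative = the observation at the smallest positive time within the
    horizon.  Returns a wide table with columns ``preop_<marker>`` and
    ``postop_first_<marker>`` (raw units).
    """
    window = preop_window_weeks / WEEKS_PER_MONTH
    records = {}
    for (pid, m), g in measurements.groupby(["patient_id", "marker"]):
        t = g["time_months"].to_numpy()
        v = g["value"].to_numpy()
        row = records.setdefault(pid, {})
        pre = (t >= -window) & (t < 0)
        if pre.any():
            # stable argmax of -|t| over original order -> last of exact ties
            cand = np.flatnonzero(pre)
            best = cand[np.flatnonzero(np.abs(t[cand]) ==
                                       np.abs(t[cand]).min())[-1]]
            row[f"preop_{m}"] = v[best]
        post = (t > 0) & (t <= postop_horizon)
        if post.any():
            cand = np.flatnonzero(post)
            row[f"postop_first_{m}"] = v[cand[np.argmin(t[cand])]]
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "patient_id"
    return out


def apply_landmark(patients: pd.DataFrame, landmark: float) -> list:
    """Risk-set patient ids: observed survival time strictly beyond ``landmark``."""
    if landmark < 0:
        raise ValueError("landmark must be >= 0")
    keep = patients["time_months"] > landmark
    return patients.loc[keep, "patient_id"].tolist()


def build_series(measurements: pd.DataFrame,
                 marker: str,
                 limits: ReferenceLimits | None = None,
                 ids=None,
                 horizon: float = 12.0) -> dict:
    """Per-patient (times, capped-log values) for one marker up to ``horizon``.

    The returned dict maps patient_id -> (t, Y) with times strictly
    increasing (duplicate times keep the last record).
    """
    limits = limits or ReferenceLimits()
    sub = measurements[(measurements["marker"] == marker)
                       & (measurements["time_months"] <= horizon)]
    if ids is not None:
        sub = sub[sub["patient_id"].isin(set(ids))]
    series = {}
    for pid, g in sub.groupby("patient_id"):
        g = g.sort_values("time_months", kind="stable")
        g = g.drop_duplicates("time_months", keep="last")
        series[pid] = (g["time_months"].to_numpy(),
                       cap_and_log(g["value"].to_numpy(), marker, limits))
    return series
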