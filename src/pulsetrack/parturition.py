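"""Parturition detection from localized movement: the rolling-MCP method.

A female ungulate localizes sharply around her birth site, so the area of
the minimum convex polygon (MCP) of her fixes over a trailing 24-h window
collapses at parturition.  An event is declared at the start of the first
run of evaluation times whose 24-h MCP area stays at or below a
species-specific threshold (30 ha for elk, 15 ha for mule deer)
continuously for at least 120 h; if no such run exists the animal is
assumed not to have given birth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .telemetry_io import times_ns

__all__ = [
    "mcp_area",
    "rolling_mcp",
    "detect_parturition",
    "detect_all",
    "score_detections",
    "ParturitionEvent",
]

M2_PER_HA = 1e4


@dataclass
class ParturitionEvent:
    animal_id: str
    event_time: pd.Timestamp
    x: float
    y: float
    method: str
    threshold_ha: float


def mcp_area(points: np.ndarray) -> float:
    """Convex-hull (MCP) area of 2-D points in hectares.

    Fewer than 3 distinct non-collinear points have zero hull area.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("mcp_area requires at least one point")
    if pts.shape[0] < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear or coincident
        return 0.0
    return float(hull.volume) / M2_PER_HA  # ConvexHull.volume is area in 2-D


def rolling_mcp(
    traj: pd.DataFrame, window_h: float = 24.0, eval_times: pd.DatetimeIndex | None = None
) -> pd.DataFrame:
    """MCP area over a trailing window, evaluated at every fix time.

    The window is past-looking: at evaluation time ``t`` it covers fixes in
    ``(t - window_h, t]``.  Evaluation starts once the trajectory has spanned
    one full window.  Windows with < 3 fixes get area 0 and ``flagged=True``.

    Returns columns ``t, window_start, n_fixes, area_ha, flagged``.
    """
    t = times_ns(traj["t"])
    if len(t) == 0:
        raise ValueError("empty trajectory")
    span_h = (t[-1] - t[0]) / np.timedelta64(1, "h")
    if span_h < window_h:
        raise ValueError(f"trajectory spans {span_h:.1f} h < window of {window_h} h")
    xy = traj[["x", "y"]].to_numpy(dtype=float)
    if eval_times is None:
        ev = t
    else:
        ev = times_ns(eval_times)
    w = np.timedelta64(int(window_h * 3600 * 1e9), "ns")
    first_valid = t[0] + w
    ev = ev[ev >= first_valid]

    starts = np.searchsorted(t, ev - w, side="left")
    ends = np.searchsorted(t, ev, side="right")
    rows = []
    for tq, i0, i1 in zip(ev, starts, ends):
        n = i1 - i0
        area = mcp_area(xy[i0:i1]) if n >= 1 else 0.0
        rows.append((tq, tq - w, n, area, n < 3))
    out = pd.DataFrame(rows, columns=["t", "window_start", "n_fixes", "area_ha", "flagged"])
    out["t"] = pd.to_datetime(out["t"], utc=True)
    out["window_start"] = pd.to_datetime(out["window_start"], utc=True)
    return out


def detect_parturition(
    traj: pd.DataFrame,
    threshold_ha: float = 30.0,
    min_duration_h: float = 120.0,
    window_h: float = 24.0,
    max_gap_h: float | None = None,
) -> ParturitionEvent | None:
    """First sustained collapse of the rolling MCP at or below the threshold.

    Both comparisons are inclusive: an area of exactly ``threshold_ha``
    qualifies and a run lasting exactly ``min_duration_h`` qualifies.  A run
    is a maximal sequence of consecutive qualifying evaluation times; a gap
    longer than ``max_gap_h`` (default: the window length) between
    consecutive evaluations breaks the run.  The event is anchored at the
    run's first evaluation time and sited at the centroid of the fixes in
    the run's first ``min_duration_h`` hours.  Returns ``None`` when no run
    qualifies (the animal is assumed not to have given birth).
    """
    if max_gap_h is None:
        max_gap_h = window_h
    series = rolling_mcp(traj, window_h=window_h)
    ok = (series["area_ha"].to_numpy() <= threshold_ha) & (series["n_fixes"].to_numpy() >= 1)
    t = times_ns(series["t"])
    gap_ns = np.timedelta64(int(max_gap_h * 3600 * 1e9), "ns")
    min_dur = np.timedelta64(int(min_duration_h * 3600 * 1e9), "ns")

    i = 0
    n = len(ok)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1] and (t[j + 1] - t[j]) <= gap_ns:
            j += 1
        if t[j] - t[i] >= min_dur:
            start = pd.Timestamp(t[i], tz="UTC")
            seg = traj[
                (traj["t"] >= start) & (traj["t"] <= start + pd.Timedelta(hours=min_duration_h))
            ]
            return ParturitionEvent(
                animal_id=str(traj["animal_id"].iloc[0]),
                event_time=start,
                x=float(seg["x"].mean()),
                y=float(seg["y"].mean()),
                method="rolling_mcp",
                threshold_ha=threshold_ha,
            )
        i = j + 1
    return None


def detect_all(
    fixes: pd.DataFrame,
    threshold_ha: float = 30.0,
    min_duration_h: float = 120.0,
    window_h: float = 24.0,
) -> pd.DataFrame:
    """Run the detector per animal; returns the events-CSV schema."""
    rows = []
    for _, grp in fixes.groupby("animal_id", sort=False):
        ev = detect_parturition(grp, threshold_ha, min_duration_h, window_h)
        if ev is not None:
            rows.append(
                {
                    "animal_id": ev.animal_id,
                    "event_time": ev.event_time,
                    "method": ev.method,
                    "x": ev.x,
                    "y": ev.y,
                }
            )
    return pd.DataFrame(rows, columns=["animal_id", "event_time", "method", "x", "y"])


def score_detections(
    detected: pd.DataFrame, truth: pd.DataFrame, max_offset_h: float = 72.0
) -> dict:
    """Sensitivity, false positives, and mean |timing error| in hours.

    Detections and truth are matched by animal_id; a detection matches if
    its |event-time difference| is within ``max_offset_h``.  Detections for
    animals with no true event, or outside the offset, count as false
    positives.
    """
    det = {str(r.animal_id): pd.Timestamp(r.event_time) for r in detected.itertuples()}
    tru = {str(r.animal_id): pd.Timestamp(r.event_time) for r in truth.itertuples()}
    offsets = []
    false_pos = 0
    for aid, t_det in det.items():
        if aid in tru:
            dt_h = abs((t_det - tru[aid]).total_seconds()) / 3600.0
            if dt_h <= max_offset_h:
                offsets.append(dt_h)
            else:
                false_pos += 1
        else:
            false_pos += 1
    sensitivity = len(offsets) / len(tru) if tru else float("nan")
    mean_dt = float(np.mean(offsets)) if offsets else float("nan")
    return {
        "sensitivity": sensitivity,
        "n_true": len(tru),
        "n_detected": len(det),
        "false_positives": false_pos,
        "mean_abs_offset_h": mean_dt,
    }
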