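"""Body, stride and leg parameters computed from tracked claw trajectories.

Swing/stance segmentation: a leg is in stance when its claw is planted, i.e.
(nearly) stationary in the arena frame, and in swing while the claw travels.
Swing detection therefore thresholds the arena-frame claw speed with
hysteresis (on at ``v_on`` = 4 mm/s, off at ``v_off`` = 2 mm/s, minimum swing
3 frames at 1,000 fps) — the hysteresis prevents chatter around lift-off and
touch-down. Each swing is one stride event; the take-off point is the
posterior extreme position (PEP) and the landing point the anterior extreme
position (AEP), both reported in body-centred millimetres.

The per-frame gait index scores the set of currently swinging legs: +1 when
it is one of the two canonical tripod sets ({L1, R2, L3} / {R1, L2, R3}), -1
when it is a canonical tetrapod (diagonal) swing pair, 0 otherwise; the
series is smoothed by a centred 120-ms moving average and clipped to [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Polygon

from .claw_tracking import BodyPose, TrackSet

__all__ = [
    "StrideEvent",
    "LegDomain",
    "GaitReport",
    "interpolate_gaps",
    "detect_strides",
    "stride_parameters",
    "leg_parameters",
    "domain_overlap",
    "stance_width",
    "gait_index",
    "swing_matrix",
    "body_parameters",
    "compute_gait_report",
]

TRIPOD_SETS = (frozenset({"L1", "R2", "L3"}), frozenset({"R1", "L2", "R3"}))


def _is_tetrapod_pair(s: frozenset) -> bool:
    """Diagonal contralateral pair {Li, Rj}, i != j — one step of a tetrapod wave."""
    if len(s) != 2:
        return False
    a, b = sorted(s)
    return a[0] != b[0] and a[1] != b[1]


@dataclass
class StrideEvent:
    leg: str
    start: int  # first swing frame
    end: int  # last swing frame (inclusive)
    pep_mm: np.ndarray  # body-frame (x, y) at take-off
    aep_mm: np.ndarray  # body-frame (x, y) at landing
    duration_ms: float = np.nan
    period_ms: float = np.nan  # start-to-start; NaN for the last stride
    displacement_mm: float = np.nan
    path_mm: float = np.nan
    amplitude_mm: float = np.nan
    stance_linearity_mm: float = np.nan
    stretch_mm: float = np.nan


@dataclass
class LegDomain:
    leg: str
    hull_mm: np.ndarray  # (k, 2) hull vertices, body frame
    area_mm2: float
    length_mm: float
    width_mm: float


@dataclass
class GaitReport:
    poses: Sequence[BodyPose]
    body_length_mm: float
    body_length_series_mm: np.ndarray
    body_velocity_mm_s: np.ndarray
    turning_points: np.ndarray  # (k, 2) arena px
    events: dict[str, list[StrideEvent]]
    domains: dict[str, LegDomain]
    gait_index_series: np.ndarray
    stride_table: pd.DataFrame
    leg_table: pd.DataFrame
    domain_overlap: pd.DataFrame
    stance_width_table: pd.DataFrame


def _odd_window(ms: float, fps: float) -> int:
    w = max(1, int(round(ms * fps / 1000.0)))
    return w if w % 2 == 1 else w + 1


def interpolate_gaps(track: np.ndarray, max_gap: int = 5) -> np.ndarray:
    """Linearly fill NaN runs of at most ``max_gap`` frames (per column)."""
    out = np.asarray(track, dtype=np.float64).copy()
    n = out.shape[0]
    bad = ~np.isfinite(out[:, 0])
    if not bad.any():
        return out
    i = 0
    while i < n:
        if bad[i]:
            j = i
            while j < n and bad[j]:
                j += 1
            run = j - i
            if 0 < i and j < n and run <= max_gap:
                for t in range(i, j):
                    a = (t - (i - 1)) / (j - (i - 1))
                    out[t] = (1 - a) * out[i - 1] + a * out[j]
            i = j
        else:
            i += 1
    return out


def detect_strides(
    arena_px: np.ndarray,
    body_px: np.ndarray,
    fps: float,
    mm_per_px: float,
    leg: str = "",
    v_on: float = 4.0,
    v_off: float = 2.0,
    min_swing_frames: int = 3,
    max_gap: int = 5,
) -> list[StrideEvent]:
    """Segment one claw trajectory into stride (swing) events.

    Gaps of up to ``max_gap`` frames are interpolated first; longer gaps
    break the hysteresis state so strides never span them. A fully
    stationary leg yields no events.
    """
    arena = interpolate_gaps(arena_px, max_gap)
    body = interpolate_gaps(body_px, max_gap)
    n = arena.shape[0]
    if n < 2:
        return []
    # Tracked tips are pixel-quantized: a planted claw jitters by ~1 px from
    # frame to frame, which at 1,000 fps reads as tens of mm/s — far above
    # any sensible swing threshold. Median-filtering the positions (7 ms)
    # flattens stance jitter to zero while shifting a swing ramp's two edges
    # equally, so stride timing and counts are preserved; a second short
    # median on the speed removes the isolated steps left at jitter
    # transitions.
    pos = arena.copy()
    w_pos = _odd_window(7.0, fps)
    if n >= w_pos > 1:
        for k in range(2):
            pos[:, k] = median_filter(pos[:, k], size=w_pos, mode="nearest")
    step = np.hypot(*np.diff(pos, axis=0).T) * mm_per_px * fps  # mm/s
    speed = np.concatenate([[0.0], step])
    w_sp = _odd_window(5.0, fps)
    if np.isfinite(speed).all() and n >= w_sp > 1:
        speed = median_filter(speed, size=w_sp, mode="nearest")
    valid = np.isfinite(arena[:, 0])

    swinging = np.zeros(n, dtype=bool)
    state = False
    for i in range(n):
        if not valid[i] or not np.isfinite(speed[i]):
            state = False
            continue
        if state:
            state = speed[i] >= v_off
        else:
            state = speed[i] > v_on
        swinging[i] = state

    events: list[StrideEvent] = []
    i = 0
    while i < n:
        if swinging[i]:
            j = i
            while j < n and swinging[j]:
                j += 1
            if j - i >= min_swing_frames:
                start, end = i, j - 1
                events.append(
                    StrideEvent(
                        leg=leg,
                        start=start,
                        end=end,
                        pep_mm=body[start] * mm_per_px,
                        aep_mm=body[end] * mm_per_px,
                        duration_ms=(end - start + 1) * 1000.0 / fps,
                    )
                )
            i = j
        else:
            i += 1
    for k in range(len(events) - 1):
        events[k].period_ms = (events[k + 1].start - events[k].start) * 1000.0 / fps
    return events


def stride_parameters(
    events: list[StrideEvent],
    arena_px: np.ndarray,
    body_px: np.ndarray,
    fps: float,
    mm_per_px: float,
    smooth_interval_ms: float = 20.0,
) -> list[StrideEvent]:
    """Fill the geometric stride parameters of detected events, in place.

    displacement = |AEP - PEP|; path = summed body-frame steps; amplitude =
    projection of (AEP - PEP) on the anterior (+y) body axis; stance
    linearity = RMS deviation of the arena-frame stride path from a cubic
    spline through control points sampled every 20 ms; stretch = distance of
    the claw from the body centre at the stride's temporal midpoint.
    """
    arena = interpolate_gaps(arena_px)
    body = interpolate_gaps(body_px)
    for ev in events:
        seg_b = body[ev.start : ev.end + 1] * mm_per_px
        seg_a = arena[ev.start : ev.end + 1] * mm_per_px
        d = ev.aep_mm - ev.pep_mm
        ev.displacement_mm = float(np.hypot(*d))
        ev.path_mm = float(np.sum(np.hypot(*np.diff(seg_b, axis=0).T)))
        ev.amplitude_mm = float(d[1])
        mid = (ev.start + ev.end) // 2
        ev.stretch_mm = float(np.hypot(*(body[mid] * mm_per_px)))
        ev.stance_linearity_mm = _linearity(seg_a, fps, smooth_interval_ms)
    return events


def _linearity(seg_arena_mm: np.ndarray, fps: float, interval_ms: float) -> float:
    m = seg_arena_mm.shape[0]
    if m < 3:
        return 0.0
    t = np.arange(m) / fps * 1000.0  # ms
    ctrl_t = np.arange(0.0, t[-1], interval_ms)
    if ctrl_t[-1] < t[-1]:
        ctrl_t = np.append(ctrl_t, t[-1])
    if len(ctrl_t) < 2:
        ctrl_t = np.array([0.0, t[-1]])
    ctrl = np.stack(
        [np.interp(ctrl_t, t, seg_arena_mm[:, 0]), np.interp(ctrl_t, t, seg_arena_mm[:, 1])],
        axis=1,
    )
    if len(ctrl_t) >= 2 and np.all(np.diff(ctrl_t) > 0):
        cs = CubicSpline(ctrl_t, ctrl, axis=0, bc_type="natural")
        smooth = cs(t)
    else:
        smooth = seg_arena_mm
    dev = np.hypot(*(seg_arena_mm - smooth).T)
    return float(np.sqrt(np.mean(dev**2)))


def leg_parameters(
    arena_px: np.ndarray,
    body_px: np.ndarray,
    events: list[StrideEvent],
    fps: float,
    mm_per_px: float,
) -> dict:
    """Per-leg summary: speed series, movement %, mean period, footprint
    regularity and the trajectory-domain geometry."""
    arena = interpolate_gaps(arena_px)
    body = interpolate_gaps(body_px)
    n = arena.shape[0]
    speed = np.full(n, np.nan)
    if n > 1:
        speed[1:] = np.hypot(*np.diff(arena, axis=0).T) * mm_per_px * fps

    tracked = np.isfinite(body[:, 0])
    in_swing = np.zeros(n, dtype=bool)
    for ev in events:
        in_swing[ev.start : ev.end + 1] = True
    movement_pct = 100.0 * in_swing[tracked].sum() / max(1, tracked.sum())

    periods = [ev.period_ms for ev in events if np.isfinite(ev.period_ms)]
    mean_period = float(np.mean(periods)) if periods else np.nan

    if events:
        aeps = np.stack([ev.aep_mm for ev in events])
        peps = np.stack([ev.pep_mm for ev in events])
        footprint = 0.5 * (_cloud_std(aeps) + _cloud_std(peps))
    else:
        footprint = np.nan

    domain = _leg_domain(body[tracked] * mm_per_px)
    return {
        "speed_mm_s": speed,
        "in_swing": in_swing,
        "movement_pct": float(movement_pct),
        "mean_stride_period_ms": mean_period,
        "footprint_regularity_mm": float(footprint) if footprint == footprint else np.nan,
        "domain": domain,
    }


def _cloud_std(pts: np.ndarray) -> float:
    """RMS distance of a 2-D point cloud from its mean."""
    c = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - c) ** 2, axis=1))))


def _leg_domain(points_mm: np.ndarray, leg: str = "") -> LegDomain | None:
    pts = points_mm[np.isfinite(points_mm[:, 0])]
    if pts.shape[0] < 3:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None
    verts = pts[hull.vertices]
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    major, minor = evecs[:, 1], evecs[:, 0]
    length = float(np.ptp(centred @ major))
    width = float(np.ptp(centred @ minor))
    return LegDomain(
        leg=leg,
        hull_mm=verts,
        area_mm2=float(hull.volume),  # 2-D hull: volume is the area
        length_mm=max(length, width),
        width_mm=min(length, width),
    )


def domain_overlap(
    domains: dict[str, LegDomain], mean_strides_per_leg: float = np.nan
) -> pd.DataFrame:
    """Pairwise polygon-intersection areas of the leg domains.

    Reported raw and normalized by the average number of strides per leg.
    """
    legs = [l for l, d in domains.items() if d is not None]
    rows = []
    for i in range(len(legs)):
        for j in range(i + 1, len(legs)):
            pa = Polygon(domains[legs[i]].hull_mm)
            pb = Polygon(domains[legs[j]].hull_mm)
            ov = float(pa.intersection(pb).area)
            rows.append(
                {
                    "leg_a": legs[i],
                    "leg_b": legs[j],
                    "overlap_mm2": ov,
                    "overlap_norm": ov / mean_strides_per_leg
                    if mean_strides_per_leg and np.isfinite(mean_strides_per_leg)
                    else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["leg_a", "leg_b", "overlap_mm2", "overlap_norm"])


def stance_width(events: dict[str, list[StrideEvent]]) -> float:
    """Average distance between the extreme positions of the two mid legs.

    AEPs (and PEPs) of the left and right middle legs are paired in stride
    order; the stance width is the mean of all paired AEP-AEP and PEP-PEP
    distances. NaN when either side has no strides.
    """
    left = events.get("L2", [])
    right = events.get("R2", [])
    k = min(len(left), len(right))
    if k == 0:
        return np.nan
    ds = []
    for i in range(k):
        ds.append(np.hypot(*(left[i].aep_mm - right[i].aep_mm)))
        ds.append(np.hypot(*(left[i].pep_mm - right[i].pep_mm)))
    return float(np.mean(ds))


def swing_matrix(
    events: dict[str, list[StrideEvent]], n_frames: int, legs: Sequence[str]
) -> np.ndarray:
    sw = np.zeros((n_frames, len(legs)), dtype=bool)
    for j, leg in enumerate(legs):
        for ev in events.get(leg, []):
            sw[ev.start : ev.end + 1, j] = True
    return sw


def gait_index(
    swing: np.ndarray,
    legs: Sequence[str],
    fps: float,
    window_ms: float = 120.0,
) -> np.ndarray:
    """Per-frame tripod/tetrapod score smoothed over a 120-ms window.

    +1: the swinging set is a canonical tripod set; -1: a canonical tetrapod
    (diagonal) pair; 0: anything else, including all-stance frames.
    """
    legs = list(legs)
    n = swing.shape[0]
    raw = np.zeros(n)
    for i in range(n):
        s = frozenset(l for j, l in enumerate(legs) if swing[i, j])
        if s in TRIPOD_SETS:
            raw[i] = 1.0
        elif _is_tetrapod_pair(s):
            raw[i] = -1.0
    win = max(1, int(round(window_ms * fps / 1000.0)))
    smoothed = uniform_filter1d(raw, size=win, mode="nearest")
    return np.clip(smoothed, -1.0, 1.0)


def body_parameters(
    poses: Sequence[BodyPose],
    fps: float,
    mm_per_px: float,
    dp_tolerance_px: float = 5.0,
    turn_threshold_deg: float = 50.0,
) -> dict:
    """Body length, instantaneous velocity and trajectory turning points.

    The centroid path is simplified with the Douglas-Peucker algorithm
    (tolerance 5 px) and a turn is recorded wherever two neighbouring
    segments of the simplified polyline differ in direction by more than
    50 degrees.
    """
    centroids = np.stack([p.centroid for p in poses])
    lengths_mm = np.array([p.length_px for p in poses]) * mm_per_px
    vel = np.zeros(len(poses))
    if len(poses) > 1:
        vel[1:] = np.hypot(*np.diff(centroids, axis=0).T) * mm_per_px * fps

    turns: list[np.ndarray] = []
    if len(poses) >= 3:
        simplified = np.asarray(
            LineString(centroids).simplify(dp_tolerance_px).coords
        )
        for k in range(1, simplified.shape[0] - 1):
            v1 = simplified[k] - simplified[k - 1]
            v2 = simplified[k + 1] - simplified[k]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                continue
            ang = math.degrees(
                math.acos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
            )
            if ang > turn_threshold_deg:
                turns.append(simplified[k])
    return {
        "body_length_mm": float(np.median(lengths_mm)),
        "body_length_series_mm": lengths_mm,
        "body_velocity_mm_s": vel,
        "turning_points": np.array(turns).reshape(-1, 2),
    }


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


def compute_gait_report(
    tracks: TrackSet,
    poses: Sequence[BodyPose],
    fps: float,
    mm_per_px: float,
    v_on: float = 4.0,
    v_off: float = 2.0,
) -> GaitReport:
    """Compute every body, stride and leg parameter from a finished TrackSet."""
    body_par = body_parameters(poses, fps, mm_per_px)
    n = tracks.n_frames
    legs = list(tracks.legs)

    events: dict[str, list[StrideEvent]] = {}
    per_leg: dict[str, dict] = {}
    domains: dict[str, LegDomain] = {}
    for j, leg in enumerate(legs):
        ev = detect_strides(
            tracks.arena[:, j], tracks.body[:, j], fps, mm_per_px,
            leg=leg, v_on=v_on, v_off=v_off,
        )
        stride_parameters(ev, tracks.arena[:, j], tracks.body[:, j], fps, mm_per_px)
        events[leg] = ev
        lp = leg_parameters(tracks.arena[:, j], tracks.body[:, j], ev, fps, mm_per_px)
        if lp["domain"] is not None:
            lp["domain"].leg = leg
        per_leg[leg] = lp
        domains[leg] = lp["domain"]

    mean_strides = float(np.mean([len(e) for e in events.values()]))
    sw = swing_matrix(events, n, legs)
    gi = gait_index(sw, legs, fps)

    stride_rows = []
    for leg in legs:
        for k, ev in enumerate(events[leg]):
            stride_rows.append(
                {
                    "leg": leg,
                    "stride": k,
                    "start_frame": ev.start,
                    "end_frame": ev.end,
                    "duration_ms": ev.duration_ms,
                    "period_ms": ev.period_ms,
                    "displacement_mm": ev.displacement_mm,
                    "path_mm": ev.path_mm,
                    "amplitude_mm": ev.amplitude_mm,
                    "PEP_x_mm": ev.pep_mm[0],
                    "PEP_y_mm": ev.pep_mm[1],
                    "AEP_x_mm": ev.aep_mm[0],
                    "AEP_y_mm": ev.aep_mm[1],
                    "stance_linearity_mm": ev.stance_linearity_mm,
                    "stretch_mm": ev.stretch_mm,
                }
            )
    stride_table = pd.DataFrame(
        stride_rows,
        columns=[
            "leg", "stride", "start_frame", "end_frame", "duration_ms",
            "period_ms", "displacement_mm", "path_mm", "amplitude_mm",
            "PEP_x_mm", "PEP_y_mm", "AEP_x_mm", "AEP_y_mm",
            "stance_linearity_mm", "stretch_mm",
        ],
    )

    leg_rows = []
    for i in range(n):
        for j, leg in enumerate(legs):
            lp = per_leg[leg]
            dom = lp["domain"]
            leg_rows.append(
                {
                    "frame": i,
                    "leg": leg,
                    "speed_mm_s": lp["speed_mm_s"][i],
                    "in_swing": bool(lp["in_swing"][i]),
                    "gait_index": gi[i],
                    "movement_pct": lp["movement_pct"],
                    "mean_stride_period_ms": lp["mean_stride_period_ms"],
                    "footprint_regularity_mm": lp["footprint_regularity_mm"],
                    "domain_area_mm2": dom.area_mm2 if dom else np.nan,
                    "domain_length_mm": dom.length_mm if dom else np.nan,
                    "domain_width_mm": dom.width_mm if dom else np.nan,
                }
            )
    leg_table = pd.DataFrame(leg_rows)

    sw_mm = stance_width(events)
    stance_table = pd.DataFrame(
        {
            "stance_width_mm": [sw_mm],
            "n_stride_pairs": [min(len(events.get("L2", [])), len(events.get("R2", [])))],
        }
    )

    return GaitReport(
        poses=poses,
        body_length_mm=body_par["body_length_mm"],
        body_length_series_mm=body_par["body_length_series_mm"],
        body_velocity_mm_s=body_par["body_velocity_mm_s"],
        turning_points=body_par["turning_points"],
        events=events,
        domains=domains,
        gait_index_series=gi,
        stride_table=stride_table,
        leg_table=leg_table,
        domain_overlap=domain_overlap(domains, mean_strides),
        stance_width_table=stance_table,
    )
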