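"""Body pose, claw-tip detection, identity tracking and manual corrections.

Per frame, the animal's pose (silhouette centroid plus principal-axis
orientation) defines a body-centred frame: points are translated by the
centroid and rotated so the anterior direction maps onto +y. Claw candidates
are skeleton endpoints of each segmented leg component, keeping per component
the endpoint farthest from the body centroid. Identities are initialized on
the first frame showing the expected number of tips (split left/right by
body-frame x sign, ranked front-to-hind by y) and then propagated by a
minimum-total-squared-distance assignment (Hungarian algorithm) gated at
20 px per frame: a tip farther than the gate from every active leg cannot be
matched, and legs that find no tip are carried as missing with their
last-seen position available for re-matching leftover tips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.morphology import skeletonize

from .imaging_io import LEG_LABELS_6, SilhouetteMask
from .leg_segmentation import LegSegmentation

__all__ = [
    "BodyPose",
    "TipSet",
    "TrackSet",
    "Correction",
    "body_pose",
    "to_body_frame",
    "from_body_frame",
    "find_claw_candidates",
    "initialize_tracks",
    "assign_tips",
    "track_claws",
    "apply_corrections",
    "filter_spikes",
    "DEFAULT_GATE_PX",
]

logger = logging.getLogger(__name__)

DEFAULT_GATE_PX = 20.0  # at 512-px frame width; scaled for other resolutions


class InitializationError(RuntimeError):
    pass


@dataclass
class BodyPose:
    centroid: np.ndarray  # (x, y) arena px
    theta: float  # body-axis angle vs image y-axis, degrees, (-90, 90]
    axis: np.ndarray  # anterior unit vector (x, y)
    frame_index: int = -1
    length_px: float = 0.0  # silhouette extent along the body axis


@dataclass
class TipSet:
    tips_body: np.ndarray  # (m, 2) body-frame px
    tips_arena: np.ndarray  # (m, 2)
    component_of: np.ndarray  # (m,)
    frame_index: int = -1

    def __len__(self) -> int:
        return self.tips_body.shape[0]


@dataclass
class Correction:
    frame_index: int
    leg: str
    x: float | None = None  # arena px; None marks the leg absent
    y: float | None = None

    @property
    def absent(self) -> bool:
        return self.x is None or self.y is None


@dataclass
class TrackSet:
    legs: tuple[str, ...]
    arena: np.ndarray  # (n_frames, L, 2), NaN while missing
    body: np.ndarray  # (n_frames, L, 2)
    missing: np.ndarray  # (n_frames, L) bool
    init_frame: int
    gate_px: float
    corrections: list[Correction] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.arena.shape[0]

    def missing_fraction(self) -> float:
        """Fraction of (frame, leg) slots missing from the init frame on."""
        m = self.missing[self.init_frame :]
        return float(m.mean()) if m.size else 1.0


# ---------------------------------------------------------------------------
# Pose and the body-centred frame
# ---------------------------------------------------------------------------


def body_pose(
    mask: SilhouetteMask,
    prev: BodyPose | None = None,
    motion_dir: np.ndarray | None = None,
) -> BodyPose:
    """Centroid + principal-axis orientation of a silhouette.

    The principal axis comes from the second central moments of the
    foreground; it is defined modulo 180 deg, so the anterior direction is
    disambiguated by the direction of travel (``motion_dir``) when available,
    else by continuity with the previous pose, else by placing the anterior
    on the broader (head + thorax) end. A degenerate (near-isotropic) mask
    inherits the previous frame's orientation.
    """
    ys, xs = np.nonzero(mask.mask)
    if ys.size == 0:
        raise ValueError("empty silhouette has no pose")
    pts = np.stack([xs, ys], axis=1).astype(np.float64)
    centroid = pts.mean(axis=0)
    d = pts - centroid
    cov = d.T @ d / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    degenerate = evals[1] < 1.2 * evals[0]
    if degenerate and prev is not None:
        axis = prev.axis.copy()
    else:
        axis = evecs[:, 1]  # major axis (x, y)

    if motion_dir is not None and np.linalg.norm(motion_dir) > 1e-9:
        if axis @ motion_dir < 0:
            axis = -axis
    elif prev is not None:
        if axis @ prev.axis < 0:
            axis = -axis
    else:
        # broader end is the head+thorax: compare spread perpendicular to the
        # axis between the two halves along the axis
        along = d @ axis
        perp = d @ np.array([-axis[1], axis[0]])
        front = along > 0
        if front.sum() and (~front).sum():
            if np.std(perp[front]) < np.std(perp[~front]):
                axis = -axis
                along = -along

    theta = float(np.degrees(np.arctan2(axis[0], -axis[1])))
    if theta > 90.0:
        theta -= 180.0
    elif theta <= -90.0:
        theta += 180.0

    along = d @ axis
    return BodyPose(
        centroid=centroid,
        theta=theta,
        axis=axis / np.linalg.norm(axis),
        frame_index=mask.frame_index,
        length_px=float(along.max() - along.min()),
    )


def _lateral(axis: np.ndarray) -> np.ndarray:
    """Body +x unit vector for an anterior unit vector."""
    return np.array([-axis[1], axis[0]])


def to_body_frame(points: np.ndarray, pose: BodyPose) -> np.ndarray:
    """Arena -> body frame: translate by the centroid, rotate anterior to +y."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    d = pts - pose.centroid
    ux = _lateral(pose.axis)
    out = np.stack([d @ ux, d @ pose.axis], axis=1)
    return out if np.asarray(points).ndim == 2 else out[0]


def from_body_frame(points: np.ndarray, pose: BodyPose) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    ux = _lateral(pose.axis)
    out = pose.centroid + pts[:, :1] * ux + pts[:, 1:] * pose.axis
    return out if np.asarray(points).ndim == 2 else out[0]


# ---------------------------------------------------------------------------
# Claw candidates
# ---------------------------------------------------------------------------

_NEIGHBOUR_KERNEL = np.ones((3, 3), dtype=int)
_NEIGHBOUR_KERNEL[1, 1] = 0


def find_claw_candidates(seg: LegSegmentation, pose: BodyPose) -> TipSet:
    """Per leg component: skeletonize, then keep the skeleton endpoint at
    maximal distance from the body centroid. Closed-loop components (no
    endpoint) are skipped.
    """
    fg = seg.labels > 0
    tips_a: list[np.ndarray] = []
    comp: list[int] = []
    if fg.any():
        skel = skeletonize(fg)
        nb = ndimage.convolve(skel.astype(int), _NEIGHBOUR_KERNEL, mode="constant")
        endpoints = skel & (nb == 1)
        # single isolated skeleton pixels count as their own endpoint
        endpoints |= skel & (nb == 0)
        for k in range(1, seg.n_components + 1):
            eys, exs = np.nonzero(endpoints & (seg.labels == k))
            if eys.size == 0:
                logger.debug("component %d has no skeleton endpoint; skipped", k)
                continue
            pts = np.stack([exs, eys], axis=1).astype(np.float64)
            d2 = np.sum((pts - pose.centroid) ** 2, axis=1)
            tips_a.append(pts[int(np.argmax(d2))])
            comp.append(k)
    tips_arena = np.array(tips_a).reshape(-1, 2)
    return TipSet(
        tips_body=to_body_frame(tips_arena, pose) if len(tips_a) else np.empty((0, 2)),
        tips_arena=tips_arena,
        component_of=np.asarray(comp, dtype=int),
        frame_index=seg.frame_index,
    )


# ---------------------------------------------------------------------------
# Identity initialization and frame-to-frame assignment
# ---------------------------------------------------------------------------


def _label_by_geometry(tips_body: np.ndarray, legs: Sequence[str]) -> np.ndarray | None:
    """Order tips to match ``legs``: left/right by x sign, front-to-hind by y.

    Returns per-leg tip indices, or ``None`` if the left/right split does not
    match the expected count per side.
    """
    per_side = len(legs) // 2
    left = np.flatnonzero(tips_body[:, 0] < 0)
    right = np.flatnonzero(tips_body[:, 0] >= 0)
    if len(left) != per_side or len(right) != per_side:
        return None
    order = np.empty(len(legs), dtype=int)
    left_sorted = left[np.argsort(-tips_body[left, 1])]  # front = largest y
    right_sorted = right[np.argsort(-tips_body[right, 1])]
    for rank in range(per_side):
        order[legs.index(f"L{rank + 1}")] = left_sorted[rank]
        order[legs.index(f"R{rank + 1}")] = right_sorted[rank]
    return order


def initialize_tracks(
    tipsets: Sequence[TipSet],
    n_legs: int = 6,
    legs: Sequence[str] | None = None,
    gate_px: float = DEFAULT_GATE_PX,
    manual_first_frame: dict[str, tuple[float, float]] | None = None,
) -> TrackSet:
    """Label legs at the first frame with the expected number of tips.

    With ``manual_first_frame`` (label -> body-frame position), identities
    are seeded from the user's marks instead — used for animals whose resting
    geometry defeats the left/right ranking (e.g. eight-legged arachnids).
    """
    legs = list(legs) if legs is not None else (
        list(LEG_LABELS_6) if n_legs == 6 else [f"{s}{i}" for s in "LR" for i in range(1, n_legs // 2 + 1)]
    )
    n = len(tipsets)
    arena = np.full((n, n_legs, 2), np.nan)
    body = np.full((n, n_legs, 2), np.nan)
    missing = np.ones((n, n_legs), dtype=bool)

    if manual_first_frame is not None:
        init = 0
        ts = tipsets[0]
        for j, leg in enumerate(legs):
            p = np.asarray(manual_first_frame[leg], dtype=np.float64)
            if len(ts):
                d2 = np.sum((ts.tips_body - p) ** 2, axis=1)
                k = int(np.argmin(d2))
                body[0, j] = ts.tips_body[k]
                arena[0, j] = ts.tips_arena[k]
            else:
                body[0, j] = p
            missing[0, j] = False
        return TrackSet(tuple(legs), arena, body, missing, init, gate_px)

    best_frame, best_count = -1, -1
    for i, ts in enumerate(tipsets):
        if len(ts) == n_legs:
            order = _label_by_geometry(ts.tips_body, legs)
            if order is not None:
                arena[i] = ts.tips_arena[order]
                body[i] = ts.tips_body[order]
                missing[i] = False
                return TrackSet(tuple(legs), arena, body, missing, i, gate_px)
        if abs(len(ts) - n_legs) < abs(best_count - n_legs):
            best_frame, best_count = i, len(ts)
    raise InitializationError(
        f"no frame shows exactly {n_legs} labelable tips; closest was frame "
        f"{best_frame} with {best_count}"
    )


def _gated_assignment(
    sources: np.ndarray, targets: np.ndarray, gate_px: float
) -> list[tuple[int, int]]:
    """Min-total-squared-distance injective matching within a hard gate."""
    if sources.shape[0] == 0 or targets.shape[0] == 0:
        return []
    d2 = np.sum((sources[:, None, :] - targets[None, :, :]) ** 2, axis=2)
    gate2 = gate_px * gate_px
    big = 4.0 * gate2 * max(sources.shape[0], targets.shape[0]) + 1.0
    cost = np.where(d2 <= gate2, d2, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if d2[i, j] <= gate2]


def assign_tips(
    positions: np.ndarray,
    active: np.ndarray,
    last_seen: np.ndarray,
    tips: TipSet,
    gate_px: float = DEFAULT_GATE_PX,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One tracking step in body-frame coordinates.

    ``positions``: (L, 2) body-frame positions at the previous frame (NaN for
    missing legs); ``active``: which legs were present; ``last_seen``: (L, 2)
    last known body-frame position of every leg. Returns (new_positions,
    matched_mask, tip_indices) where ``tip_indices[j]`` is the tip matched to
    leg j (or -1).
    """
    L = positions.shape[0]
    new_pos = np.full((L, 2), np.nan)
    matched = np.zeros(L, dtype=bool)
    tip_idx = np.full(L, -1, dtype=int)
    m = len(tips)
    if m == 0:
        return new_pos, matched, tip_idx

    act = np.flatnonzero(active)
    pairs = _gated_assignment(positions[act], tips.tips_body, gate_px)
    used = set()
    for i, j in pairs:
        leg = act[i]
        new_pos[leg] = tips.tips_body[j]
        matched[leg] = True
        tip_idx[leg] = j
        used.add(j)

    # second pass: missing legs vs leftover tips, matched on last-seen position
    leftover = np.array([j for j in range(m) if j not in used], dtype=int)
    lost = np.array(
        [j for j in range(L) if not matched[j] and np.isfinite(last_seen[j, 0])],
        dtype=int,
    )
    if leftover.size and lost.size:
        pairs2 = _gated_assignment(last_seen[lost], tips.tips_body[leftover], gate_px)
        for i, j in pairs2:
            leg = lost[i]
            tip = leftover[j]
            new_pos[leg] = tips.tips_body[tip]
            matched[leg] = True
            tip_idx[leg] = tip
            used.add(tip)

    if len(used) < m:
        logger.debug("%d unassigned tips discarded", m - len(used))
    return new_pos, matched, tip_idx


def track_claws(
    tipsets: Sequence[TipSet],
    poses: Sequence[BodyPose],
    n_legs: int = 6,
    gate_px: float | None = None,
    image_width: int = 512,
    manual_first_frame: dict[str, tuple[float, float]] | None = None,
) -> TrackSet:
    """Full tracking pass: initialize identities, then assign frame by frame."""
    if gate_px is None:
        gate_px = DEFAULT_GATE_PX * (512.0 / image_width)
    tracks = initialize_tracks(
        tipsets, n_legs=n_legs, gate_px=gate_px,
        manual_first_frame=manual_first_frame,
    )
    _run_forward(tracks, tipsets, poses, start=tracks.init_frame + 1)
    return tracks


def _run_forward(
    tracks: TrackSet,
    tipsets: Sequence[TipSet],
    poses: Sequence[BodyPose],
    start: int,
) -> None:
    n = tracks.n_frames
    last_seen = tracks.body[start - 1].copy()
    for j in range(tracks.legs.__len__()):
        if not np.isfinite(last_seen[j, 0]):
            prior = tracks.body[: start, j]
            fin = np.flatnonzero(np.isfinite(prior[:, 0]))
            if fin.size:
                last_seen[j] = prior[fin[-1]]
    for i in range(start, n):
        prev = tracks.body[i - 1]
        active = ~tracks.missing[i - 1]
        new_pos, matched, _ = assign_tips(
            prev, active, last_seen, tipsets[i], tracks.gate_px
        )
        tracks.body[i] = new_pos
        tracks.missing[i] = ~matched
        for j in np.flatnonzero(matched):
            last_seen[j] = new_pos[j]
            tracks.arena[i, j] = from_body_frame(new_pos[j], poses[i])
        tracks.arena[i, ~matched] = np.nan


# ---------------------------------------------------------------------------
# Manual corrections & spike filtering
# ---------------------------------------------------------------------------


def apply_corrections(
    tracks: TrackSet,
    fixes: Sequence[Correction],
    tipsets: Sequence[TipSet],
    poses: Sequence[BodyPose],
    fps: float = 1000.0,
    image_shape: tuple[int, int] = (512, 512),
) -> TrackSet:
    """Overwrite positions (or mark absent) and re-track from the fix onward.

    After re-tracking, displacement spikes completing within 1 ms are
    filtered from analysis (marked missing). Returns a new TrackSet.
    """
    out = TrackSet(
        legs=tracks.legs,
        arena=tracks.arena.copy(),
        body=tracks.body.copy(),
        missing=tracks.missing.copy(),
        init_frame=tracks.init_frame,
        gate_px=tracks.gate_px,
        corrections=list(tracks.corrections),
    )
    if not fixes:
        return out
    earliest = tracks.n_frames
    H, W = image_shape
    for fx in fixes:
        j = out.legs.index(fx.leg)
        if fx.absent:
            out.body[fx.frame_index, j] = np.nan
            out.arena[fx.frame_index, j] = np.nan
            out.missing[fx.frame_index, j] = True
        else:
            if not (0 <= fx.x < W and 0 <= fx.y < H):
                raise ValueError(
                    f"correction for {fx.leg}@{fx.frame_index} is outside the image"
                )
            p = np.array([fx.x, fx.y], dtype=np.float64)
            out.arena[fx.frame_index, j] = p
            out.body[fx.frame_index, j] = to_body_frame(p, poses[fx.frame_index])
            out.missing[fx.frame_index, j] = False
        out.corrections.append(fx)
        earliest = min(earliest, fx.frame_index)
    if earliest + 1 < tracks.n_frames:
        _run_forward(out, tipsets, poses, start=earliest + 1)
    filter_spikes(out, fps)
    return out


def filter_spikes(tracks: TrackSet, fps: float, thresh_px: float = 5.0) -> int:
    """Mark single out-and-back jumps completing within 1 ms as missing.

    Returns the number of filtered (frame, leg) samples.
    """
    span = max(1, int(round(fps / 1000.0)))  # frames per millisecond
    n_filtered = 0
    for j in range(len(tracks.legs)):
        p = tracks.body[:, j]
        for i in range(1, tracks.n_frames - span):
            a, b, c = p[i - 1], p[i], p[i + span]
            if np.isfinite(a[0]) and np.isfinite(b[0]) and np.isfinite(c[0]):
                if (
                    np.hypot(*(b - a)) > thresh_px
                    and np.hypot(*(b - c)) > thresh_px
                    and np.hypot(*(c - a)) <= thresh_px
                ):
                    tracks.body[i, j] = np.nan
                    tracks.arena[i, j] = np.nan
                    tracks.missing[i, j] = True
                    n_filtered += 1
    return n_filtered
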