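"""Deterministic synthetic walking videos and claw traces with ground truth.

The renderer emulates the recording regime the tracking pipeline is built
for: a backlit arena imaged from below at high speed, so the animal appears
as a dark silhouette (body ellipse plus wing lobe, six — or eight — tapering
legs ending in ~3-px-wide tips) on a bright background. Defaults follow that
regime: 512 x 512 px frames over a 10 mm field of view, 1,000 fps, a body
about 133 px long, and at least 1.5 body lengths of travel over the clip.

Rendering is done on a 2x supersampled boolean canvas and box-downsampled to
8-bit grayscale, which produces the blurred, partially covered pixels at leg
edges that real backlit recordings show. Everything is driven by a single
seed: identical parameters give bit-identical stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .imaging_io import FrameStack, LEG_LABELS_6

__all__ = [
    "WalkerParams",
    "GroundTruth",
    "render_walker_video",
    "synth_trace",
    "synth_gait_pattern",
]

_SS = 2  # supersampling factor


@dataclass
class WalkerParams:
    """Geometry, kinematics and imaging parameters of a synthetic walker."""

    image_size: int = 512
    fov_mm: float = 10.0
    fps: float = 1000.0
    n_frames: int = 600
    body_length_px: float = 133.0
    body_width_px: float = 40.0
    leg_base_width_px: float = 4.5
    tip_width_px: float = 3.0
    gait_mode: str = "tripod"  # {"tripod", "tetrapod", "custom"}
    custom_schedule: np.ndarray | None = None  # (n_frames, n_legs) bool
    cycle_ms: float = 100.0
    swing_ms: float = 50.0
    stride_mm: float = 1.0
    # default stride/cycle gives ~2.3 body lengths of travel over 600 frames,
    # comfortably above the 1.5-body-length minimum the automated background
    # estimate needs (a pixel must be animal-free in most sampled frames)
    path: str = "straight"  # or "zigzag"
    zigzag_bend_deg: float = 60.0
    zigzag_period_frames: int = 200
    tremor_hz: float = 0.0
    tremor_amp_px: float = 0.0
    tremor_legs: tuple[str, ...] = ()
    occlusions: tuple[tuple[str, int, int], ...] = ()  # (leg, start, n_frames)
    contrast: str = "default"  # {"default", "low", "high"}
    noise_sd: float = 2.0
    n_legs: int = 6
    seed: int = 0

    @property
    def mm_per_px(self) -> float:
        return self.fov_mm / self.image_size

    @property
    def stride_px(self) -> float:
        return self.stride_mm / self.mm_per_px

    @property
    def body_speed_px(self) -> float:
        """Pixels travelled per frame: one stride per gait cycle."""
        frames_per_cycle = self.cycle_ms * self.fps / 1000.0
        return self.stride_px / frames_per_cycle


@dataclass
class GroundTruth:
    """Per-frame truth matching a rendered stack pixel-for-pixel."""

    legs: tuple[str, ...]
    centroid: np.ndarray  # (n, 2) model body centre, arena px
    axis: np.ndarray  # (n, 2) anterior unit vector
    theta: np.ndarray  # (n,) body-axis angle vs image y-axis, deg
    claws_arena: np.ndarray  # (n, L, 2)
    claws_body: np.ndarray  # (n, L, 2)
    swing: np.ndarray  # (n, L) bool
    hidden: np.ndarray  # (n, L) bool (occluded, not rendered)
    _leg_masks: np.ndarray  # packed bits, (n, packed_len)
    _ignore_masks: np.ndarray
    _mask_shape: tuple[int, int] = (512, 512)

    def leg_mask(self, i: int) -> np.ndarray:
        """True leg pixels of frame ``i`` (full leg coverage, outside body)."""
        return _unpack(self._leg_masks[i], self._mask_shape)

    def ignore_mask(self, i: int) -> np.ndarray:
        """Pixels excluded from pixel-level scoring of frame ``i``.

        Partially covered (anti-aliased) leg-edge pixels and leg pixels
        overlapping the body carry no reliable label, mirroring how blurred
        leg edges are zero-weighted when scoring segmentations of real
        recordings.
        """
        return _unpack(self._ignore_masks[i], self._mask_shape)


def _pack(mask: np.ndarray) -> np.ndarray:
    return np.packbits(mask.ravel())


def _unpack(packed: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    n = shape[0] * shape[1]
    return np.unpackbits(packed, count=n).astype(bool).reshape(shape)


# ---------------------------------------------------------------------------
# Gait schedules
# ---------------------------------------------------------------------------

_TRIPOD_A = ("L1", "L3", "R2")
_TRIPOD_B = ("R1", "R3", "L2")
#: tetrapod wave: three diagonal pairs swinging in sequence
_TETRAPOD_PAIRS = (("L1", "R2"), ("L2", "R3"), ("L3", "R1"))


def synth_gait_pattern(
    mode: str,
    fps: float,
    n_frames: int,
    cycle_ms: float = 100.0,
    swing_ms: float | None = None,
    legs: Sequence[str] = LEG_LABELS_6,
    custom: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean swing schedule, shape ``(n_frames, len(legs))``.

    ``tripod``: the two canonical tripod sets alternate; with the default
    ``swing_ms = cycle/2`` exactly three legs swing at every instant.
    ``tetrapod``: the three diagonal pairs swing in sequence; with the
    default ``swing_ms = cycle/3`` exactly two legs swing at every instant.
    ``custom``: a user-supplied table is validated and returned.
    """
    legs = list(legs)
    if mode == "custom":
        if custom is None:
            raise ValueError("custom mode needs a schedule table")
        sched = np.asarray(custom, dtype=bool)
        if sched.shape != (n_frames, len(legs)):
            raise ValueError("custom schedule has wrong shape")
        return sched

    frames_per_cycle = max(2, int(round(cycle_ms * fps / 1000.0)))
    sched = np.zeros((n_frames, len(legs)), dtype=bool)
    t = np.arange(n_frames)
    phase = t % frames_per_cycle

    if mode == "tripod":
        half = frames_per_cycle // 2
        sw = half if swing_ms is None else int(round(swing_ms * fps / 1000.0))
        sw = min(sw, half)
        set_a = [legs.index(l) for l in _TRIPOD_A]
        set_b = [legs.index(l) for l in _TRIPOD_B]
        a_on = phase < sw
        b_on = (phase >= half) & (phase < half + sw)
        for i in set_a:
            sched[a_on, i] = True
        for i in set_b:
            sched[b_on, i] = True
        return sched

    if mode == "tetrapod":
        # the cycle must divide evenly into the three pair slots, otherwise a
        # leftover frame each cycle has no swinging pair
        third = max(1, int(round(frames_per_cycle / 3.0)))
        phase = t % (3 * third)
        sw = third if swing_ms is None else int(round(swing_ms * fps / 1000.0))
        sw = min(sw, third)
        for k, pair in enumerate(_TETRAPOD_PAIRS):
            on = (phase >= k * third) & (phase < k * third + sw)
            for l in pair:
                sched[on, legs.index(l)] = True
        return sched

    raise ValueError(f"unknown gait mode: {mode}")


# ---------------------------------------------------------------------------
# Walker kinematics
# ---------------------------------------------------------------------------

# neutral body-frame positions (x lateral, y anterior), units: fraction of
# body length; scaled at render time. Left legs mirror x.
_ATTACH = {"1": (0.12, 0.26), "2": (0.15, 0.0), "3": (0.12, -0.26)}
_CLAW = {"1": (0.33, 0.44), "2": (0.42, 0.04), "3": (0.35, -0.39)}


def _leg_geometry(params: WalkerParams, leg: str) -> tuple[np.ndarray, np.ndarray]:
    """(attach, neutral claw) in body-frame px for one leg label."""
    side = -1.0 if leg[0] == "L" else 1.0
    row = leg[1]
    L = params.body_length_px
    attach = np.array([side * _ATTACH[row][0] * L, _ATTACH[row][1] * L])
    claw = np.array([side * _CLAW[row][0] * L, _CLAW[row][1] * L])
    return attach, claw


def _heading_sequence(params: WalkerParams) -> np.ndarray:
    """(n, 2) unit anterior vectors per frame (image coords, y = row)."""
    n = params.n_frames
    if params.path == "straight":
        h = np.tile(np.array([0.0, -1.0]), (n, 1))  # walking "up" the image
        return h
    if params.path == "zigzag":
        # alternate between two headings differing by the bend angle
        half = math.radians(params.zigzag_bend_deg) / 2.0
        h = np.empty((n, 2))
        seg = (np.arange(n) // params.zigzag_period_frames) % 2
        for s, sign in ((0, -1.0), (1, 1.0)):
            ang = sign * half
            h[seg == s] = (math.sin(ang), -math.cos(ang))
        return h
    raise ValueError(f"unknown path: {params.path}")


def _body_frame_axes(heading: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Anterior (+y) and lateral (+x) unit vectors of the body frame."""
    uy = heading
    ux = np.stack([-uy[:, 1], uy[:, 0]], axis=1)
    return ux, uy


def _smoothstep(s: np.ndarray | float) -> np.ndarray | float:
    return s * s * (3.0 - 2.0 * s)


def render_walker_video(params: WalkerParams) -> tuple[FrameStack, GroundTruth]:
    """Render a silhouette walking video plus full ground truth.

    Kinematics: during stance a claw is pinned to its arena position; during
    a scheduled swing it travels, in the body frame, from its take-off
    position to the anterior extreme position (neutral + stride/2 forward)
    along a smooth-step path with a small lateral bow. The body advances one
    stride length per gait cycle, so the steady-state stride of every leg
    equals ``stride_mm``. Optional occlusion episodes hide a leg (it is not
    rendered and its truth row is flagged hidden); optional tremor adds a
    lateral body-frame oscillation to chosen claws.
    """
    p = params
    n, H = p.n_frames, p.image_size
    legs = LEG_LABELS_6[: p.n_legs] if p.n_legs == 6 else (
        "L1",
        "L2",
        "L3",
        "L4",
        "R1",
        "R2",
        "R3",
        "R4",
    )
    if p.n_legs != 6:
        raise ValueError("only the 6-legged walker is rendered; use n_legs=6")
    rng = np.random.default_rng(p.seed)

    sched = synth_gait_pattern(
        p.gait_mode,
        p.fps,
        n,
        cycle_ms=p.cycle_ms,
        swing_ms=p.swing_ms,
        legs=legs,
        custom=p.custom_schedule,
    )
    # hold the first 10 frames in full stance so tracking can initialize on a
    # clean six-tip frame
    sched[:10] = False

    heading = _heading_sequence(p)
    ux, uy = _body_frame_axes(heading)

    # body centre path
    centre = np.empty((n, 2))
    margin = p.body_length_px * 0.75
    c = np.array([H / 2.0, H - margin - 2.0])
    travel = p.body_speed_px
    for i in range(n):
        centre[i] = c
        c = c + heading[i] * travel
    # keep the body inside the arena
    if (centre.min() < margin) or (centre.max() > H - margin):
        raise ValueError("infeasible geometry: walker leaves the arena")

    theta = np.degrees(np.arctan2(heading[:, 0], -heading[:, 1]))
    theta = np.where(theta > 90.0, theta - 180.0, theta)
    theta = np.where(theta <= -90.0, theta + 180.0, theta)

    hidden = np.zeros((n, p.n_legs), dtype=bool)
    for leg, start, length in p.occlusions:
        hidden[start : start + length, legs.index(leg)] = True

    # --- claw kinematics ------------------------------------------------
    claws_body = np.empty((n, p.n_legs, 2))
    claws_arena = np.empty((n, p.n_legs, 2))
    stride = p.stride_px
    bow_px = 2.0

    def to_arena(i: int, pb: np.ndarray) -> np.ndarray:
        return centre[i] + pb[0] * ux[i] + pb[1] * uy[i]

    def to_body(i: int, pa: np.ndarray) -> np.ndarray:
        d = pa - centre[i]
        return np.array([d @ ux[i], d @ uy[i]])

    for j, leg in enumerate(legs):
        _, neutral = _leg_geometry(p, leg)
        aep = neutral + np.array([0.0, stride / 2.0])
        side = -1.0 if leg[0] == "L" else 1.0
        pb = aep - np.array([0.0, stride * 0.5])  # start mid-stance
        pa = to_arena(0, pb)
        swing_col = sched[:, j]
        # precompute swing run boundaries
        starts = np.flatnonzero(swing_col & ~np.roll(swing_col, 1))
        if swing_col[0]:
            starts = np.unique(np.concatenate([[0], starts]))
        run_start = {int(s): True for s in starts}
        t0 = -1
        pb_start = pb.copy()
        for i in range(n):
            if hidden[i, j]:
                # frozen in the body frame while occluded
                pa = to_arena(i, pb)
            elif swing_col[i]:
                if i in run_start or t0 < 0:
                    t0 = i
                    pb_start = pb.copy()
                run = np.flatnonzero(~swing_col[i:])
                t1 = i + int(run[0]) if run.size else n
                dur = max(1, t1 - t0)
                s = _smoothstep((i - t0 + 1) / dur)
                pb = pb_start + s * (aep - pb_start)
                pb = pb + np.array([side * bow_px * math.sin(math.pi * s), 0.0])
                pa = to_arena(i, pb)
            else:
                t0 = -1
                pb = to_body(i, pa)  # pinned in the arena
            if p.tremor_amp_px > 0 and leg in p.tremor_legs:
                osc = p.tremor_amp_px * math.sin(
                    2.0 * math.pi * p.tremor_hz * i / p.fps
                )
                claws_body[i, j] = pb + np.array([osc, 0.0])
            else:
                claws_body[i, j] = pb
            claws_arena[i, j] = to_arena(i, claws_body[i, j])

    # --- rendering -------------------------------------------------------
    if p.contrast == "default":
        bg_val, fg_val = 200.0, 60.0
    elif p.contrast == "low":
        bg_val, fg_val = 200.0, 140.0
    elif p.contrast == "high":
        bg_val, fg_val = 230.0, 30.0
    else:
        raise ValueError(f"unknown contrast: {p.contrast}")

    frames = np.empty((n, H, H), dtype=np.uint8)
    leg_masks = np.empty((n, H * H // 8), dtype=np.uint8)
    ignore_masks = np.empty_like(leg_masks)

    S = _SS
    for i in range(n):
        body = np.zeros((H * S, H * S), dtype=bool)
        legcv = np.zeros_like(body)
        # body: main ellipse + posterior wing lobe
        L = p.body_length_px
        _draw_ellipse(body, centre[i] * S, ux[i], uy[i], 0.45 * L * S, 0.5 * p.body_width_px * S)
        wing_c = centre[i] + uy[i] * (-0.30 * L)
        _draw_ellipse(body, wing_c * S, ux[i], uy[i], 0.25 * L * S, 0.35 * p.body_width_px * S)
        for j, leg in enumerate(legs):
            if hidden[i, j]:
                continue
            attach_b, _ = _leg_geometry(p, leg)
            a = to_arena(i, attach_b)
            clw = claws_arena[i, j]
            side = -1.0 if leg[0] == "L" else 1.0
            mid_b = attach_b + 0.55 * (claws_body[i, j] - attach_b)
            mid_b = mid_b + np.array([side * 0.10 * L, 0.0])
            knee = to_arena(i, mid_b)
            w0, w1 = p.leg_base_width_px, p.tip_width_px
            wm = 0.5 * (w0 + w1)
            _draw_segment(legcv, a * S, knee * S, w0 * S / 2, wm * S / 2)
            _draw_segment(legcv, knee * S, clw * S, wm * S / 2, w1 * S / 2)

        alpha_body = _downsample(body, S)
        alpha_leg = _downsample(legcv, S)
        alpha = np.maximum(alpha_body, alpha_leg)
        img = bg_val - (bg_val - fg_val) * alpha
        if p.noise_sd > 0:
            img = img + rng.normal(0.0, p.noise_sd, img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

        leg_core = (alpha_leg >= 0.5) & (alpha_body < 0.5)
        ignore = ((alpha_leg > 0) & (alpha_leg < 1.0)) | (
            (alpha_leg >= 0.5) & (alpha_body >= 0.5)
        )
        leg_masks[i] = _pack(leg_core)
        ignore_masks[i] = _pack(ignore)

    stack = FrameStack(
        frames=frames,
        frame_rate=p.fps,
        mm_per_px=p.mm_per_px,
        source_dir="<synthetic>",
    )
    truth = GroundTruth(
        legs=tuple(legs),
        centroid=centre,
        axis=uy.copy(),
        theta=theta,
        claws_arena=claws_arena,
        claws_body=claws_body,
        swing=sched,
        hidden=hidden,
        _leg_masks=leg_masks,
        _ignore_masks=ignore_masks,
        _mask_shape=(H, H),
    )
    return stack, truth


def _draw_ellipse(
    canvas: np.ndarray,
    centre: np.ndarray,
    ux: np.ndarray,
    uy: np.ndarray,
    a_along: float,
    b_across: float,
) -> None:
    """OR an ellipse (semi-axis ``a_along`` along uy, ``b_across`` along ux)."""
    H, W = canvas.shape
    r = int(math.ceil(max(a_along, b_across))) + 2
    x0 = max(0, int(centre[0]) - r)
    x1 = min(W, int(centre[0]) + r + 1)
    y0 = max(0, int(centre[1]) - r)
    y1 = min(H, int(centre[1]) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xx, yy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    dx = xx - centre[0]
    dy = yy - centre[1]
    along = dx * uy[0] + dy * uy[1]
    across = dx * ux[0] + dy * ux[1]
    inside = (along / a_along) ** 2 + (across / b_across) ** 2 <= 1.0
    canvas[y0:y1, x0:x1] |= inside


def _draw_segment(
    canvas: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    r0: float,
    r1: float,
) -> None:
    """OR a thick segment with radius tapering linearly from ``r0`` to ``r1``."""
    H, W = canvas.shape
    rmax = max(r0, r1) + 2
    x0 = max(0, int(min(a[0], b[0]) - rmax))
    x1 = min(W, int(max(a[0], b[0]) + rmax) + 1)
    y0 = max(0, int(min(a[1], b[1]) - rmax))
    y1 = min(H, int(max(a[1], b[1]) + rmax) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xx, yy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    ab = b - a
    den = float(ab @ ab)
    if den == 0:
        den = 1.0
    t = ((xx - a[0]) * ab[0] + (yy - a[1]) * ab[1]) / den
    t = np.clip(t, 0.0, 1.0)
    px = a[0] + t * ab[0]
    py = a[1] + t * ab[1]
    d2 = (xx - px) ** 2 + (yy - py) ** 2
    rad = r0 + t * (r1 - r0)
    canvas[y0:y1, x0:x1] |= d2 <= rad * rad


def _downsample(canvas: np.ndarray, s: int) -> np.ndarray:
    H, W = canvas.shape
    return (
        canvas.reshape(H // s, s, W // s, s)
        .mean(axis=(1, 3))
        .astype(np.float64)
    )


# ---------------------------------------------------------------------------
# 1-D claw traces for tremor analysis
# ---------------------------------------------------------------------------


def synth_trace(
    freq_hz: float,
    amp_px: float,
    fps: float,
    n_frames: int,
    baseline: str = "stride",
    noise_px: float = 0.0,
    burst_ms: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """A smooth stride-like claw trace plus an optional lateral oscillation.

    Returns ``(trace, truth)`` where ``trace`` is an ``(n, 2)`` body-frame
    (x, y) series in pixels and ``truth`` lists the oscillation's extremum
    frames (``peaks`` where the lateral offset is maximal, ``valleys`` where
    minimal; exact only for ``noise_px = 0``). ``noise_px`` adds seeded
    Gaussian positional noise emulating the tracker's ~1-px jitter.
    ``burst_ms = (on, off)`` gates the oscillation with a square envelope,
    emulating episodic walking tremor rather than a continuous oscillation.
    Requesting ``freq_hz >= fps / 2`` is an aliasing error.
    """
    if freq_hz >= fps / 2.0:
        raise ValueError("oscillation frequency must be below fps/2 (Nyquist)")
    t = np.arange(n_frames) / fps
    if baseline == "stride":
        # smooth alternation between stance drift and swing advance
        cycle = 0.1  # s
        phase = (t % cycle) / cycle
        within = np.where(
            phase < 0.5,
            _smoothstep(phase / 0.5),  # swing: forward
            1.0 - (phase - 0.5) / 0.5,  # stance: drift back
        )
        y = 20.0 * within
    elif baseline == "flat":
        y = np.zeros(n_frames)
    else:
        raise ValueError(f"unknown baseline: {baseline}")

    x = np.zeros(n_frames)
    peaks: list[int] = []
    valleys: list[int] = []
    if amp_px > 0 and freq_hz > 0:
        x = amp_px * np.sin(2.0 * np.pi * freq_hz * t)
        envelope = np.ones(n_frames, dtype=bool)
        if burst_ms is not None:
            on = int(round(burst_ms[0] * fps / 1000.0))
            off = int(round(burst_ms[1] * fps / 1000.0))
            envelope = (np.arange(n_frames) % (on + off)) < on
            x = np.where(envelope, x, 0.0)
        period = fps / freq_hz
        k = 0
        while True:
            fp = (k + 0.25) * period
            fv = (k + 0.75) * period
            if fp < n_frames and envelope[int(round(fp))]:
                peaks.append(int(round(fp)))
            if fv < n_frames and envelope[int(round(fv))]:
                valleys.append(int(round(fv)))
            if fp >= n_frames and fv >= n_frames:
                break
            k += 1
    trace = np.stack([x, y], axis=1)
    if noise_px > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_px, trace.shape)
    truth = {
        "peaks": np.array(peaks, dtype=int),
        "valleys": np.array(valleys, dtype=int),
        "period_frames": (fps / freq_hz) if freq_hz > 0 else np.inf,
    }
    return trace, truth
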