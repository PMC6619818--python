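"""Shaking/tremor event detection, interval statistics and effect sizes.

A shaking event is a local extremum of the claw's deviation signal — the
offset of the body-frame trace from a 50-ms moving-average centreline,
computed per axis — whose magnitude is at least 3 px (roughly one leg-tip
width, and the tracking noise floor), with peaks and valleys alternating.
A tremor event is any shake belonging to a run of three or more shakes whose
consecutive gaps are all under 100 ms (strides themselves repeat at ~10 Hz,
so genuine rhythmic shaking is well inside that gate). The tremor frequency
is read off the distribution of intervals between consecutive same-polarity
extrema (full periods): an interval of T ms means a frequency of 1000/T Hz.

Cliff's delta is the nonparametric effect size used to compare a test group
against a control: the normalized excess of pairwise "greater" over
"smaller" comparisons, in [-1, +1]; confidence intervals come from a
percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "ShakeEvent",
    "TremorEvent",
    "EffectSize",
    "detect_shake_events",
    "detect_tremor_events",
    "interval_spectrum",
    "interval_permutation_test",
    "interval_to_frequency",
    "cliffs_delta",
    "bootstrap_ci",
]


@dataclass
class ShakeEvent:
    leg: str
    frame: int
    polarity: int  # +1 peak, -1 valley
    amplitude_px: float  # |deviation from the centreline| at the extremum
    axis: int = 0  # trace axis the extremum was found on


@dataclass
class TremorEvent:
    leg: str
    frames: np.ndarray  # member shake frames (>= 3)
    polarities: np.ndarray
    intervals_ms: np.ndarray  # gaps between consecutive members


@dataclass
class EffectSize:
    delta: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_boot: int = 0


# ---------------------------------------------------------------------------
# Shake / tremor detection
# ---------------------------------------------------------------------------


def _deviation(x: np.ndarray, fps: float, window_ms: float) -> np.ndarray:
    win = max(1, int(round(window_ms * fps / 1000.0)))
    centre = uniform_filter1d(x, size=win, mode="nearest")
    return x - centre


def _alternating_extrema(dev: np.ndarray, min_amp: float) -> list[tuple[int, int, float]]:
    """(frame, polarity, amplitude) of qualifying alternating extrema.

    Plateaus count once (their first frame). An extremum qualifies when its
    |deviation| is at least ``min_amp``; consecutive extrema of the same
    polarity are collapsed onto the stronger one so that peaks and valleys
    strictly alternate.
    """
    n = dev.shape[0]
    if n < 3:
        return []
    cand: list[tuple[int, int]] = []
    i = 1
    while i < n - 1:
        # skip forward over plateaus
        j = i
        while j < n - 1 and dev[j + 1] == dev[j]:
            j += 1
        if j >= n - 1:
            break
        if dev[i] > dev[i - 1] and dev[j] > dev[j + 1]:
            cand.append((i, +1))
        elif dev[i] < dev[i - 1] and dev[j] < dev[j + 1]:
            cand.append((i, -1))
        i = j + 1

    out: list[tuple[int, int, float]] = []
    for f, pol in cand:
        amp = pol * float(dev[f])  # signed: peaks above, valleys below zero
        if amp < min_amp:
            continue
        if out and out[-1][1] == pol:
            if amp > out[-1][2]:
                out[-1] = (f, pol, amp)
            continue
        out.append((f, pol, amp))
    return out


def detect_shake_events(
    trace: np.ndarray,
    fps: float = 1000.0,
    min_amp_px: float = 3.0,
    centreline_ms: float = 50.0,
    leg: str = "",
) -> list[ShakeEvent]:
    """Find shaking events on a body-frame claw trace.

    For an (n, 2) xy series the deviation signal is the signed perpendicular
    offset of the trace from its 50-ms moving-average centreline: the
    longitudinal component — ordinary stride progress, which departs from
    any short moving average by far more than 3 px on a walking leg — is
    discarded, so only lateral shaking registers. A 1-D trace is simply
    detrended by its centreline. Gaps of up to 5 frames are interpolated;
    traces shorter than the centreline window yield no events.
    """
    arr = np.asarray(trace, dtype=np.float64)
    n = arr.shape[0] if arr.ndim else 0
    win = max(1, int(round(centreline_ms * fps / 1000.0)))
    if arr.ndim == 0 or n < win:
        return []
    if arr.ndim == 1:
        dev = _deviation(_interp_nan(arr), fps, centreline_ms)
    else:
        xy = np.stack([_interp_nan(arr[:, 0]), _interp_nan(arr[:, 1])], axis=1)
        offset = np.stack(
            [_deviation(xy[:, k], fps, centreline_ms) for k in range(2)], axis=1
        )  # trace - moving average, per axis
        smooth = xy - offset
        # the claw travels back and forth along one dominant direction; the
        # deviation axis is the fixed perpendicular to it (an instantaneous
        # tangent would flip sign at every swing/stance reversal and destroy
        # the peak/valley alternation)
        d = np.gradient(smooth, axis=0)
        m = d.T @ d
        evals, evecs = np.linalg.eigh(m)
        perp = evecs[:, 0] if evals.sum() > 1e-12 else np.array([1.0, 0.0])
        dev = offset @ perp
    events: list[ShakeEvent] = []
    for f, pol, amp in _alternating_extrema(dev, min_amp_px):
        events.append(
            ShakeEvent(leg=leg, frame=f, polarity=pol, amplitude_px=amp, axis=0)
        )
    return events


def _interp_nan(x: np.ndarray, max_gap: int = 5) -> np.ndarray:
    out = x.copy()
    bad = ~np.isfinite(out)
    if bad.any():
        idx = np.arange(len(out))
        good = ~bad
        if good.sum() >= 2:
            out[bad] = np.interp(idx[bad], idx[good], out[good])
        else:
            out[bad] = 0.0
    return out


def detect_tremor_events(
    shakes: list[ShakeEvent],
    fps: float = 1000.0,
    max_gap_ms: float = 100.0,
    min_run: int = 3,
) -> list[TremorEvent]:
    """Group shakes into tremor runs: >= 3 shakes with gaps < 100 ms.

    Every shake inside a qualifying run counts as one tremor event, so a run
    of five shakes contributes five tremor events; the returned objects are
    the runs, whose member counts sum to the tremor-event total.
    """
    if not shakes:
        return []
    shakes = sorted(shakes, key=lambda e: e.frame)
    frames = np.array([e.frame for e in shakes], dtype=float)
    gaps_ms = np.diff(frames) * 1000.0 / fps
    runs: list[TremorEvent] = []
    start = 0
    for i in range(len(shakes)):
        last = i == len(shakes) - 1
        if last or gaps_ms[i] >= max_gap_ms:
            end = i + 1
            if end - start >= min_run:
                member_frames = frames[start:end].astype(int)
                runs.append(
                    TremorEvent(
                        leg=shakes[start].leg,
                        frames=member_frames,
                        polarities=np.array(
                            [shakes[k].polarity for k in range(start, end)]
                        ),
                        intervals_ms=np.diff(member_frames) * 1000.0 / fps,
                    )
                )
            start = i + 1
    return runs


def tremor_event_count(tremors: list[TremorEvent]) -> int:
    return int(sum(len(t.frames) for t in tremors))


def interval_spectrum(
    tremors: list[TremorEvent], fps: float = 1000.0, bin_ms: float = 10.0
) -> tuple[np.ndarray, np.ndarray, tuple[float, float] | None]:
    """Histogram of intervals between consecutive same-polarity extrema.

    Same-polarity intervals are full oscillation periods, so the dominant bin
    directly reflects the tremor frequency. Returns (bin_edges, counts,
    dominant_bin); empty input gives empty arrays and ``None``.
    """
    intervals = same_polarity_intervals(tremors, fps)
    if intervals.size == 0:
        return np.array([]), np.array([], dtype=int), None
    top = float(np.ceil(intervals.max() / bin_ms) + 1) * bin_ms
    edges = np.arange(0.0, top + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(intervals, bins=edges)
    k = int(np.argmax(counts))
    return edges, counts, (float(edges[k]), float(edges[k + 1]))


def same_polarity_intervals(tremors: list[TremorEvent], fps: float = 1000.0) -> np.ndarray:
    """Peak-to-peak and valley-to-valley intervals (ms) between tremor extrema.

    All tremor-member extrema of a leg are pooled (episodic tremor means the
    intervals that separate bursts belong to the distribution too) and the
    gaps between consecutive same-polarity extrema are returned.
    """
    out: list[float] = []
    by_leg: dict[str, list[TremorEvent]] = {}
    for run in tremors:
        by_leg.setdefault(run.leg, []).append(run)
    for runs in by_leg.values():
        frames = np.concatenate([r.frames for r in runs])
        pols = np.concatenate([r.polarities for r in runs])
        order = np.argsort(frames)
        frames, pols = frames[order], pols[order]
        for pol in (+1, -1):
            f = frames[pols == pol]
            if f.size >= 2:
                out.extend(np.diff(f) * 1000.0 / fps)
    return np.asarray(out, dtype=float)


def interval_permutation_test(
    intervals: np.ndarray,
    bin_range: tuple[float, float],
    n_iter: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for an excess of intervals in one histogram bin.

    The observed statistic is the fraction of intervals falling in
    ``bin_range``; the null redraws the same number of intervals uniformly
    over the observed interval range, ``n_iter`` times. The add-one
    convention p = (1 + #{null >= observed}) / (1 + n_iter) avoids zero
    p-values.
    """
    intervals = np.asarray(intervals, dtype=float)
    n = intervals.size
    if n < 5:
        raise ValueError("need at least 5 intervals for the permutation test")
    rng = rng or np.random.default_rng(0)
    lo, hi = bin_range
    obs = float(np.mean((intervals >= lo) & (intervals < hi)))
    lo_r, hi_r = float(intervals.min()), float(intervals.max())
    if hi_r <= lo_r:
        hi_r = lo_r + 1e-9
    count = 0
    chunk = max(1, min(n_iter, 2_000_000 // max(1, n)))
    done = 0
    while done < n_iter:
        k = min(chunk, n_iter - done)
        null = rng.uniform(lo_r, hi_r, size=(k, n))
        frac = np.mean((null >= lo) & (null < hi), axis=1)
        count += int(np.sum(frac >= obs))
        done += k
    return (1 + count) / (1 + n_iter)


def interval_to_frequency(interval_ms: float) -> float:
    """Oscillation frequency (Hz) of a full-period interval in milliseconds."""
    if interval_ms <= 0:
        raise ValueError("interval must be positive")
    return 1000.0 / interval_ms


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------


def cliffs_delta(a: np.ndarray, b: np.ndarray) -> EffectSize:
    """Cliff's delta of sample ``a`` versus control ``b``.

    delta = (#{a_i > b_j} - #{a_i < b_j}) / (|a| * |b|); +1 when every value
    of ``a`` exceeds every value of ``b``, -1 in the mirrored case, 0 for
    identical samples. Computed via sorted-array rank counting, equivalent to
    the brute-force double loop.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    bs = np.sort(b)
    greater = np.searchsorted(bs, a, side="left").sum()  # b_j < a_i
    less = (b.size - np.searchsorted(bs, a, side="right")).sum()  # b_j > a_i
    return EffectSize(delta=float((greater - less) / (a.size * b.size)))


def bootstrap_ci(
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int = 10_000,
    level: float = 95.0,
    rng: np.random.Generator | None = None,
) -> EffectSize:
    """Percentile-bootstrap confidence interval for Cliff's delta.

    Both samples are resampled with replacement ``n_boot`` times; the CI is
    the percentile interval of the resampled deltas, clipped to [-1, 1].
    Single-observation groups give a degenerate CI (warned via the result's
    width only — the point estimate is still exact).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    rng = rng or np.random.default_rng(0)
    point = cliffs_delta(a, b).delta
    na, nb = a.size, b.size
    deltas = np.empty(n_boot)
    chunk = max(1, min(n_boot, 4_000_000 // max(1, na * nb)))
    done = 0
    while done < n_boot:
        k = min(chunk, n_boot - done)
        ra = a[rng.integers(0, na, size=(k, na))]
        rb = b[rng.integers(0, nb, size=(k, nb))]
        sgn = np.sign(ra[:, :, None] - rb[:, None, :])
        deltas[done : done + k] = sgn.mean(axis=(1, 2))
        done += k
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(deltas, [alpha, 100.0 - alpha])
    return EffectSize(
        delta=point,
        ci_low=float(np.clip(lo, -1.0, 1.0)),
        ci_high=float(np.clip(hi, -1.0, 1.0)),
        n_boot=n_boot,
    )
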