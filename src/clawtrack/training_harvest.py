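"""Self-supervised harvesting of leg / non-leg training pixels.

No human annotation is used anywhere in the pipeline. High-confidence leg
pixels are found purely morphologically: on a silhouette mask, the medial-axis
skeleton and the mask boundary coincide only where the structure is thin —
i.e. on the legs — so their intersection yields positive (leg) samples with
high precision and low recall. Negatives come from the thick body core
(pixels whose distance to the mask boundary exceeds half the leg width) and
from a band of background pixels around the silhouette. Every other
foreground pixel is a low-confidence "grey" zone excluded from learning.

Samples are materialised as 41 x 41 grayscale patches centred on the chosen
pixels, labelled +1 (leg) / -1 (non-leg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import medial_axis

from .imaging_io import FrameStack, SilhouetteMask

__all__ = [
    "LabeledPixelPool",
    "TrainingPatchSet",
    "sample_training_frames",
    "harvest_confident_pixels",
    "extract_patches",
]


class HarvestError(RuntimeError):
    """Raised when one of the two classes has an empty pixel pool."""


@dataclass
class LabeledPixelPool:
    """Confident pixel coordinates, as (frame_index, x, y) triples."""

    positives: list[tuple[int, int, int]] = field(default_factory=list)
    negatives: list[tuple[int, int, int]] = field(default_factory=list)

    def extend(self, other: "LabeledPixelPool") -> None:
        self.positives.extend(other.positives)
        self.negatives.extend(other.negatives)

    def sizes(self) -> tuple[int, int]:
        return len(self.positives), len(self.negatives)


@dataclass
class TrainingPatchSet:
    patches: np.ndarray  # (n, p, p) float32, intensities scaled to [0, 1]
    labels: np.ndarray  # (n,) values in {+1, -1}
    weights: np.ndarray  # (n,) positive reals
    residuals: np.ndarray  # (n,)
    round_index: int = 0

    def __post_init__(self) -> None:
        n = self.patches.shape[0]
        if not (len(self.labels) == len(self.weights) == len(self.residuals) == n):
            raise ValueError("patch / label / weight / residual lengths differ")

    def __len__(self) -> int:
        return self.patches.shape[0]


def sample_training_frames(stack: FrameStack, stride: int = 20) -> list[int]:
    """One frame from every ``stride`` frames (all frames for short stacks)."""
    n = len(stack)
    if n < stride:
        return list(range(n))
    return list(range(0, n, stride))


def harvest_confident_pixels(
    mask: SilhouetteMask,
    frame: np.ndarray,
    leg_width_px: float = 5.0,
    edge_dilation: int = 1,
    bg_band: tuple[int, int] = (3, 20),
    rng: np.random.Generator | None = None,
    negative_body_fraction: float = 0.5,
) -> LabeledPixelPool:
    """Harvest confident leg / non-leg pixels from one silhouette.

    Positives: medial-axis skeleton intersected with the (1-px dilated)
    boundary of the mask — the thin-structure signature of legs. Negatives:
    an even mix of body-core pixels (distance-to-boundary > leg_width/2) and
    background pixels in a band ``bg_band`` px around the silhouette.
    """
    m = mask.mask
    if not m.any():
        raise ValueError("harvest needs a nonempty silhouette")
    rng = rng or np.random.default_rng(0)
    fi = mask.frame_index

    # fixed rng: medial_axis breaks ties randomly by default, and the harvest
    # must be a deterministic function of the mask
    skel, dist = medial_axis(m, return_distance=True, rng=0)
    boundary = m & ~ndimage.binary_erosion(m)
    if edge_dilation > 0:
        edges = ndimage.binary_dilation(boundary, structure=_disk(edge_dilation))
    else:
        edges = boundary
    pos = skel & edges

    core = ndimage.distance_transform_edt(m) > leg_width_px / 2.0
    # Extend the thick body core by a small margin back out to the mask edge:
    # this ring is body, not leg. It is harvested as negatives (the body's own
    # boundary has no other supervision and would otherwise be mistaken for
    # leg), and skeleton/edge intersections falling inside it — the rounded
    # head and tail caps, where the body's medial axis also meets the
    # boundary — are removed from the positives so that positives come from
    # thin structures only.
    core = ndimage.binary_dilation(core, structure=_disk(3)) & m
    pos &= ~core
    pys, pxs = np.nonzero(pos)
    positives = [(fi, int(x), int(y)) for x, y in zip(pxs, pys)]
    cys, cxs = np.nonzero(core)
    band = (
        ndimage.binary_dilation(m, structure=_disk(bg_band[1]))
        & ~ndimage.binary_dilation(m, structure=_disk(bg_band[0]))
    )
    bys, bxs = np.nonzero(band)

    # balance the negative mix: as many body-core as near-background pixels
    n_core = len(cys)
    n_band = len(bys)
    target = min(n_core, n_band)
    if n_core > target:
        sel = rng.choice(n_core, size=target, replace=False)
        cys, cxs = cys[sel], cxs[sel]
    if n_band > target:
        sel = rng.choice(n_band, size=target, replace=False)
        bys, bxs = bys[sel], bxs[sel]
    negatives = [(fi, int(x), int(y)) for x, y in zip(cxs, cys)]
    negatives += [(fi, int(x), int(y)) for x, y in zip(bxs, bys)]
    return LabeledPixelPool(positives=positives, negatives=negatives)


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx * xx + yy * yy) <= r * r


def extract_patches(
    pool: LabeledPixelPool,
    stack: FrameStack,
    n_pos: int = 30_000,
    n_neg: int = 30_000,
    patch_size: int = 41,
    rng: np.random.Generator | None = None,
    round_index: int = 0,
) -> TrainingPatchSet:
    """Sample the pool and cut labelled patches from the raw grayscale frames.

    Sampling is uniform without replacement, falling back to sampling with
    replacement when a pool is smaller than the request. Patches are centred
    on the sampled pixel and zero-padded beyond image borders. Intensities
    are scaled to [0, 1]. Initial boosting state: weights 1, residuals equal
    to the labels.
    """
    rng = rng or np.random.default_rng(0)
    if not pool.positives or not pool.negatives:
        raise HarvestError("both pixel classes must be nonempty")

    half = patch_size // 2
    scale = 1.0 / float(np.iinfo(stack.frames.dtype).max) if np.issubdtype(
        stack.frames.dtype, np.integer
    ) else 1.0

    def _sample(entries: list[tuple[int, int, int]], k: int) -> np.ndarray:
        n = len(entries)
        idx = rng.choice(n, size=k, replace=n < k)
        return np.asarray(entries, dtype=np.int64)[idx]

    chosen_pos = _sample(pool.positives, n_pos)
    chosen_neg = _sample(pool.negatives, n_neg)
    chosen = np.concatenate([chosen_pos, chosen_neg])
    labels = np.concatenate(
        [np.ones(n_pos, dtype=np.int8), -np.ones(n_neg, dtype=np.int8)]
    )

    patches = np.zeros((len(chosen), patch_size, patch_size), dtype=np.float32)
    # group by frame so each frame is padded once
    order = np.argsort(chosen[:, 0], kind="stable")
    for fi in np.unique(chosen[:, 0]):
        rows = order[chosen[order, 0] == fi]
        padded = np.pad(
            stack.frames[fi].astype(np.float32) * scale,
            half,
            mode="constant",
        )
        for r in rows:
            _, x, y = chosen[r]
            patches[r] = padded[y : y + patch_size, x : x + patch_size]

    return TrainingPatchSet(
        patches=patches,
        labels=labels,
        weights=np.ones(len(chosen)),
        residuals=labels.astype(np.float64),
        round_index=round_index,
    )
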