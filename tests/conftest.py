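"""Shared fixtures: rendered walkers, ground-truth track sets, training sets."""

from __future__ import annotations

import numpy as np
import pytest

import clawtrack as ct
from clawtrack.claw_tracking import BodyPose, TrackSet
from clawtrack.kernel_boost import TrainingConfig
from clawtrack.training_harvest import TrainingPatchSet


def scaled_training_config(seed: int = 0, **overrides) -> TrainingConfig:
    """Training profile scaled down for the test suite's problem sizes."""
    base = dict(
        n_pos=2000,
        n_neg=2000,
        t1_size=1000,
        n_rounds=30,
        n_candidates=40,
        max_fit_samples=1000,
        self_train_rounds=1,
        seed=seed,
    )
    base.update(overrides)
    return TrainingConfig(**base)


@pytest.fixture(scope="session")
def walker_small():
    """A short, small-arena walker for cheap unit tests (no occlusions)."""
    params = ct.WalkerParams(
        image_size=384, fov_mm=7.5, n_frames=120, seed=7, noise_sd=1.0
    )
    return params, *ct.render_walker_video(params)


@pytest.fixture(scope="session")
def walker_gait():
    """Ground-truth walker used for gait-metric tests: 30-ms scripted swings."""
    params = ct.WalkerParams(n_frames=400, seed=9, swing_ms=30, noise_sd=0.0)
    stack, truth = ct.render_walker_video(params)
    return params, stack, truth


def truth_trackset(params: ct.WalkerParams, truth: ct.GroundTruth) -> tuple[TrackSet, list[BodyPose]]:
    """Build a TrackSet and pose list directly from renderer ground truth."""
    n = truth.centroid.shape[0]
    arena = truth.claws_arena.copy()
    body = truth.claws_body.copy()
    missing = truth.hidden.copy()
    arena[missing] = np.nan
    body[missing] = np.nan
    poses = [
        BodyPose(
            centroid=truth.centroid[i],
            theta=float(truth.theta[i]),
            axis=truth.axis[i],
            frame_index=i,
            length_px=params.body_length_px,
        )
        for i in range(n)
    ]
    tracks = TrackSet(
        legs=truth.legs,
        arena=arena,
        body=body,
        missing=missing,
        init_frame=0,
        gate_px=20.0,
    )
    return tracks, poses


def texture_patches(
    n_per_class: int = 150, rng: np.random.Generator | None = None
) -> TrainingPatchSet:
    """Two-class 41x41 texture set: dark line through the centre vs blob/flat.

    A miniature stand-in for harvested leg/body patches, cheap enough to
    boost for 100 rounds.
    """
    rng = rng or np.random.default_rng(0)
    p = 41
    yy, xx = np.mgrid[0:p, 0:p].astype(np.float64)
    patches = np.empty((2 * n_per_class, p, p), dtype=np.float32)
    for i in range(n_per_class):
        ang = rng.uniform(0, np.pi)
        d = np.abs((xx - 20) * np.sin(ang) - (yy - 20) * np.cos(ang))
        img = 0.8 - 0.55 * (d < 1.5)
        patches[i] = img + rng.normal(0, 0.03, (p, p))
    for i in range(n_per_class):
        if rng.random() < 0.5:
            img = np.full((p, p), 0.8)
        else:
            cy, cx = rng.uniform(12, 28, 2)
            r2 = (xx - cx) ** 2 + (yy - cy) ** 2
            img = 0.8 - 0.55 * (r2 < rng.uniform(8, 15) ** 2)
        patches[n_per_class + i] = img + rng.normal(0, 0.03, (p, p))
    labels = np.concatenate(
        [np.ones(n_per_class, dtype=np.int8), -np.ones(n_per_class, dtype=np.int8)]
    )
    return TrainingPatchSet(
        patches=patches,
        labels=labels,
        weights=np.ones(2 * n_per_class),
        residuals=labels.astype(np.float64),
    )
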