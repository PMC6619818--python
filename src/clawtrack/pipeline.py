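"""End-to-end orchestration: train -> segment -> track -> analyze.

The library modules are usable on their own; this module wires them into the
standard run (with config snapshotting, logging and resumability) used by the
command-line interface.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import claw_tracking, gait_metrics, imaging_io, kernel_boost, tremor_effectsize
from .claw_tracking import BodyPose, Correction, TipSet, TrackSet
from .imaging_io import BackgroundImage, FrameStack, SilhouetteMask
from .kernel_boost import BoostedClassifier, TrainingConfig
from .leg_segmentation import segment_legs
from .training_harvest import sample_training_frames

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "process_stack", "read_corrections"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; a JSON snapshot is stored with each run."""

    input_dir: str = ""
    output_dir: str = "clawtrack_out"
    frame_rate: float = 1000.0
    fov_mm: float = 10.0
    invert: bool = False  # reserved for bright-animal rigs; subtraction uses |diff|
    background_mode: str = "auto"
    background_path: str = ""
    threshold: float = 0.65  # classification confidence threshold
    min_component: int = 4
    n_legs: int = 6
    gate_px: float = claw_tracking.DEFAULT_GATE_PX
    v_on: float = 4.0
    v_off: float = 2.0
    seed: int = 0
    save_label_images: bool = False
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)


@dataclass
class PipelineResult:
    classifier: BoostedClassifier
    background: BackgroundImage
    masks: list[SilhouetteMask]
    poses: list[BodyPose]
    tipsets: list[TipSet]
    tracks: TrackSet
    report: gait_metrics.GaitReport
    pool_sizes: list[tuple[int, int]]


def _silhouettes(stack: FrameStack, bg: BackgroundImage, cfg: RunConfig) -> list[SilhouetteMask]:
    return [
        imaging_io.extract_silhouette(stack.frames[i], bg, "auto", frame_index=i)
        for i in range(len(stack))
    ]


def _poses(masks: Sequence[SilhouetteMask]) -> list[BodyPose]:
    # overall direction of travel disambiguates the anterior end
    cents = []
    for m in masks:
        ys, xs = np.nonzero(m.mask)
        cents.append(
            np.array([xs.mean(), ys.mean()]) if ys.size else np.array([np.nan, np.nan])
        )
    cents = np.stack(cents)
    fin = np.isfinite(cents[:, 0])
    motion = cents[fin][-1] - cents[fin][0] if fin.sum() >= 2 else None
    poses: list[BodyPose] = []
    prev = None
    for m in masks:
        if m.mask.any():
            p = claw_tracking.body_pose(m, prev=prev, motion_dir=motion)
        elif prev is not None:
            p = dataclasses.replace(prev, frame_index=m.frame_index)
        else:
            raise ValueError("first frame has an empty silhouette")
        poses.append(p)
        prev = p
    return poses


def process_stack(
    stack: FrameStack,
    cfg: RunConfig | None = None,
    background: np.ndarray | None = None,
    classifier: BoostedClassifier | None = None,
) -> PipelineResult:
    """Run the full in-memory pipeline on a frame stack."""
    cfg = cfg or RunConfig()
    bg = imaging_io.estimate_background(
        stack, cfg.background_mode, background=background
    )
    masks = _silhouettes(stack, bg, cfg)

    train_ids = sample_training_frames(stack, cfg.training.frame_stride)
    pool_sizes: list[tuple[int, int]] = []
    if classifier is None:
        train_masks = [masks[i] for i in train_ids]
        classifier, pool_sizes = kernel_boost.self_train(
            stack,
            train_masks,
            rounds=cfg.training.self_train_rounds,
            config=cfg.training,
            rng=np.random.default_rng(cfg.seed),
        )

    poses = _poses(masks)
    label_dir = None
    if cfg.save_label_images and cfg.output_dir:
        label_dir = Path(cfg.output_dir) / "labels"
        label_dir.mkdir(parents=True, exist_ok=True)
    tipsets: list[TipSet] = []
    for i in range(len(stack)):
        conf = kernel_boost.predict_confidence(classifier, stack.frames[i], masks[i])
        seg = segment_legs(conf, thr=cfg.threshold, min_size=cfg.min_component)
        if label_dir is not None:
            import imageio.v3 as iio

            iio.imwrite(
                label_dir / f"labels_{i:05d}.png",
                seg.labels.astype(np.uint8),
            )
        tipsets.append(claw_tracking.find_claw_candidates(seg, poses[i]))

    tracks = claw_tracking.track_claws(
        tipsets,
        poses,
        n_legs=cfg.n_legs,
        gate_px=cfg.gate_px * (512.0 / stack.shape[1]),
        image_width=stack.shape[1],
    )
    report = gait_metrics.compute_gait_report(
        tracks, poses, stack.frame_rate, stack.mm_per_px, v_on=cfg.v_on, v_off=cfg.v_off
    )
    return PipelineResult(
        classifier=classifier,
        background=bg,
        masks=masks,
        poses=poses,
        tipsets=tipsets,
        tracks=tracks,
        report=report,
        pool_sizes=pool_sizes,
    )


def _persist(result: PipelineResult, stack: FrameStack, cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(cfg.to_json())
    kernel_boost.save_classifier(result.classifier, outdir / "classifier.npz")
    imaging_io.write_track_tables(result.tracks, result.report, outdir)

    rows = []
    for ts in result.tipsets:
        for k in range(len(ts)):
            rows.append(
                {
                    "frame": ts.frame_index,
                    "component": int(ts.component_of[k]),
                    "x_arena_px": ts.tips_arena[k, 0],
                    "y_arena_px": ts.tips_arena[k, 1],
                    "x_body_px": ts.tips_body[k, 0],
                    "y_body_px": ts.tips_body[k, 1],
                }
            )
    pd.DataFrame(
        rows,
        columns=["frame", "component", "x_arena_px", "y_arena_px", "x_body_px", "y_body_px"],
    ).to_csv(outdir / "tips.csv", index=False)
    pd.DataFrame(
        {
            "frame": [p.frame_index for p in result.poses],
            "cx_px": [p.centroid[0] for p in result.poses],
            "cy_px": [p.centroid[1] for p in result.poses],
            "axis_x": [p.axis[0] for p in result.poses],
            "axis_y": [p.axis[1] for p in result.poses],
            "theta_deg": [p.theta for p in result.poses],
            "length_px": [p.length_px for p in result.poses],
        }
    ).to_csv(outdir / "poses.csv", index=False)

    # tremor analysis of every tracked leg
    write_tremor_tables(result.tracks, stack.frame_rate, outdir)


def write_tremor_tables(tracks: TrackSet, fps: float, outdir: Path) -> None:
    shake_rows, run_rows, all_tremors = [], [], []
    for j, leg in enumerate(tracks.legs):
        shakes = tremor_effectsize.detect_shake_events(
            tracks.body[:, j], fps=fps, leg=leg
        )
        tremors = tremor_effectsize.detect_tremor_events(shakes, fps=fps)
        all_tremors.extend(tremors)
        for s in shakes:
            shake_rows.append(
                {
                    "leg": leg,
                    "frame": s.frame,
                    "polarity": s.polarity,
                    "amplitude_px": s.amplitude_px,
                }
            )
        for t in tremors:
            run_rows.append(
                {
                    "leg": leg,
                    "start_frame": int(t.frames[0]),
                    "end_frame": int(t.frames[-1]),
                    "n_shakes": len(t.frames),
                }
            )
    pd.DataFrame(
        shake_rows, columns=["leg", "frame", "polarity", "amplitude_px"]
    ).to_csv(outdir / "shakes.csv", index=False)
    pd.DataFrame(
        run_rows, columns=["leg", "start_frame", "end_frame", "n_shakes"]
    ).to_csv(outdir / "tremor_events.csv", index=False)
    edges, counts, dom = tremor_effectsize.interval_spectrum(all_tremors, fps=fps)
    pd.DataFrame(
        {
            "bin_lo_ms": edges[:-1] if edges.size else [],
            "bin_hi_ms": edges[1:] if edges.size else [],
            "count": counts,
        }
    ).to_csv(outdir / "interval_histogram.csv", index=False)


def run_pipeline(cfg: RunConfig, stack: FrameStack | None = None) -> PipelineResult:
    """Execute the standard run and persist all artifacts to the output dir."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        filename=outdir / "run.log", level=logging.INFO, force=False
    )
    logger.info("run config: %s", cfg.to_json())

    if stack is None:
        stack = imaging_io.load_frame_stack(cfg.input_dir, cfg.frame_rate, cfg.fov_mm)
    background = None
    if cfg.background_mode == "loaded":
        import tifffile

        background = tifffile.imread(cfg.background_path)
    result = process_stack(stack, cfg, background=background)
    _persist(result, stack, cfg, outdir)
    return result


def read_corrections(path: str | Path) -> list[Correction]:
    """Corrections CSV: columns frame, leg, x, y — ``ABSENT`` in x marks a leg absent."""
    df = pd.read_csv(path, dtype={"x": str, "y": str})
    fixes = []
    for _, row in df.iterrows():
        if str(row["x"]).strip().upper() == "ABSENT":
            fixes.append(Correction(int(row["frame"]), str(row["leg"])))
        else:
            fixes.append(
                Correction(
                    int(row["frame"]), str(row["leg"]),
                    float(row["x"]), float(row["y"]),
                )
            )
    return fixes
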