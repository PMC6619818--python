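"""Frame-stack I/O, background estimation, silhouette extraction, output tables.

The recordings this package targets are backlit top-view videos of a walking
arthropod: a dark body-and-leg silhouette on a bright, static background.
Foreground extraction is plain background subtraction,

    silhouette = |image(x, y) - background| > threshold,

followed by connected-component cleanup so that exactly one animal (plus any
components within a small radius of it, e.g. legs that pinch off at the
threshold) survives.

Coordinate convention used throughout the package: 0-based pixel coordinates,
origin at the top-left corner, ``x`` = column index, ``y`` = row index. All
output CSVs use this convention and say so in their headers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "FrameStack",
    "BackgroundImage",
    "SilhouetteMask",
    "load_frame_stack",
    "estimate_background",
    "extract_silhouette",
    "write_track_tables",
    "read_table",
    "LEG_LABELS_6",
    "LEG_LABELS_8",
]

LEG_LABELS_6 = ("L1", "L2", "L3", "R1", "R2", "R3")
LEG_LABELS_8 = ("L1", "L2", "L3", "L4", "R1", "R2", "R3", "R4")

#: image suffixes accepted by :func:`load_frame_stack`
_FRAME_SUFFIXES = (".tif", ".tiff", ".png")


class NoInputError(ValueError):
    """Raised when an input directory holds no usable frames."""


class FormatError(ValueError):
    """Raised when frames disagree in shape or cannot be read as grayscale."""


@dataclass
class FrameStack:
    """An ordered grayscale image sequence plus acquisition metadata."""

    frames: np.ndarray  # (n_frames, H, W), uint8 or uint16
    frame_rate: float  # frames per second
    mm_per_px: float  # millimetres per pixel
    source_dir: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError("frames must form a (n, H, W) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class BackgroundImage:
    image: np.ndarray
    mode: str  # one of {"auto", "spliced", "loaded"}
    stationary_warning: bool = False


@dataclass
class SilhouetteMask:
    mask: np.ndarray  # 2-D bool, True = animal foreground
    frame_index: int = -1


def load_frame_stack(
    directory: str | Path, frame_rate: float, fov_mm: float
) -> FrameStack:
    """Read a directory of same-shaped grayscale frames, sorted by filename.

    ``mm_per_px`` is derived as ``fov_mm / image_width``; tracking requires at
    least two frames.
    """
    import tifffile
    import imageio.v3 as iio

    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
    )
    if not paths:
        raise NoInputError(f"no frames found in {directory}")
    if len(paths) < 2:
        raise NoInputError("tracking needs at least 2 frames")

    frames = []
    shape = None
    for p in paths:
        if p.suffix.lower() in (".tif", ".tiff"):
            img = tifffile.imread(p)
        else:
            img = iio.imread(p)
        img = np.asarray(img)
        if img.ndim == 3:  # collapse an RGB frame that is really grayscale
            img = img[..., 0]
        if img.ndim != 2:
            raise FormatError(f"{p.name}: not a 2-D grayscale image")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise FormatError(
                f"{p.name}: shape {img.shape} differs from {shape}"
            )
        frames.append(img)

    stack = np.stack(frames)
    return FrameStack(
        frames=stack,
        frame_rate=frame_rate,
        mm_per_px=fov_mm / stack.shape[2],
        source_dir=str(directory),
    )


def _rough_animal_mask(frame: np.ndarray) -> np.ndarray:
    """Largest dark blob of a single frame (used only for splicing/motion checks)."""
    f = frame.astype(np.float64)
    thr = threshold_otsu(f)
    mask = f < thr
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _mask_centroid(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return np.array([xs.mean(), ys.mean()])


def estimate_background(
    stack: FrameStack,
    mode: str = "auto",
    background: np.ndarray | None = None,
    sample_stride: int = 20,
) -> BackgroundImage:
    """Estimate the static background of a stack.

    auto
        Per-pixel median over every ``sample_stride``-th frame (a robust
        bright estimate; the moving animal occupies any given pixel in only a
        minority of samples).
    spliced
        First and last frames mosaicked along the perpendicular bisector of
        the two animal centroids, so neither half contains the animal. Meant
        for short clips where the animal moved far between the ends.
    loaded
        A user-supplied background image, passed through unchanged.

    In ``auto``/``spliced`` modes the animal should displace at least 1.5
    body lengths over the stack; otherwise the result carries a
    ``stationary_warning`` flag (the median will retain grey traces of the
    animal).
    """
    if mode == "loaded":
        if background is None:
            raise ValueError("loaded mode requires a background image")
        bg = np.asarray(background)
        if bg.shape != stack.shape:
            raise FormatError("background shape differs from frames")
        return BackgroundImage(image=bg, mode="loaded")

    first = stack.frames[0]
    last = stack.frames[-1]
    m0 = _rough_animal_mask(first)
    m1 = _rough_animal_mask(last)
    c0 = _mask_centroid(m0)
    c1 = _mask_centroid(m1)
    # body length proxy: max extent of the first-frame blob
    ys, xs = np.nonzero(m0)
    body_len = max(np.ptp(ys), np.ptp(xs)) if ys.size else 1.0
    displacement = float(np.hypot(*(c1 - c0)))
    stationary = displacement < 1.5 * body_len

    if mode == "auto":
        samples = stack.frames[::sample_stride]
        if samples.shape[0] < 3:
            samples = stack.frames
        bg = np.median(samples.astype(np.float64), axis=0)
        if stationary:
            warnings.warn(
                "animal displaced < 1.5 body lengths; auto background may "
                "retain silhouette traces",
                stacklevel=2,
            )
        return BackgroundImage(
            image=bg, mode="auto", stationary_warning=stationary
        )

    if mode == "spliced":
        d = c1 - c0
        if np.allclose(d, 0):
            raise ValueError("spliced mode needs the animal to move between ends")
        h, w = stack.shape
        xx, yy = np.meshgrid(np.arange(w), np.arange(h))
        mid = (c0 + c1) / 2.0
        # pixels on the c0 side of the bisector held the animal in the first
        # frame, so they are taken from the last frame, and vice versa.
        side0 = (xx - mid[0]) * d[0] + (yy - mid[1]) * d[1] < 0
        bg = np.where(side0, last, first).astype(np.float64)
        return BackgroundImage(
            image=bg, mode="spliced", stationary_warning=stationary
        )

    raise ValueError(f"unknown background mode: {mode}")


def extract_silhouette(
    frame: np.ndarray,
    bg: BackgroundImage,
    thr: float | str = "auto",
    dust_radius: int = 5,
    frame_index: int = -1,
) -> SilhouetteMask:
    """Binary foreground via |frame - background| > threshold.

    ``thr="auto"`` picks the Otsu threshold of the absolute difference image.
    After thresholding, the largest connected component is kept, together
    with any component lying within ``dust_radius`` pixels of it; isolated
    specks (dust, compression artifacts) are suppressed.
    """
    f = np.asarray(frame, dtype=np.float64)
    if f.shape != bg.image.shape:
        raise FormatError("frame and background shapes differ")
    diff = np.abs(f - bg.image)
    if thr == "auto":
        thr_val = float(threshold_otsu(diff))
    else:
        thr_val = float(thr)
    mask = diff > thr_val

    if not mask.any():
        warnings.warn("empty silhouette mask", stacklevel=2)
        return SilhouetteMask(mask=mask, frame_index=frame_index)

    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n > 1:
        sizes = ndimage.sum_labels(
            np.ones_like(lab), lab, index=np.arange(1, n + 1)
        )
        main = 1 + int(np.argmax(sizes))
        near = ndimage.binary_dilation(
            lab == main, structure=_disk(dust_radius)
        )
        keep_ids = np.unique(lab[near & (lab > 0)])
        mask = np.isin(lab, keep_ids)
    return SilhouetteMask(mask=mask, frame_index=frame_index)


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx * xx + yy * yy) <= r * r


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

#: the nine CSV files produced by a full run
TABLE_FILES = (
    "CoM.csv",
    "trajectory.csv",
    "norm_trajectory.csv",
    "bodylength.csv",
    "bodyvelocity.csv",
    "StrideParameters.csv",
    "LegParameters.csv",
    "LegDomainOverlap.csv",
    "StanceWidth.csv",
)


def write_track_tables(tracks, report, outdir: str | Path) -> list[Path]:
    """Write the full set of output CSVs for a finished run.

    ``tracks`` is a :class:`~clawtrack.claw_tracking.TrackSet`; ``report`` is a
    :class:`~clawtrack.gait_metrics.GaitReport`. Missing claw positions are
    written as empty cells. Columns use 0-based pixel coordinates (origin
    top-left, x = column, y = row) unless a unit suffix says otherwise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    n = tracks.n_frames
    legs = list(tracks.legs)

    com = pd.DataFrame(
        {
            "frame": np.arange(n),
            "x_px": [p.centroid[0] for p in report.poses],
            "y_px": [p.centroid[1] for p in report.poses],
            "theta_deg": [p.theta for p in report.poses],
        }
    )
    written.append(_write(com, outdir / "CoM.csv"))

    for name, coords in (
        ("trajectory.csv", tracks.arena),
        ("norm_trajectory.csv", tracks.body),
    ):
        cols: dict[str, np.ndarray] = {"frame": np.arange(n)}
        for j, leg in enumerate(legs):
            cols[f"{leg}_x_px"] = coords[:, j, 0]
            cols[f"{leg}_y_px"] = coords[:, j, 1]
        written.append(_write(pd.DataFrame(cols), outdir / name))

    written.append(
        _write(
            pd.DataFrame(
                {
                    "frame": np.arange(n),
                    "body_length_mm": report.body_length_series_mm,
                }
            ),
            outdir / "bodylength.csv",
        )
    )
    written.append(
        _write(
            pd.DataFrame(
                {
                    "frame": np.arange(n),
                    "velocity_mm_per_s": report.body_velocity_mm_s,
                }
            ),
            outdir / "bodyvelocity.csv",
        )
    )

    written.append(_write(report.stride_table, outdir / "StrideParameters.csv"))
    written.append(_write(report.leg_table, outdir / "LegParameters.csv"))
    written.append(_write(report.domain_overlap, outdir / "LegDomainOverlap.csv"))
    written.append(_write(report.stance_width_table, outdir / "StanceWidth.csv"))
    return written


def _write(df: pd.DataFrame, path: Path) -> Path:
    # 17 significant digits: float64 values survive the CSV round trip exactly
    df.to_csv(path, index=False, na_rep="", float_format=lambda x: format(x, ".17g"))
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Inverse of the CSV writers (empty cells come back as NaN)."""
    return pd.read_csv(path, float_precision="round_trip")
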