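"""Velocity-encoded scanpath rendering.

A gaze recording is turned into grayscale images in three steps: (1) a
straight stroke is drawn for every transition between consecutive valid
samples, (2) the stroke's gray level encodes the instantaneous gaze speed,
and (3) the raster is vertically mirrored because the tracker reports the
point of gaze with a bottom-left origin while rasters grow downward.

Long recordings are split into segments of at most ``max_points``
consecutive valid samples (default 200) so that every image carries a
comparable amount of scanpath; per-transition speeds are clipped at a
displacement bound of a quarter of the screen diagonal, beyond which a
single-transition movement is not physiological.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.draw import line as _bresenham_line

from .errors import DataError
from .io import DEFAULT_SCREEN, GazeRecording

#: Default raster dimensions (width, height) of a rendered scanpath image.
DEFAULT_DIMS = (640, 480)

#: Default gray floor: the darkest stroke intensity, so that even the
#: fastest strokes stay visible on the black background.
DEFAULT_G_MIN = 0.1

#: Default segmentation thresholds (samples per image).
DEFAULT_MAX_POINTS = 200
DEFAULT_MIN_POINTS = 20

#: Divisor of the screen diagonal defining the displacement clip bound.
CLIP_DIVISOR = 4.0


def clip_bound_px(screen: tuple[int, int], divisor: float = CLIP_DIVISOR) -> float:
    """Displacement cap per transition: screen diagonal / ``divisor`` pixels."""
    w, h = screen
    if w <= 0 or h <= 0:
        raise DataError("screen dimensions must be positive")
    return math.hypot(w, h) / divisor


@dataclass
class VelocityTrace:
    """Per-transition gaze speeds in px/ms.

    ``speeds`` holds one entry per consecutive valid sample pair;
    transitions that span an invalid sample are omitted.  ``dts`` carries
    the matching time steps in ms so that displacement (= speed * dt) can
    be clipped with dt unchanged.  ``clip_bound`` records the displacement
    cap once :func:`clip_dynamics` has been applied.
    """

    speeds: np.ndarray
    dts: np.ndarray
    clip_bound: float | None = None

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        self.dts = np.asarray(self.dts, dtype=float)
        if self.speeds.shape != self.dts.shape:
            raise DataError("speeds and dts must align")
        if np.any(self.speeds < 0):
            raise DataError("speeds must be non-negative")

    def __len__(self) -> int:
        return len(self.speeds)


@dataclass
class ScanpathSegment:
    """A run of at most ``max_points`` consecutive valid samples.

    ``src_index`` keeps each sample's row in the source recording, so a
    transition whose samples were not adjacent in the raw stream (an
    invalid sample was skipped in between) is recognised as a gap: no
    stroke is drawn across it and it contributes no speed.
    """

    participant_id: str
    stimulus_id: str
    segment_index: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    src_index: np.ndarray
    screen: tuple[int, int] = DEFAULT_SCREEN
    sampling_rate: float = 250.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.src_index = np.asarray(self.src_index, dtype=int)
        if len(self.t) < 2:
            raise DataError("a scanpath segment needs at least 2 samples")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def nominal_dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def contiguous(self) -> np.ndarray:
        """Boolean mask over transitions: True where samples were raw-adjacent."""
        return np.diff(self.src_index) == 1

    def transition_speeds(self) -> np.ndarray:
        """Speed per transition in px/ms; NaN across track-loss gaps."""
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise DataError("non-positive time step inside a segment")
        dist = np.hypot(np.diff(self.x), np.diff(self.y))
        speeds = dist / dt
        speeds[~self.contiguous] = np.nan
        return speeds

    def velocity_trace(self) -> VelocityTrace:
        """Trace over the segment's gap-free transitions only."""
        keep = self.contiguous
        dt = np.diff(self.t)[keep]
        speeds = self.transition_speeds()[keep]
        return VelocityTrace(speeds=speeds, dts=dt)


@dataclass
class ScanpathImage:
    """Grayscale raster of one scanpath segment, strokes on black.

    ``pixels`` is a float array of shape (H, W) with values in [0, 1];
    background pixels are exactly 0.
    """

    pixels: np.ndarray
    participant_id: str
    stimulus_id: str
    segment_index: int
    label: str | None = None
    augmented_from: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise DataError("scanpath images are single-channel 2-D rasters")

    @property
    def dims(self) -> tuple[int, int]:
        """(width, height)."""
        h, w = self.pixels.shape
        return (w, h)

    @property
    def name(self) -> str:
        base = f"{self.participant_id}_{self.stimulus_id}_{self.segment_index}"
        if self.augmented_from is not None:
            base += f"_aug{self.augmented_from}"
        return base

    def save(self, path: str | Path) -> Path:
        """Write as an 8-bit single-channel PNG."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arr = np.clip(np.rint(self.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path)
        return path

    @classmethod
    def load(cls, path: str | Path, **meta) -> "ScanpathImage":
        path = Path(path)
        arr = np.asarray(Image.open(path).convert("L"), dtype=np.float32) / 255.0
        stem = path.stem
        parts = stem.split("_")
        defaults = dict(participant_id=stem, stimulus_id="", segment_index=0)
        if len(parts) >= 3 and parts[-1].isdigit():
            defaults = dict(
                participant_id="_".join(parts[:-2]),
                stimulus_id=parts[-2],
                segment_index=int(parts[-1]),
            )
        defaults.update(meta)
        return cls(pixels=arr, **defaults)


def compute_velocity(recording: GazeRecording) -> VelocityTrace:
    """Speed of gaze movement for each consecutive valid sample pair.

    Speed is the Euclidean POG displacement in pixels divided by the time
    step in ms.  Transitions that span an invalid sample are omitted, so a
    blink never masquerades as a fast movement.
    """
    valid_idx = np.nonzero(recording.valid)[0]
    if valid_idx.size < 2:
        raise DataError("need at least 2 valid samples to compute velocity")
    adjacent = np.diff(valid_idx) == 1
    i = valid_idx[:-1][adjacent]
    dt = recording.t[i + 1] - recording.t[i]
    if np.any(dt <= 0):
        raise DataError("non-positive time step between consecutive samples")
    dist = np.hypot(
        recording.x[i + 1] - recording.x[i], recording.y[i + 1] - recording.y[i]
    )
    return VelocityTrace(speeds=dist / dt, dts=dt)


def clip_dynamics(
    trace: VelocityTrace,
    screen: tuple[int, int],
    divisor: float = CLIP_DIVISOR,
) -> VelocityTrace:
    """Cap each transition's implied displacement at a quarter of the
    screen diagonal.

    A transition whose displacement (speed * dt) exceeds the bound has its
    speed rescaled as if the displacement were exactly the bound, with dt
    unchanged; slower transitions pass through untouched.  Idempotent.
    """
    bound = clip_bound_px(screen, divisor)
    with np.errstate(invalid="ignore"):
        displacement = trace.speeds * trace.dts
        speeds = np.where(
            displacement > bound, bound / trace.dts, trace.speeds
        )
    return VelocityTrace(speeds=speeds, dts=trace.dts.copy(), clip_bound=bound)


def segment_scanpath(
    recording: GazeRecording,
    max_points: int = DEFAULT_MAX_POINTS,
    min_points: int = DEFAULT_MIN_POINTS,
) -> list[ScanpathSegment]:
    """Partition a recording's valid samples into runs of ``max_points``.

    Consecutive, non-overlapping chunks; a trailing run shorter than
    ``min_points`` is dropped.  Segment indices are contiguous from 0.  A
    recording with too few valid samples yields an empty list.
    """
    if max_points < 2:
        raise DataError("max_points must be at least 2")
    valid_idx = np.nonzero(recording.valid)[0]
    segments: list[ScanpathSegment] = []
    for start in range(0, valid_idx.size, max_points):
        chunk = valid_idx[start : start + max_points]
        if chunk.size < max(2, min_points):
            continue
        segments.append(
            ScanpathSegment(
                participant_id=recording.participant_id,
                stimulus_id=recording.stimulus_id,
                segment_index=len(segments),
                t=recording.t[chunk],
                x=recording.x[chunk],
                y=recording.y[chunk],
                src_index=chunk,
                screen=recording.screen,
                sampling_rate=recording.sampling_rate,
            )
        )
    return segments


def speed_to_gray(
    speed,
    clip_bound: float,
    nominal_dt: float,
    g_min: float = DEFAULT_G_MIN,
    invert: bool = False,
):
    """Map a speed in px/ms to a stroke intensity in [g_min, 1].

    The speed is normalised by the largest speed the clip bound allows at
    the nominal sampling interval (``clip_bound / nominal_dt``), then
    mapped linearly: slow movement renders bright (1.0), movement at or
    beyond the bound renders at the dark floor ``g_min``, so every stroke
    stays visible on the black background.  ``invert=True`` flips the
    orientation (slow dark, fast bright).  Monotone in speed either way.
    Accepts scalars or arrays.
    """
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise DataError("speed must be non-negative")
    if clip_bound <= 0 or nominal_dt <= 0:
        raise DataError("clip_bound and nominal_dt must be positive")
    s = np.minimum(speed / (clip_bound / nominal_dt), 1.0)
    intensity = g_min + (1.0 - g_min) * s if invert else 1.0 - (1.0 - g_min) * s
    return float(intensity) if intensity.ndim == 0 else intensity


def render_segment(
    segment: ScanpathSegment,
    dims: tuple[int, int] = DEFAULT_DIMS,
    screen: tuple[int, int] | None = None,
    g_min: float = DEFAULT_G_MIN,
    invert_gray: bool = False,
    clip_divisor: float = CLIP_DIVISOR,
    label: str | None = None,
) -> ScanpathImage:
    """Rasterise one segment into a velocity-encoded grayscale image.

    One straight 1-px stroke per gap-free transition, drawn with an
    integer (Bresenham) line algorithm, no anti-aliasing; where strokes
    overlap the maximum intensity wins, so rendering is deterministic and
    bit-identical across runs.  Data space has its origin at the
    bottom-left of the screen, rasters at the top-left, so the y axis is
    mirrored here -- and only here.
    """
    if len(segment) < 2:
        raise DataError("render_segment needs a segment of >= 2 samples")
    screen = screen or segment.screen
    w, h = dims
    if w <= 0 or h <= 0:
        raise DataError("raster dimensions must be positive")
    bound = clip_bound_px(screen, clip_divisor)
    speeds = segment.transition_speeds()
    dt = np.diff(segment.t)
    with np.errstate(invalid="ignore"):
        displacement = speeds * dt
        speeds = np.where(displacement > bound, bound / dt, speeds)

    # screen -> raster scale, then vertical mirror (bottom of screen ->
    # bottom rows of the raster).
    sx, sy = screen
    col = np.clip(np.rint(segment.x / sx * (w - 1)), 0, w - 1).astype(int)
    row_up = np.clip(np.rint(segment.y / sy * (h - 1)), 0, h - 1).astype(int)
    row = (h - 1) - row_up

    pixels = np.zeros((h, w), dtype=np.float32)
    contiguous = segment.contiguous
    for k in range(len(segment) - 1):
        if not contiguous[k]:
            continue
        rr, cc = _bresenham_line(row[k], col[k], row[k + 1], col[k + 1])
        g = speed_to_gray(
            float(speeds[k]), bound, segment.nominal_dt_ms, g_min, invert_gray
        )
        np.maximum.at(pixels, (rr, cc), np.float32(g))
    return ScanpathImage(
        pixels=pixels,
        participant_id=segment.participant_id,
        stimulus_id=segment.stimulus_id,
        segment_index=segment.segment_index,
        label=label,
    )


def render_recording(
    recording: GazeRecording,
    dims: tuple[int, int] = DEFAULT_DIMS,
    max_points: int = DEFAULT_MAX_POINTS,
    min_points: int = DEFAULT_MIN_POINTS,
    g_min: float = DEFAULT_G_MIN,
    invert_gray: bool = False,
    clip_divisor: float = CLIP_DIVISOR,
    label: str | None = None,
) -> tuple[list[ScanpathSegment], list[ScanpathImage]]:
    """Segment a recording and render every segment."""
    segments = segment_scanpath(recording, max_points, min_points)
    images = [
        render_segment(
            s, dims=dims, g_min=g_min, invert_gray=invert_gray,
            clip_divisor=clip_divisor, label=label,
        )
        for s in segments
    ]
    return segments, images


def save_images(images: Sequence[ScanpathImage], outdir: str | Path) -> list[Path]:
    """Write images as ``{participant}_{stimulus}_{segment}.png`` under ``outdir``."""
    outdir = Path(outdir)
    return [img.save(outdir / f"{img.name}.png") for img in images]
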