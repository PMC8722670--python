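"""Cropping, resizing and augmentation of scanpath images.

The rendered rasters are mostly black; cropping the background to the
tight bounding box of the strokes and rescaling everything to one fixed
size (default 256 x 256) removes uninformative pixels before training.
Augmentation produces label-preserving affine jitters (small rotation,
shift and zoom) of each image.  Photometric transforms are deliberately
excluded: the gray level encodes velocity, and changing it would corrupt
the signal.  Horizontal flips are excluded too, since gaze laterality may
itself be diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from skimage.transform import AffineTransform, resize as _sk_resize, warp

from .errors import ConfigError
from .render import ScanpathImage

DEFAULT_TARGET_DIMS = (256, 256)
DEFAULT_CROP_MARGIN = 2
DEFAULT_AUGMENT_PER_IMAGE = 5

#: Augmentation jitter ranges: rotation in degrees, shift as a fraction of
#: the image side, zoom as a fractional scale change.
DEFAULT_ROTATION_DEG = 10.0
DEFAULT_SHIFT_FRACTION = 0.05
DEFAULT_ZOOM_FRACTION = 0.10


@dataclass
class PreprocessConfig:
    """Parameters of the crop -> resize -> augment stage."""

    target_dims: tuple[int, int] = DEFAULT_TARGET_DIMS
    crop_margin: int = DEFAULT_CROP_MARGIN
    augment_per_image: int = DEFAULT_AUGMENT_PER_IMAGE
    rotation_deg: float = DEFAULT_ROTATION_DEG
    shift_fraction: float = DEFAULT_SHIFT_FRACTION
    zoom_fraction: float = DEFAULT_ZOOM_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.augment_per_image < 0:
            raise ConfigError("augment_per_image must be >= 0")
        if self.target_dims[0] <= 0 or self.target_dims[1] <= 0:
            raise ConfigError("target dims must be positive")


def crop_background(
    image: ScanpathImage, margin: int = DEFAULT_CROP_MARGIN
) -> ScanpathImage:
    """Crop the black background to the strokes' bounding box plus a margin.

    The box is clamped to the image bounds.  An all-black image (a
    degenerate segment that drew nothing) is returned unchanged with an
    ``"all_black"`` flag so cohort bookkeeping can drop or keep it
    explicitly.
    """
    px = image.pixels
    rows = np.nonzero(px.max(axis=1) > 0)[0]
    cols = np.nonzero(px.max(axis=0) > 0)[0]
    if rows.size == 0:
        out = replace(image, pixels=px.copy())
        out.flags = list(image.flags) + ["all_black"]
        return out
    r0 = max(int(rows[0]) - margin, 0)
    r1 = min(int(rows[-1]) + margin + 1, px.shape[0])
    c0 = max(int(cols[0]) - margin, 0)
    c1 = min(int(cols[-1]) + margin + 1, px.shape[1])
    out = replace(image, pixels=px[r0:r1, c0:c1].copy())
    out.flags = list(image.flags)
    return out


def resize_image(
    image: ScanpathImage, dims: tuple[int, int] = DEFAULT_TARGET_DIMS
) -> ScanpathImage:
    """Rescale to exactly ``dims`` (width, height), bilinear, aspect ratio
    not preserved.

    The same target is applied uniformly after variable crops, so shapes
    stretch; an input already at the target passes through bit-identical.
    Downscaling applies a Gaussian anti-aliasing prefilter: the strokes
    are one pixel wide, and plain bilinear subsampling would skip most of
    them instead of averaging them into the output -- the prefilter turns
    stroke intensity times local density into the downscaled gray level,
    preserving the velocity encoding.
    """
    w, h = dims
    if image.pixels.shape == (h, w):
        out = replace(image, pixels=image.pixels.copy())
        out.flags = list(image.flags)
        return out
    downscaling = h < image.pixels.shape[0] or w < image.pixels.shape[1]
    resized = _sk_resize(
        image.pixels.astype(np.float64), (h, w), order=1,
        anti_aliasing=downscaling, preserve_range=True,
    ).astype(np.float32)
    out = replace(image, pixels=np.clip(resized, 0.0, 1.0))
    out.flags = list(image.flags)
    return out


def _affine_jitter(
    pixels: np.ndarray,
    rotation_deg: float,
    shift_xy: tuple[float, float],
    zoom: float,
) -> np.ndarray:
    """Rotate/zoom about the image centre, then shift; bilinear, black fill."""
    h, w = pixels.shape
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t_centre = AffineTransform(translation=-centre)
    t_jitter = AffineTransform(rotation=np.deg2rad(rotation_deg), scale=(zoom, zoom))
    t_back = AffineTransform(translation=centre + np.asarray(shift_xy))
    tform = t_centre + t_jitter + t_back
    out = warp(
        pixels.astype(np.float64), tform.inverse, order=1, mode="constant",
        cval=0.0, preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def augment_dataset(
    images: Sequence[ScanpathImage],
    n_per_image: int = DEFAULT_AUGMENT_PER_IMAGE,
    seed: int = 0,
    rotation_deg: float = DEFAULT_ROTATION_DEG,
    shift_fraction: float = DEFAULT_SHIFT_FRACTION,
    zoom_fraction: float = DEFAULT_ZOOM_FRACTION,
) -> list[ScanpathImage]:
    """Generate ``n_per_image`` affine-jittered variants of every image.

    Returns exactly ``n_per_image * len(images)`` new images (the originals
    are kept separately by the caller).  Each variant draws an independent
    rotation within +/-``rotation_deg``, shift within +/-``shift_fraction``
    of the side length per axis, and zoom within +/-``zoom_fraction``, all
    from a generator seeded with ``seed`` -- the output is fully
    reproducible.  Variants inherit the source's participant, stimulus and
    label, and record the source in ``augmented_from`` so participant-wise
    splits can keep variants with their participant.
    """
    if n_per_image < 0:
        raise ConfigError("n_per_image must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[ScanpathImage] = []
    for img in images:
        h, w = img.pixels.shape
        for k in range(n_per_image):
            rot = rng.uniform(-rotation_deg, rotation_deg)
            shift = (
                rng.uniform(-shift_fraction, shift_fraction) * w,
                rng.uniform(-shift_fraction, shift_fraction) * h,
            )
            zoom = 1.0 + rng.uniform(-zoom_fraction, zoom_fraction)
            variant = replace(
                img, pixels=_affine_jitter(img.pixels, rot, shift, zoom)
            )
            variant.flags = list(img.flags)
            variant.augmented_from = f"{img.name}:{k}"
            out.append(variant)
    return out


def preprocess_images(
    images: Sequence[ScanpathImage], config: PreprocessConfig | None = None
) -> tuple[list[ScanpathImage], list[ScanpathImage]]:
    """Crop + resize every image, then augment.

    Returns ``(processed, augmented)``: the originals at target dims and
    the ``augment_per_image`` variants of each.  All-black inputs are
    flagged (not dropped) so counts stay conserved.
    """
    config = config or PreprocessConfig()
    processed = [
        resize_image(crop_background(img, config.crop_margin), config.target_dims)
        for img in images
    ]
    augmented = augment_dataset(
        processed,
        n_per_image=config.augment_per_image,
        seed=config.seed,
        rotation_deg=config.rotation_deg,
        shift_fraction=config.shift_fraction,
        zoom_fraction=config.zoom_fraction,
    )
    return processed, augmented
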