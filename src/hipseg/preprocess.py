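"""Slice preprocessing: Hounsfield windowing, resizing, and the mid-split/mirror
augmentation used by every network in the pipeline.

Two windows feed the system.  The bone-highlight window (level 40 HU, width
200 HU) goes to the bone/soft-tissue separator and the slice classifier; the
femur window (level 500 HU, width 1000 HU) suppresses soft tissue and feeds
the main femur segmenter.  A window maps ``[level - width/2, level + width/2]``
linearly onto [0, 1], clamping outside.

The augmentation cuts a slice down the middle and mirrors the right half so it
looks like a left hip, doubling the dataset; at test time the two
half-predictions are un-mirrored and concatenated back into a full slice.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.transform import resize as _sk_resize

BONE_WINDOW_LEVEL, BONE_WINDOW_WIDTH = 40.0, 200.0
FEMUR_WINDOW_LEVEL, FEMUR_WINDOW_WIDTH = 500.0, 1000.0
BONE_THRESHOLD_HU = 200.0


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """A Hounsfield level/width pair defining an intensity normalisation."""

    level: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"window width must be positive, got {self.width}")

    @property
    def low(self):
        return self.level - self.width / 2.0

    @property
    def high(self):
        return self.level + self.width / 2.0


BONE_WINDOW = WindowSpec(BONE_WINDOW_LEVEL, BONE_WINDOW_WIDTH)
FEMUR_WINDOW = WindowSpec(FEMUR_WINDOW_LEVEL, FEMUR_WINDOW_WIDTH)


@dataclasses.dataclass
class SlicePair:
    """One axial training sample: a normalised image, its labels, and the
    femur-presence flag targeted by the slice classifier."""

    image: np.ndarray
    labels: np.ndarray
    has_femur: bool

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ValueError(
                f"image {self.image.shape} and labels {self.labels.shape} differ"
            )


def apply_window(hu_slice, window: WindowSpec) -> np.ndarray:
    """Normalise an HU array into [0, 1] through a level/width window.

    Monotone nondecreasing in HU; values at or below ``level - width/2`` map
    to 0, at or above ``level + width/2`` to 1.
    """
    hu = np.asarray(hu_slice, dtype=np.float32)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU values must be finite")
    return np.clip((hu - window.low) / window.width, 0.0, 1.0).astype(np.float32)


def resize_slice(image, target, is_label=False) -> np.ndarray:
    """Resize a 2D slice: bilinear for images, nearest-neighbour for labels.

    Nearest-neighbour guarantees the label value set is preserved; bilinear
    keeps image values inside the input's [min, max].
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("input must be a nonempty 2D array")
    rows, cols = target
    if rows < 1 or cols < 1:
        raise ValueError(f"target dims must be >= 1, got {target}")
    if image.shape == (rows, cols):
        return image.copy()
    if is_label:
        out = _sk_resize(image, (rows, cols), order=0, preserve_range=True,
                         anti_aliasing=False)
        return np.rint(out).astype(image.dtype)
    out = _sk_resize(image.astype(np.float32), (rows, cols), order=1,
                     preserve_range=True, anti_aliasing=False)
    return np.clip(out, image.min(), image.max()).astype(np.float32)


def split_and_flip(image) -> tuple:
    """Cut a slice down the middle; mirror the right half left-right.

    Returns ``(left_half, mirrored_right_half)``, each rows x (cols/2).  Apply
    identically to label slices.  Requires an even column count.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("input must be 2D")
    cols = image.shape[1]
    if cols % 2:
        raise ValueError(f"column count must be even, got {cols}")
    half = cols // 2
    left = image[:, :half].copy()
    right_mirrored = image[:, half:][:, ::-1].copy()
    return left, right_mirrored


def unsplit(left, right_mirrored) -> np.ndarray:
    """Inverse of :func:`split_and_flip`: un-mirror the right half and
    concatenate the halves back into a full-width slice."""
    left = np.asarray(left)
    right_mirrored = np.asarray(right_mirrored)
    if left.shape != right_mirrored.shape:
        raise ValueError("halves must share a shape")
    return np.concatenate([left, right_mirrored[:, ::-1]], axis=1)


def bone_threshold_mask(hu_slice, threshold=BONE_THRESHOLD_HU) -> np.ndarray:
    """Binary bone mask: HU >= 200 (inclusive)."""
    hu = np.asarray(hu_slice)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU values must be finite")
    return (hu >= threshold).astype(np.uint8)
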