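"""Run the assembled pipeline over a CT volume, slice by slice.

Per axial slice: the bone window (level 40, width 200) feeds the upward net,
which predicts the bone map that is fused into the main femur net alongside
the femur-windowed (level 500, width 1000) image; the slice classifier scores
the bone-windowed input and its confidence multiplies the femur probability
map before thresholding, so slices unlikely to contain femur are suppressed.
Each slice is processed as two mirrored halves (the same augmentation used in
training); the half-predictions are un-mirrored, concatenated, resized back to
the scan grid, thresholded, and re-stacked in the original slice order.
Output classes: femur = 1, other bone (predicted bone minus femur) = 2.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from . import engine as eg
from .ct_io import CtVolume, LabelVolume, LABEL_FEMUR, LABEL_OTHER_BONE
from .preprocess import (
    BONE_WINDOW,
    FEMUR_WINDOW,
    apply_window,
    resize_slice,
    split_and_flip,
    unsplit,
)
from .training import Pipeline

_CHUNK = 64  # half-slices per forward pass, to bound peak memory


@dataclasses.dataclass
class SegmentationResult:
    """Per-slice femur probabilities and confidences plus the assembled volume."""

    per_slice_probs: list
    per_slice_confidence: list
    labels3d: LabelVolume
    threshold: float

    def __post_init__(self):
        n = self.labels3d.shape[2]
        if len(self.per_slice_probs) != n or len(self.per_slice_confidence) != n:
            raise ValueError("per-slice lists must match the slice count")


def gate_by_confidence(probs, confidence: float) -> np.ndarray:
    """Scale a probability map by the slice classifier's confidence.

    Monotone: raising the confidence never removes a pixel that survived
    thresholding at a lower confidence."""
    if not 0.0 <= confidence <= 1.0:
        raise ValueError(f"confidence must be in [0, 1], got {confidence}")
    return np.asarray(probs, dtype=np.float32) * np.float32(confidence)


def stack_slices(masks, spacing) -> LabelVolume:
    """Pile segmented slices back up in the original CT sequence order."""
    masks = [np.asarray(m) for m in masks]
    if not masks:
        raise ValueError("need at least one slice")
    if any(m.shape != masks[0].shape for m in masks):
        raise ValueError("all slices must share a shape")
    return LabelVolume(np.stack(masks, axis=2).astype(np.int16), spacing)


def _forward_chunks(fn, *arrays):
    outs = []
    n = arrays[0].shape[0]
    for i in range(0, n, _CHUNK):
        outs.append(fn(*[a[i : i + _CHUNK] for a in arrays]))
    return np.concatenate(outs, axis=0)


def segment_volume(
    ct: CtVolume,
    pipeline: Pipeline,
    threshold: float = 0.5,
    postprocess: bool = False,
    bone_window=BONE_WINDOW,
    femur_window=FEMUR_WINDOW,
) -> SegmentationResult:
    """Segment femur and pelvis in a CT volume with an assembled pipeline.

    ``postprocess=True`` additionally keeps only the largest 3D femur
    component and fills holes; off by default.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    rows, cols = pipeline.in_rows, pipeline.in_cols
    n_slices = ct.shape[2]
    hu = ct.hu()

    bone_halves, femur_halves = [], []
    for k in range(n_slices):
        hu_k = resize_slice(hu[:, :, k], (rows, 2 * cols))
        for b, f in zip(
            split_and_flip(apply_window(hu_k, bone_window)),
            split_and_flip(apply_window(hu_k, femur_window)),
        ):
            bone_halves.append(b)
            femur_halves.append(f)
    xb = np.stack(bone_halves)[:, None].astype(np.float32)
    xf = np.stack(femur_halves)[:, None].astype(np.float32)

    bone_probs = _forward_chunks(lambda a: pipeline.upward(eg.Tensor(a))[0].data, xb)
    conf = _forward_chunks(
        lambda a: pipeline.classifier(eg.Tensor(a)).data, xb
    ).ravel()
    femur_probs = _forward_chunks(
        lambda a, b: pipeline.main(eg.Tensor(a), eg.Tensor(b))[-1].data, xf, bone_probs
    )

    per_slice_probs, per_slice_conf, femur_masks, bone_masks = [], [], [], []
    in_plane = ct.shape[:2]
    for k in range(n_slices):
        left, right = 2 * k, 2 * k + 1
        gated_halves = [
            gate_by_confidence(femur_probs[h, 0], float(conf[h])) for h in (left, right)
        ]
        gated = unsplit(*gated_halves)
        bone = unsplit(bone_probs[left, 0], bone_probs[right, 0])
        gated_full = resize_slice(gated, in_plane)
        bone_full = resize_slice(bone, in_plane)
        per_slice_probs.append(gated_full)
        per_slice_conf.append(float(max(conf[left], conf[right])))
        femur_masks.append(gated_full >= threshold)
        bone_masks.append(bone_full >= 0.5)

    femur3d = np.stack(femur_masks, axis=2)
    bone3d = np.stack(bone_masks, axis=2)
    if postprocess and femur3d.any():
        comp, ncomp = ndimage.label(femur3d)
        if ncomp > 1:
            sizes = ndimage.sum_labels(femur3d, comp, index=range(1, ncomp + 1))
            femur3d = comp == (1 + int(np.argmax(sizes)))
        femur3d = ndimage.binary_fill_holes(femur3d)

    labels = np.zeros(ct.shape, dtype=np.int16)
    labels[bone3d & ~femur3d] = LABEL_OTHER_BONE
    labels[femur3d] = LABEL_FEMUR
    return SegmentationResult(
        per_slice_probs=per_slice_probs,
        per_slice_confidence=per_slice_conf,
        labels3d=LabelVolume(labels, ct.spacing_mm),
        threshold=threshold,
    )
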