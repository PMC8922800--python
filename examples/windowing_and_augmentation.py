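"""Hounsfield windowing and the mid-split/mirror augmentation.

Two windows drive the pipeline: level 40 / width 200 HU highlights all bone
against soft tissue; level 500 / width 1000 HU suppresses soft tissue for the
femur net.  The augmentation halves each slice and mirrors the right half so
every sample looks like a left hip — doubling the dataset — and is exactly
invertible at test time.
"""

import numpy as np

from hipseg import BONE_WINDOW, FEMUR_WINDOW, apply_window, split_and_flip, unsplit

for hu in (-200.0, -60.0, 0.0, 40.0, 140.0, 500.0, 1200.0):
    b = apply_window(np.array([hu]), BONE_WINDOW)[0]
    f = apply_window(np.array([hu]), FEMUR_WINDOW)[0]
    print(f"HU {hu:7.1f} -> bone window {b:.3f}, femur window {f:.3f}")
# The bone window saturates at [-60, 140] HU; 40 HU sits exactly at 0.5.

slice_ = np.random.default_rng(0).random((256, 256)).astype(np.float32)
left, right = split_and_flip(slice_)
print(f"split: {slice_.shape} -> {left.shape} + {right.shape}")
print("reconstruction exact:", np.array_equal(unsplit(left, right), slice_))
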