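"""Image preprocessing and train-time augmentation.

Protocol: images are clipped to the largest square shared by the cohort
(default 3000 px) by a centered crop, resized to 256×256 with bilinear
interpolation, and scaled to [0, 1].  Training augmentation shifts within 5%
of the side (13 px at side 256) on both axes and rotates within ±5°.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize


@dataclass(frozen=True)
class AugmentationPolicy:
    shift_fraction: float = 0.05
    rotation_limit_degrees: float = 5.0
    # interpolation is bilinear, out-of-frame pixels filled with 0

    def max_shift(self, side: int) -> int:
        # round-half-up so that side 256 gives 13 (5% = 12.8 px)
        return int(np.floor(self.shift_fraction * side + 0.5))


def preprocess(image: np.ndarray, crop_side: int = 3000, out_side: int = 256) -> np.ndarray:
    """Centered square crop to ``crop_side`` then bilinear resize to ``out_side``.

    Accepts a 2-D grayscale array; integer dtypes are scaled to [0, 1] by
    their type maximum, floats are passed through.
    """
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    h, w = image.shape
    if h < crop_side or w < crop_side:
        raise ValueError(
            f"image {h}x{w} smaller than crop side {crop_side}"
        )
    top = (h - crop_side) // 2
    left = (w - crop_side) // 2
    cropped = image[top : top + crop_side, left : left + crop_side]
    if np.issubdtype(cropped.dtype, np.integer):
        cropped = cropped.astype(float) / np.iinfo(image.dtype).max
    else:
        cropped = cropped.astype(float)
    if crop_side == out_side:
        return cropped
    return resize(cropped, (out_side, out_side), order=1, anti_aliasing=True)


def sample_augmentation_params(policy: AugmentationPolicy, side: int,
                               rng: np.random.Generator) -> Tuple[float, int, int]:
    """Draw (angle_degrees, shift_x, shift_y) for one augmentation."""
    angle = rng.uniform(-policy.rotation_limit_degrees, policy.rotation_limit_degrees)
    m = policy.max_shift(side)
    dx = int(rng.integers(-m, m + 1))
    dy = int(rng.integers(-m, m + 1))
    return angle, dx, dy


def augment(image: np.ndarray, policy: AugmentationPolicy,
            rng: np.random.Generator) -> np.ndarray:
    """Random rotation then integer shift; bilinear, zero fill, fixed order."""
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("expected a square 2-D image")
    angle, dx, dy = sample_augmentation_params(policy, image.shape[0], rng)
    out = image
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="constant", cval=0.0)
    if dx or dy:
        out = ndimage.shift(out, (dy, dx), order=0, mode="constant", cval=0.0)
    return out
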