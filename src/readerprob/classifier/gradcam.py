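"""Grad-CAM saliency from the last convolutional feature maps."""

from __future__ import annotations

import numpy as np
from skimage.transform import resize


def grad_cam(model, image: np.ndarray, finding: int) -> np.ndarray:
    """Gradient-weighted class activation map at input resolution, in [0, 1].

    Channel weights are the spatial means of the gradient of the finding's
    logit with respect to the last convolutional feature maps; the heatmap is
    the ReLU of the weighted sum, bilinearly upsampled and max-normalized
    (all-zero if every weighted activation is negative).
    """
    if not hasattr(model, "feature_maps_and_grads"):
        raise TypeError("backend does not expose feature maps and gradients")
    maps, grads = model.feature_maps_and_grads(image, finding)
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum(np.tensordot(weights, maps, axes=1), 0.0)
    cam = resize(cam, image.shape, order=1, anti_aliasing=False)
    peak = cam.max()
    return cam / peak if peak > 0 else np.zeros_like(cam)
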