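"""Class-activation heatmaps (Grad-CAM) and overlay rendering.

The gradient of the target class's *pre-softmax* logit is taken with respect
to the post-SE feature maps of a chosen block (by default the last residual
block before the classifier head). Channel weights are the spatial means of
that gradient; the heatmap is the ReLU of the weighted feature-map sum,
normalized by its maximum into [0, 1] (an identically-zero map is left at
zero rather than divided), then bilinearly upsampled to the input resolution.
Using the logit rather than the softmax output avoids vanishing gradients on
confidently classified images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _resize

from .model import PortNet

__all__ = ["CamHeatmap", "grad_cam", "render_overlay"]


@dataclass
class CamHeatmap:
    """Per-pixel class-evidence map in [0, 1], aligned to the input image."""

    values: np.ndarray
    target_class: int

    def mass_inside(self, mask: np.ndarray) -> float:
        """Fraction of total heatmap mass falling inside a boolean mask."""
        total = float(self.values.sum())
        if total == 0.0:
            return 0.0
        return float(self.values[mask].sum()) / total


def _to_unit_chw(img: np.ndarray) -> np.ndarray:
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got {img.shape}")
    unit = img.astype(np.float32) / 255.0 if np.issubdtype(img.dtype, np.integer) \
        else img.astype(np.float32)
    return unit.transpose(2, 0, 1)[None]


def grad_cam(model: PortNet, img: np.ndarray, target_class: int,
             block_index: int | None = None) -> CamHeatmap:
    """Gradient-weighted class-activation map for one image.

    ``block_index`` selects which block's output to explain; the default is
    the final residual block (index ``len(blocks) - 2``), whose features
    carry the most class-specific evidence at the coarsest resolution.
    """
    if not 0 <= target_class < model.config.num_classes:
        raise ValueError(
            f"target_class {target_class} outside 0..{model.config.num_classes - 1}")
    if block_index is None:
        block_index = len(model.blocks) - 2
    if not 0 <= block_index < len(model.blocks) - 1:
        raise ValueError(f"block_index {block_index} out of range")
    x = _to_unit_chw(img)
    logits = model.forward(x, train=False, record=True)
    features = model._block_outputs[block_index][0]
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    model.zero_grad()
    grad = model.backward(dlogits, capture_block=block_index)[0]
    model.zero_grad()

    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * features).sum(axis=0), 0.0)
    cam_full = _resize(cam, img.shape[:2], order=1, preserve_range=True,
                       anti_aliasing=False)
    cam_full = np.maximum(cam_full, 0.0)
    peak = cam_full.max()
    if peak > 0:  # an all-zero map (no positive evidence) is left at zero
        cam_full = cam_full / peak
    return CamHeatmap(values=np.clip(cam_full, 0.0, 1.0).astype(np.float32),
                      target_class=target_class)


def render_overlay(img: np.ndarray, cam: CamHeatmap, colormap: str = "jet",
                   alpha: float = 0.6) -> np.ndarray:
    """Alpha-blend a color-mapped heatmap over the image.

    The blend is pixel-wise convex with weight ``alpha * cam``: zero heat
    leaves the pixel untouched, full heat gives the maximal tint. Returns the
    same representation (uint8 or unit float) as the input.
    """
    if img.shape[:2] != cam.values.shape:
        raise ValueError(
            f"image {img.shape[:2]} and heatmap {cam.values.shape} misaligned")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0,1]")
    was_int = np.issubdtype(img.dtype, np.integer)
    unit = img.astype(np.float64) / 255.0 if was_int else img.astype(np.float64)
    color = colormaps[colormap](cam.values)[..., :3]
    w = (alpha * cam.values)[..., None]
    out = (1.0 - w) * unit + w * color
    out = np.clip(out, 0.0, 1.0)
    if was_int:
        return np.floor(out * 255.0 + 0.5).astype(img.dtype)
    return out.astype(img.dtype)
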