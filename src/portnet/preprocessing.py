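"""Histology image enhancement: denoise, edge re-injection, equalization.

The chain applied before classification:

1. k x k mean (box) filtering to suppress surface noise;
2. a Gaussian high-pass (image minus Gaussian blur) extracts edge detail from
   the *original* image, which is scaled by a gain ``alpha`` and added back to
   the denoised image — recovering the edges the box filter smeared;
3. histogram equalization applied to the brightness channel only (BT.601
   luminance by default, HSV value optionally), leaving chrominance intact.

Images are H x W x 3 RGB arrays, either integer-valued in [0, 255] or real in
[0, 1]; every operation preserves the representation it was given and clips
back into the declared range. All operations are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessParams",
    "mean_filter",
    "gaussian_highpass",
    "enhance",
    "equalize_brightness",
    "preprocess_pipeline",
]

# BT.601 full-range RGB <-> YCbCr
_RGB_TO_YCBCR = np.array([
    [0.299, 0.587, 0.114],
    [-0.168736, -0.331264, 0.5],
    [0.5, -0.418688, -0.081312],
], dtype=np.float64)
_YCBCR_TO_RGB = np.linalg.inv(_RGB_TO_YCBCR)


@dataclass
class PreprocessParams:
    """Tunables of the enhancement chain.

    mean_kernel: odd box-filter width in pixels (default 3).
    sigma: Gaussian low-pass scale in pixels for the high-pass (default 2.0).
    alpha: gain on the re-injected edge map (default 1.0; 0 disables).
    highpass_on_filtered: take the high-pass of the already-denoised image
        instead of the original.
    space: brightness space for equalization, "ycbcr" or "hsv".
    """

    mean_kernel: int = 3
    sigma: float = 2.0
    alpha: float = 1.0
    highpass_on_filtered: bool = False
    space: str = "ycbcr"

    def validate(self) -> None:
        if self.mean_kernel < 1 or self.mean_kernel % 2 == 0:
            raise ValueError(f"mean_kernel must be odd and >= 1, got {self.mean_kernel}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if self.space not in ("ycbcr", "hsv"):
            raise ValueError(f"space must be 'ycbcr' or 'hsv', got {self.space!r}")


def _check_image(img: np.ndarray) -> None:
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {img.shape}")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError(f"image smaller than 8x8: {img.shape[:2]}")


def _as_unit(img: np.ndarray) -> tuple[np.ndarray, bool]:
    """Return (float64 image in [0,1], was_integer)."""
    _check_image(img)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.float64) / 255.0, True
    return img.astype(np.float64), False


def _restore(unit: np.ndarray, was_int: bool, like: np.ndarray) -> np.ndarray:
    unit = np.clip(unit, 0.0, 1.0)
    if was_int:
        return np.floor(unit * 255.0 + 0.5).astype(like.dtype)
    return unit.astype(like.dtype if np.issubdtype(like.dtype, np.floating) else np.float64)


def mean_filter(img: np.ndarray, k: int = 3) -> np.ndarray:
    """Per-channel k x k box average with reflective borders."""
    if k < 1 or k % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {k}")
    unit, was_int = _as_unit(img)
    if k == 1:
        return _restore(unit, was_int, img)
    out = ndimage.uniform_filter(unit, size=(k, k, 1), mode="reflect")
    return _restore(out, was_int, img)


def _gaussian_blur(unit: np.ndarray, sigma: float) -> np.ndarray:
    radius = int(ceil(3.0 * sigma))
    return ndimage.gaussian_filter(unit, sigma=(sigma, sigma, 0),
                                   mode="reflect", radius=(radius, radius, 0))


def gaussian_highpass(img: np.ndarray, sigma: float) -> np.ndarray:
    """Signed edge map ``img - G_sigma(img)`` in [-1, 1] on the unit scale.

    The blur kernel has half-width ceil(3*sigma) and is normalized. The
    per-channel mean is subtracted before blurring (the high-pass is
    invariant to this shift up to rounding), which makes the edge map of a
    constant image exactly zero in floating point.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    unit, _ = _as_unit(img)
    centered = unit - unit.mean(axis=(0, 1))
    return centered - _gaussian_blur(centered, sigma)


def enhance(img: np.ndarray, p: PreprocessParams | None = None) -> np.ndarray:
    """Mean-filter then add back alpha-scaled high-pass edge detail."""
    p = p or PreprocessParams()
    p.validate()
    unit, was_int = _as_unit(img)
    base = (unit if p.mean_kernel == 1
            else ndimage.uniform_filter(unit, size=(p.mean_kernel, p.mean_kernel, 1),
                                        mode="reflect"))
    if p.alpha > 0:
        source = base if p.highpass_on_filtered else unit
        centered = source - source.mean(axis=(0, 1))
        base = base + p.alpha * (centered - _gaussian_blur(centered, p.sigma))
    return _restore(base, was_int, img)


def _equalize_u8(channel_u8: np.ndarray) -> np.ndarray:
    """256-bin CDF equalization of a uint8 channel; y -> round(cdf(y)*255)."""
    hist = np.bincount(channel_u8.ravel(), minlength=256)
    cdf = np.cumsum(hist) / channel_u8.size
    lut = np.floor(cdf * 255.0 + 0.5).astype(np.uint8)
    return lut[channel_u8]


def equalize_brightness(img: np.ndarray, space: str = "ycbcr") -> np.ndarray:
    """Histogram-equalize the brightness channel only.

    ``ycbcr``: BT.601 luminance Y is equalized; Cb/Cr untouched. ``hsv``: the
    HSV value channel is equalized; hue/saturation untouched.
    """
    unit, was_int = _as_unit(img)
    if space == "ycbcr":
        ycc = unit @ _RGB_TO_YCBCR.T
        y_u8 = np.clip(np.floor(ycc[..., 0] * 255.0 + 0.5), 0, 255).astype(np.uint8)
        ycc[..., 0] = _equalize_u8(y_u8) / 255.0
        out = ycc @ _YCBCR_TO_RGB.T
    elif space == "hsv":
        import matplotlib.colors as mcolors
        hsv = mcolors.rgb_to_hsv(np.clip(unit, 0, 1))
        v_u8 = np.clip(np.floor(hsv[..., 2] * 255.0 + 0.5), 0, 255).astype(np.uint8)
        hsv[..., 2] = _equalize_u8(v_u8) / 255.0
        out = mcolors.hsv_to_rgb(hsv)
    else:
        raise ValueError(f"space must be 'ycbcr' or 'hsv', got {space!r}")
    return _restore(out, was_int, img)


def preprocess_pipeline(img: np.ndarray, p: PreprocessParams | None = None) -> np.ndarray:
    """Full chain: denoise + edge re-injection, then brightness equalization."""
    p = p or PreprocessParams()
    p.validate()
    return equalize_brightness(enhance(img, p), space=p.space)
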