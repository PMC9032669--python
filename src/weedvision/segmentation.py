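"""Vegetation/soil segmentation in HSV colour space.

Field images of young corn and weeds are separated from the soil background
by thresholding in HSV, where hue (the colour angle) is decorrelated from
value (brightness) — the property that makes greenness detection robust to
the sunny/cloudy illumination swings of outdoor acquisition.  The byte-range
HSV convention is used throughout: hue in [0, 180), saturation and value in
[0, 255], so a threshold band is six small integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

__all__ = [
    "HSVThresholds",
    "DEFAULT_THRESHOLDS",
    "rgb_to_hsv",
    "threshold_vegetation",
    "segment_vegetation",
]


@dataclass(frozen=True)
class HSVThresholds:
    """Inclusive per-channel bounds defining the vegetation colour band.

    The defaults are the hand-tuned values for green vegetation over bare
    soil under variable natural light: hue 33–95 on the [0, 180) scale
    (roughly 66°–190°, the green band), saturation 34–255 (excludes grey
    soil and specular highlights), value 60–250 (excludes deep shadow and
    blown-out pixels).
    """

    h_lo: int = 33
    h_hi: int = 95
    s_lo: int = 34
    s_hi: int = 255
    v_lo: int = 60
    v_hi: int = 250

    def __post_init__(self) -> None:
        for lo, hi, name, top in (
            (self.h_lo, self.h_hi, "hue", 179),
            (self.s_lo, self.s_hi, "saturation", 255),
            (self.v_lo, self.v_hi, "value", 255),
        ):
            if lo > hi:
                raise ValueError(f"{name} lower bound {lo} exceeds upper bound {hi}")
            if lo < 0 or hi > top:
                raise ValueError(f"{name} bounds ({lo}, {hi}) outside [0, {top}]")


DEFAULT_THRESHOLDS = HSVThresholds()


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (m, n, 3) RGB image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image has no pixels")
    return img


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to byte-range HSV.

    Parameters
    ----------
    img : (m, n, 3) uint8 array
        RGB pixels, each channel in [0, 255].

    Returns
    -------
    (m, n, 3) uint8 array with hue in [0, 180), saturation and value in
    [0, 255] (the OpenCV byte convention).
    """
    img = _check_rgb(img)
    hsv = rgb2hsv(img.astype(np.float64) / 255.0)
    h = np.round(hsv[..., 0] * 180.0) % 180
    s = np.round(hsv[..., 1] * 255.0)
    v = np.round(hsv[..., 2] * 255.0)
    return np.stack([h, s, v], axis=-1).astype(np.uint8)


def threshold_vegetation(
    hsv: np.ndarray, thresholds: HSVThresholds = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Binary vegetation mask from a byte-range HSV image.

    A pixel is foreground (255) iff all three channels lie inside the
    band, bounds inclusive; everything else is background (0).
    """
    hsv = np.asarray(hsv)
    if hsv.ndim != 3 or hsv.shape[2] != 3:
        raise ValueError(f"expected an (m, n, 3) HSV image, got shape {hsv.shape}")
    h = hsv[..., 0].astype(np.int32)
    s = hsv[..., 1].astype(np.int32)
    v = hsv[..., 2].astype(np.int32)
    t = thresholds
    inside = (
        (h >= t.h_lo) & (h <= t.h_hi)
        & (s >= t.s_lo) & (s <= t.s_hi)
        & (v >= t.v_lo) & (v <= t.v_hi)
    )
    return np.where(inside, 255, 0).astype(np.uint8)


def segment_vegetation(
    img: np.ndarray, thresholds: HSVThresholds = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """RGB field image -> raw binary vegetation mask (threshold only).

    Morphological clean-up and small-region discard are separate steps; see
    :func:`weedvision.morphology.enhance_mask` and
    :func:`weedvision.components.filter_small_components`.
    """
    return threshold_vegetation(rgb_to_hsv(img), thresholds)
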