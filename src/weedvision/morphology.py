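"""Binary morphology for mask clean-up.

Thresholded vegetation masks carry salt noise (small bright clusters over
soil) and pepper holes (dark specks inside leaves).  Opening — erosion then
dilation — removes artifacts smaller than the structuring element; closing —
dilation then erosion — fills comparably small holes.  Both are run with the
same structuring element, a solid 5×5 square by default.

Masks are uint8 arrays over {0, 255}; pixels outside the image are treated
as background, so erosion shaves foreground touching the border.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "square_se",
    "disk_se",
    "erode",
    "dilate",
    "morph_open",
    "morph_close",
    "enhance_mask",
]


def square_se(size: int = 5) -> np.ndarray:
    """Solid size×size boolean structuring element (size odd)."""
    if size < 1 or size % 2 == 0:
        raise ValueError(f"structuring element size must be odd and positive, got {size}")
    return np.ones((size, size), dtype=bool)


def disk_se(radius: int) -> np.ndarray:
    """Disk-shaped structuring element of given radius (side 2*radius+1)."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = np.arange(-radius, radius + 1)
    yy, xx = np.meshgrid(r, r, indexing="ij")
    return (yy**2 + xx**2) <= radius**2


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {mask.shape}")
    return mask > 0


def _as_mask(fg: np.ndarray) -> np.ndarray:
    return np.where(fg, 255, 0).astype(np.uint8)


def erode(mask: np.ndarray, se: np.ndarray = None) -> np.ndarray:
    """Erosion: keep a pixel iff the SE translated there fits in the foreground."""
    se = square_se() if se is None else np.asarray(se, dtype=bool)
    return _as_mask(ndimage.binary_erosion(_as_bool(mask), structure=se, border_value=0))


def dilate(mask: np.ndarray, se: np.ndarray = None) -> np.ndarray:
    """Dilation: set a pixel iff the reflected SE translated there hits the foreground."""
    se = square_se() if se is None else np.asarray(se, dtype=bool)
    return _as_mask(ndimage.binary_dilation(_as_bool(mask), structure=se, border_value=0))


def morph_open(mask: np.ndarray, se: np.ndarray = None) -> np.ndarray:
    """Opening (erosion then dilation): removes artifacts smaller than the SE."""
    se = square_se() if se is None else np.asarray(se, dtype=bool)
    return dilate(erode(mask, se), se)


def morph_close(mask: np.ndarray, se: np.ndarray = None) -> np.ndarray:
    """Closing (dilation then erosion): fills holes smaller than the SE."""
    se = square_se() if se is None else np.asarray(se, dtype=bool)
    return erode(dilate(mask, se), se)


def enhance_mask(mask: np.ndarray, se: np.ndarray = None) -> np.ndarray:
    """Mask clean-up as run in the pipeline: opening, then closing, same SE."""
    se = square_se() if se is None else np.asarray(se, dtype=bool)
    return morph_close(morph_open(mask, se), se)
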