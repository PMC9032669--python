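"""Connected-component analysis and ROI extraction.

Each maximal connected foreground region of the cleaned vegetation mask is
one plant candidate.  Regions are labelled 1..K in raster order of their
first pixel (deterministic output ordering), small regions are discarded as
residual noise, and the survivors' bounding boxes are cropped from the
*original* RGB image to yield one region-of-interest patch per plant.

Bounding boxes are stored inclusive: (rmin, cmin, rmax, cmax) spans
rmax - rmin + 1 rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "Component",
    "ComponentMap",
    "ROIPatch",
    "label_components",
    "filter_small_components",
    "extract_patches",
]


@dataclass(frozen=True)
class Component:
    label: int
    area: int
    bbox: tuple[int, int, int, int]  # rmin, cmin, rmax, cmax (inclusive)


@dataclass(frozen=True)
class ComponentMap:
    """Label image plus per-component summary.

    ``labels`` is an int array the size of the source mask, 0 for background,
    with component labels consecutive from 1.
    """

    labels: np.ndarray
    components: tuple[Component, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.components)

    def to_frame(self) -> pd.DataFrame:
        """Component table: label, area, bbox_rmin, bbox_cmin, bbox_rmax, bbox_cmax."""
        rows = [
            {
                "label": c.label,
                "area": c.area,
                "bbox_rmin": c.bbox[0],
                "bbox_cmin": c.bbox[1],
                "bbox_rmax": c.bbox[2],
                "bbox_cmax": c.bbox[3],
            }
            for c in self.components
        ]
        return pd.DataFrame(
            rows,
            columns=["label", "area", "bbox_rmin", "bbox_cmin", "bbox_rmax", "bbox_cmax"],
        )


@dataclass(frozen=True)
class ROIPatch:
    """RGB crop around one segmented plant."""

    pixels: np.ndarray
    bbox: tuple[int, int, int, int]  # crop bounds in the source image, inclusive
    component_label: int
    class_label: str | None = None

    def with_label(self, label: str) -> "ROIPatch":
        return replace(self, class_label=label)


def label_components(mask: np.ndarray, connectivity: int = 8) -> ComponentMap:
    """Label maximal connected foreground regions of a binary mask.

    connectivity 8 (default) merges diagonal neighbours — fragments of one
    leaf touching only corner-wise stay one plant; 4 treats them as separate.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    fg = np.asarray(mask) > 0
    raw = measure.label(fg, connectivity=1 if connectivity == 4 else 2)
    return _relabel_raster_order(raw)


def _relabel_raster_order(raw: np.ndarray) -> ComponentMap:
    """Re-index labels 1..K by raster order of each component's first pixel."""
    n = int(raw.max())
    if n == 0:
        return ComponentMap(labels=np.zeros_like(raw, dtype=np.int32))
    flat = raw.ravel()
    # first flat index at which each label occurs
    order = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    order[flat[idx[::-1]]] = idx[::-1]
    ranking = np.argsort(order[1:], kind="stable")  # old label-1 -> rank
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + ranking] = np.arange(1, n + 1)
    labels = remap[raw]

    components = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        components.append(
            Component(
                label=lab,
                area=int(rows.size),
                bbox=(int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())),
            )
        )
    return ComponentMap(labels=labels, components=tuple(components))


def filter_small_components(cm: ComponentMap, min_area: int = 400) -> ComponentMap:
    """Drop components with area < min_area; relabel survivors 1..K'.

    The default 400 px suits full-resolution field images; for small
    synthetic scenes pass a value scaled to the scene.  ``min_area`` may
    also be derived from an image fraction by the caller.
    """
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    keep = [c for c in cm.components if c.area >= min_area]
    remap = np.zeros(len(cm.components) + 1, dtype=np.int32)
    survivors = []
    for new_lab, c in enumerate(keep, start=1):
        remap[c.label] = new_lab
        survivors.append(Component(label=new_lab, area=c.area, bbox=c.bbox))
    return ComponentMap(labels=remap[cm.labels], components=tuple(survivors))


def extract_patches(
    rgb: np.ndarray, cm: ComponentMap, padding: int = 0
) -> list[ROIPatch]:
    """Crop one RGB patch per component, bbox expanded by ``padding`` px.

    Crops come from the original RGB image (colour and texture intact) and
    are clipped at the image border; ordered by component label.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (m, n, 3) RGB image, got shape {rgb.shape}")
    if rgb.shape[:2] != cm.labels.shape:
        raise ValueError(
            f"image shape {rgb.shape[:2]} does not match component map {cm.labels.shape}"
        )
    if padding < 0:
        raise ValueError("padding must be non-negative")
    m, n = rgb.shape[:2]
    patches = []
    for c in cm.components:
        rmin = max(c.bbox[0] - padding, 0)
        cmin = max(c.bbox[1] - padding, 0)
        rmax = min(c.bbox[2] + padding, m - 1)
        cmax = min(c.bbox[3] + padding, n - 1)
        patches.append(
            ROIPatch(
                pixels=rgb[rmin : rmax + 1, cmin : cmax + 1].copy(),
                bbox=(rmin, cmin, rmax, cmax),
                component_label=c.label,
            )
        )
    return patches
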