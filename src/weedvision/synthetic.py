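"""Synthetic multi-plant field scenes with ground truth.

Emulates the imaging conditions of early-season corn fields — brownish
textured soil, well-separated green plants (no occlusion at the 2–7 leaf
stage), sun/cloud illumination swings — so every pipeline stage can be
exercised and scored without real imagery.  Three class-distinct plant
archetypes are rendered:

* ``Crop`` (corn): a few wide blades radiating from a hub, coarse vein
  striping (low spatial frequency across the blade);
* ``NLW`` (narrow-leaf weeds, grasses): many thin blades, fine striping
  (high frequency) — the same monocot body plan as corn, which is exactly
  the confusion structure observed on real fields;
* ``BLW`` (broadleaf weeds): lobed, roundish leaves with blotchy,
  isotropic surface texture.

Stripe frequency is the lever separating Crop from NLW: the default gap
keeps the classes texture-separable; ``stripe_overlap`` in (0, 1] narrows
it to emulate Crop↔NLW confusion.  Plant colours are multiplicatively
shaded (hue-preserving), so every plant pixel stays inside the default HSV
vegetation band; soil hue sits below it.  All randomness flows from one
seed, making scenes bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import components as comp
from . import morphology, segmentation

__all__ = [
    "SceneParams",
    "PlantInstance",
    "FieldScene",
    "render_plant",
    "generate_scene",
    "scene_to_dataset",
    "render_patch_dataset",
]

CLASSES = ("Crop", "NLW", "BLW")

# base RGB per class; shading is multiplicative so hue is preserved
_BASE_RGB = {
    "Crop": (58, 142, 48),
    "NLW": (72, 152, 62),
    "BLW": (48, 132, 56),
}
_SOIL_RGB = (112, 86, 58)


@dataclass(frozen=True)
class SceneParams:
    """Scene layout and imaging conditions (defaults = study conditions)."""

    image_size: int = 768
    n_per_class: tuple[int, int, int] = (3, 3, 3)  # Crop, NLW, BLW
    scale_range: tuple[int, int] = (72, 110)  # plant diameter, px
    min_separation: int = 30  # gap between plant bounding circles, px
    soil_noise: float = 8.0  # chromatic per-pixel noise, grey levels
    illumination_range: tuple[float, float] = (0.85, 1.15)
    stripe_overlap: float = 0.0  # 0 = separable classes, 1 = Crop/NLW overlap
    seed: int = 0

    def __post_init__(self):
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("plant counts must be non-negative")
        if self.min_separation < 0:
            raise ValueError("separation must be non-negative")
        if self.illumination_range[0] <= 0:
            raise ValueError("illumination gain must be positive")
        if not 0.0 <= self.stripe_overlap <= 1.0:
            raise ValueError("stripe_overlap must be in [0, 1]")


@dataclass(frozen=True)
class PlantInstance:
    cls: str
    center: tuple[int, int]  # row, col in the scene
    bbox: tuple[int, int, int, int]  # rmin, cmin, rmax, cmax inclusive
    mask: np.ndarray  # patch-sized boolean support
    texture: dict = field(default_factory=dict)

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0 : r1 + 1, c0 : c1 + 1] = self.mask
        return out


@dataclass(frozen=True)
class FieldScene:
    image: np.ndarray  # uint8 RGB
    plants: tuple[PlantInstance, ...]
    params: SceneParams

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "plant": k,
                "class": p.cls,
                "center_row": p.center[0],
                "center_col": p.center[1],
                "bbox_rmin": p.bbox[0],
                "bbox_cmin": p.bbox[1],
                "bbox_rmax": p.bbox[2],
                "bbox_cmax": p.bbox[3],
            }
            for k, p in enumerate(self.plants)
        ]
        return pd.DataFrame(
            rows,
            columns=["plant", "class", "center_row", "center_col",
                     "bbox_rmin", "bbox_cmin", "bbox_rmax", "bbox_cmax"],
        )


def _vein_bands(overlap: float) -> dict:
    """Vein-stripe density bands for the monocots, in cycles per blade width.

    Specifying veining relative to blade width (how many vein bands cross
    one leaf) rather than in absolute pixels makes the texture cue
    scale-invariant — a small grass is as finely veined as a large one,
    which is the botanical reality and what keeps the classes separable
    across the plant-size range.  Corn shows about one coarse band per
    blade, grasses two to three fine ones.  ``overlap`` in (0, 1] narrows
    the gap between the bands to emulate Crop↔NLW confusion.
    """
    gap_mid = 1.75
    crop_hi = 1.3 + (gap_mid - 1.3) * overlap
    nlw_lo = 2.2 - (2.2 - gap_mid) * overlap
    return {"Crop": (0.9, crop_hi), "NLW": (nlw_lo, 2.8)}


def _blade_mask(size: int, angle: float, length: float, width: float) -> np.ndarray:
    """Elliptical blade rooted at the patch centre, pointing along ``angle``."""
    c = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size]
    y, x = rr - c, cc - c
    u = x * np.cos(angle) + y * np.sin(angle)  # along the blade
    v = -x * np.sin(angle) + y * np.cos(angle)  # across the blade
    return ((u - length / 2) / (length / 2)) ** 2 + (v / (width / 2)) ** 2 <= 1.0


def render_plant(
    cls: str, scale: int, rng: np.random.Generator, stripe_overlap: float = 0.0
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render one plant: (RGB float patch, boolean support mask, texture params).

    The patch is scale×scale; pixels outside the mask are zero.  Monocots
    (Crop, NLW) get blades with sinusoidal vein striping across the blade;
    BLW gets lobed leaves with low-pass blotch texture.  All plant pixels
    keep the class hue (shading is multiplicative), so the rendered plant
    lies inside the default vegetation threshold band.
    """
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    if scale < 24:
        raise ValueError(f"plant scale {scale} too small to render")
    s = int(scale)
    c = (s - 1) / 2.0
    rr, cc = np.mgrid[0:s, 0:s]
    dist = np.hypot(rr - c, cc - c)

    mask = dist <= max(4.0, 0.08 * s)  # hub keeps the blades connected
    texture = np.zeros((s, s))
    params: dict = {"class": cls, "scale": s}

    if cls in ("Crop", "NLW"):
        n_blades = int(rng.integers(3, 5)) if cls == "Crop" else int(rng.integers(6, 9))
        width_frac = 0.18 if cls == "Crop" else 0.11
        lo, hi = _vein_bands(stripe_overlap)[cls]
        cycles = float(rng.uniform(lo, hi))  # vein bands per blade width
        base_angle = float(rng.uniform(0, 2 * np.pi))
        freq = cycles / (width_frac * s)
        for k in range(n_blades):
            angle = base_angle + 2 * np.pi * k / n_blades + rng.normal(0, 0.12)
            extent = (s / 2 - 1) * rng.uniform(0.85, 1.0)
            width = max(8.0, width_frac * s * rng.uniform(0.85, 1.15))
            blade = _blade_mask(s, angle, extent, width)
            mask |= blade
            v = -(cc - c) * np.sin(angle) + (rr - c) * np.cos(angle)
            phase = rng.uniform(0, 2 * np.pi)
            texture[blade] = np.sin(2 * np.pi * freq * v[blade] + phase)
        params.update(n_blades=n_blades, vein_cycles=cycles, stripe_frequency=freq)
    else:  # BLW: lobed leaves, blotchy surface
        n_lobes = int(rng.integers(4, 7))
        for _ in range(n_lobes):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.16, 0.24) * s
            d = rng.uniform(0.12, 0.26) * s
            cy, cx = c + d * np.sin(ang), c + d * np.cos(ang)
            mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= rad**2
        blotch_scale = 0.05 * s
        noise = rng.normal(size=(s, s))
        smooth = ndimage.gaussian_filter(noise, blotch_scale)
        smooth /= np.abs(smooth).max() + 1e-12
        texture = smooth
        params.update(n_lobes=n_lobes, blotch_scale=blotch_scale)

    mask &= dist <= (s - 1) / 2.0 + 0.5  # keep the plant inside its bounding circle
    base = np.asarray(_BASE_RGB[cls], dtype=np.float64) * rng.uniform(0.92, 1.08)
    shading = 1.0 + 0.32 * texture
    patch = np.zeros((s, s, 3))
    patch[mask] = base[None, :] * shading[mask][:, None]
    return patch, mask, params


def _soil_background(size: int, noise: float, rng: np.random.Generator) -> np.ndarray:
    base = np.asarray(_SOIL_RGB, dtype=np.float64)
    img = np.broadcast_to(base, (size, size, 3)).copy()
    # achromatic low-frequency variation (clods, moisture): hue-preserving
    lf = ndimage.gaussian_filter(rng.normal(size=(size, size)), size / 24.0)
    lf = lf / (np.abs(lf).max() + 1e-12) * 0.16
    img *= (1.0 + lf)[..., None]
    # mild chromatic per-pixel noise
    img += rng.normal(0, noise, size=(size, size, 3))
    return img


def generate_scene(params: SceneParams = SceneParams()) -> FieldScene:
    """Compose a full field scene: soil + placed plants + illumination gain.

    Plants are placed by rejection sampling so their bounding circles stay
    ``min_separation`` apart (no occlusion, as on early-season fields);
    raises if the requested plants cannot be packed after bounded retries.
    """
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    img = _soil_background(size, params.soil_noise, rng)

    placed: list[tuple[float, float, float]] = []  # row, col, radius
    plants: list[PlantInstance] = []
    for cls, count in zip(CLASSES, params.n_per_class):
        for _ in range(count):
            scale = int(rng.integers(params.scale_range[0], params.scale_range[1] + 1))
            radius = scale / 2.0
            margin = int(np.ceil(radius)) + 1
            if size - margin <= margin:
                raise ValueError("image too small for the requested plant scale")
            for _attempt in range(300):
                r = float(rng.uniform(margin, size - margin))
                c = float(rng.uniform(margin, size - margin))
                if all(
                    np.hypot(r - pr, c - pc) >= radius + prad + params.min_separation
                    for pr, pc, prad in placed
                ):
                    break
            else:
                raise RuntimeError(
                    f"could not place {sum(params.n_per_class)} plants at "
                    f"separation {params.min_separation} in a {size}px scene"
                )
            placed.append((r, c, radius))
            patch, mask, texture = render_plant(
                cls, scale, rng, stripe_overlap=params.stripe_overlap
            )
            s = patch.shape[0]
            r0 = int(round(r - (s - 1) / 2.0))
            c0 = int(round(c - (s - 1) / 2.0))
            region = img[r0 : r0 + s, c0 : c0 + s]
            region[mask] = patch[mask]
            plants.append(
                PlantInstance(
                    cls=cls,
                    center=(int(round(r)), int(round(c))),
                    bbox=(r0, c0, r0 + s - 1, c0 + s - 1),
                    mask=mask,
                    texture=texture,
                )
            )

    gain = rng.uniform(*params.illumination_range)
    img = np.clip(img * gain, 0, 255).astype(np.uint8)
    return FieldScene(image=img, plants=tuple(plants), params=params)


def scene_to_dataset(
    scenes,
    min_area: int = 150,
    min_iou: float = 0.5,
    se: np.ndarray = None,
    thresholds=segmentation.DEFAULT_THRESHOLDS,
) -> tuple[list, pd.DataFrame]:
    """Run the segmentation pipeline on scenes and label ROIs by ground truth.

    Each extracted ROI is matched to the plant whose support mask has the
    highest intersection-over-union with the ROI's component, accepted at
    IoU >= ``min_iou``; unmatched ROIs are excluded and counted in the
    manifest.  Returns (labelled patches, manifest frame).
    """
    patches_out = []
    rows = []
    for scene_id, scene in enumerate(scenes):
        mask = segmentation.segment_vegetation(scene.image, thresholds)
        mask = morphology.enhance_mask(mask, se)
        cm = comp.filter_small_components(comp.label_components(mask), min_area)
        rois = comp.extract_patches(scene.image, cm)
        gt_masks = [p.full_mask(scene.image.shape[:2]) for p in scene.plants]
        for roi in rois:
            region = cm.labels == roi.component_label
            best_iou, best_plant = 0.0, None
            for plant_id, gt in enumerate(gt_masks):
                inter = np.logical_and(region, gt).sum()
                if inter == 0:
                    continue
                union = np.logical_or(region, gt).sum()
                iou = inter / union
                if iou > best_iou:
                    best_iou, best_plant = iou, plant_id
            matched = best_plant is not None and best_iou >= min_iou
            rows.append({
                "scene": scene_id,
                "component": roi.component_label,
                "matched": matched,
                "iou": best_iou,
                "class": scene.plants[best_plant].cls if matched else None,
            })
            if matched:
                patches_out.append(roi.with_label(scene.plants[best_plant].cls))
    manifest = pd.DataFrame(
        rows, columns=["scene", "component", "matched", "iou", "class"]
    )
    return patches_out, manifest


def render_patch_dataset(
    n_per_class: int,
    seed: int = 0,
    scale_range: tuple[int, int] = (72, 110),
    stripe_overlap: float = 0.0,
) -> tuple[list, list]:
    """Standalone labelled single-plant patches (no scene composition).

    Convenience generator for training classifiers: each patch is one plant
    rendered over a soil background square, with the class label attached.
    """
    rng = np.random.default_rng(seed)
    patches, labels = [], []
    for cls in CLASSES:
        for _ in range(n_per_class):
            scale = int(rng.integers(scale_range[0], scale_range[1] + 1))
            plant, mask, _ = render_plant(cls, scale, rng, stripe_overlap)
            soil = _soil_background(scale, 8.0, rng)
            soil[mask] = plant[mask]
            gain = rng.uniform(0.85, 1.15)
            patches.append(np.clip(soil * gain, 0, 255).astype(np.uint8))
            labels.append(cls)
    return patches, labels
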