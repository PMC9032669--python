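"""Rotation-invariant uniform local binary patterns (LBP^riu2).

The descriptor behind the shallow classification route.  For a centre pixel
with grey value g_c and P neighbours g_0..g_{P-1} sampled on a circle of
radius R (p = 0 due east, proceeding counter-clockwise, non-integer
positions bilinearly interpolated), the classic LBP code is

    LBP_{P,R} = sum_p s(g_p - g_c) * 2^p,      s(x) = 1 if x >= 0 else 0,

a number in [0, 2^P - 1].  Most of those 2^P patterns are noise; the
*uniform* ones — at most two 0<->1 transitions around the circle (U <= 2) —
carry the micro-structure (spots, edges, line ends, flats).  The riu2 map
collapses each uniform pattern to its count of ones (which is invariant
under rotation, i.e. circular bit shifts) and every non-uniform pattern to
one shared bin P+1, giving P+2 bins in total: 10, 18, 26 for the standard
(P, R) pairs (8,1), (16,2), (24,3).

Texture features for a plant patch are per-cell riu2 histograms: the
grey patch is resized to image_size², partitioned into a grid of
cell_size² cells, each cell's histogram (L1-normalised) computed over its
interior pixels, and the histograms concatenated in raster order — vector
length (image_size/cell_size)² × (P+2).

Ties (g_p == g_c) count as 1, so a constant image produces the all-ones
pattern (U = 0, P ones): bin P.  Adding a constant to every grey value
changes no comparison, which is the operator's monotonic grey-scale
invariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = [
    "LBPConfig",
    "TABLE_CONFIGS",
    "to_grayscale",
    "circular_neighbors",
    "binary_pattern",
    "lbp_code",
    "uniformity",
    "riu2_code",
    "riu2_histogram",
    "cell_grid_features",
    "featurize_patch",
    "feature_length",
]

#: ITU-R BT.601 luma weights for the RGB -> grey conversion.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: Supported circle geometries: neighbour count -> radius.
STANDARD_PR = {8: 1, 16: 2, 24: 3}


@dataclass(frozen=True)
class LBPConfig:
    """Geometry of one descriptor configuration.

    n_points, radius : the (P, R) circle, one of (8,1), (16,2), (24,3).
    image_size : side length the grey patch is resized to (256/128/64).
    cell_size : side of the square grid cells; must divide image_size,
        be strictly smaller than it, and exceed 2R so a cell has at least
        one interior centre pixel.
    normalize : L1-normalise each cell histogram (default) or keep counts.
    """

    n_points: int = 8
    radius: int = 1
    image_size: int = 256
    cell_size: int = 32
    normalize: bool = True

    def __post_init__(self) -> None:
        if STANDARD_PR.get(self.n_points) != self.radius:
            raise ValueError(
                f"(P, R) = ({self.n_points}, {self.radius}) is not one of "
                f"{sorted(STANDARD_PR.items())}"
            )
        if self.image_size < 1 or self.cell_size < 1:
            raise ValueError("image_size and cell_size must be positive")
        if self.image_size % self.cell_size != 0:
            raise ValueError(
                f"cell_size {self.cell_size} does not divide image_size {self.image_size}"
            )
        if self.cell_size >= self.image_size:
            raise ValueError("cell_size must be strictly smaller than image_size")
        if self.cell_size <= 2 * self.radius:
            raise ValueError(
                f"cell_size {self.cell_size} admits no interior centre at radius {self.radius}"
            )

    @property
    def n_cells(self) -> int:
        return (self.image_size // self.cell_size) ** 2

    @property
    def n_bins(self) -> int:
        return self.n_points + 2

    @property
    def feature_length(self) -> int:
        return self.n_cells * self.n_bins

    def fingerprint(self) -> str:
        """Short id used to bind trained models to their feature geometry."""
        norm = "l1" if self.normalize else "raw"
        return (
            f"lbp{self.n_points}_{self.radius}-img{self.image_size}"
            f"-cell{self.cell_size}-{norm}"
        )


#: The 12 grid configurations explored in the study: every (P, R) with
#: image 256 (cells 8..128), 128 (cells 8..64), 64 (cells 8..32) — here per
#: (P, R) those whose cells admit interior centres.
TABLE_CONFIGS = [
    (image, cell)
    for image in (256, 128, 64)
    for cell in (8, 16, 32, 64, 128)
    if cell < image
]


def feature_length(n_points: int, image_size: int, cell_size: int) -> int:
    """(image_size/cell_size)² cells × (P+2) bins."""
    return (image_size // cell_size) ** 2 * (n_points + 2)


def to_grayscale(img: np.ndarray, weights: tuple = GRAY_WEIGHTS) -> np.ndarray:
    """RGB -> 8-bit grey by luma weighting (BT.601 by default)."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (m, n, 3) RGB image, got shape {img.shape}")
    w = np.asarray(weights, dtype=np.float64)
    gray = img.astype(np.float64) @ w
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def _sample_offsets(n_points: int, radius: float) -> np.ndarray:
    """(P, 2) array of (row, col) offsets; p=0 east, counter-clockwise.

    Image rows grow downward, so counter-clockwise on the page is a
    negative row offset.  The (8, 1) case is the classic 3×3 formulation:
    the eight immediate lattice neighbours, diagonals included, with no
    interpolation.  Larger circles sample at angle 2πp/P and radius R;
    offsets within 1e-9 of an integer are snapped to it.
    """
    if n_points == 8 and radius == 1:
        return np.array(
            [(0, 1), (-1, 1), (-1, 0), (-1, -1),
             (0, -1), (1, -1), (1, 0), (1, 1)],
            dtype=np.float64,
        )
    p = np.arange(n_points)
    theta = 2.0 * np.pi * p / n_points
    offs = np.stack([-radius * np.sin(theta), radius * np.cos(theta)], axis=1)
    snapped = np.round(offs)
    offs[np.abs(offs - snapped) < 1e-9] = snapped[np.abs(offs - snapped) < 1e-9]
    return offs


def circular_neighbors(
    gray: np.ndarray, center: tuple[int, int], n_points: int, radius: float
) -> np.ndarray:
    """Grey values g_0..g_{P-1} around one centre (row, col).

    Bilinear interpolation at non-integer positions.  The centre must be at
    least ceil(radius) pixels from every border.
    """
    gray = np.asarray(gray, dtype=np.float64)
    r, c = center
    margin = int(np.ceil(radius))
    if not (margin <= r < gray.shape[0] - margin and margin <= c < gray.shape[1] - margin):
        raise ValueError(
            f"centre {center} closer than {margin} px to the border of {gray.shape}"
        )
    offs = _sample_offsets(n_points, radius)
    rows = r + offs[:, 0]
    cols = c + offs[:, 1]
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    # zero-weight +1 neighbours of integer offsets stay in bounds
    r1 = np.where(fr > 0, r0 + 1, r0)
    c1 = np.where(fc > 0, c0 + 1, c0)
    return (
        gray[r0, c0] * (1 - fr) * (1 - fc)
        + gray[r0, c1] * (1 - fr) * fc
        + gray[r1, c0] * fr * (1 - fc)
        + gray[r1, c1] * fr * fc
    )


def binary_pattern(g_c: float, neighbors: np.ndarray) -> np.ndarray:
    """Thresholded neighbour comparisons b_p = s(g_p - g_c), ties -> 1."""
    return (np.asarray(neighbors, dtype=np.float64) >= g_c).astype(np.uint8)


def lbp_code(pattern: np.ndarray) -> int:
    """Classic LBP code: sum of b_p · 2^p (b_0 least significant)."""
    bits = np.asarray(pattern)
    return int(bits @ (1 << np.arange(bits.size, dtype=np.int64)))


def uniformity(pattern: np.ndarray) -> int:
    """Circular 0<->1 transition count U, wrap-around pair included."""
    bits = np.asarray(pattern, dtype=np.int8)
    return int(np.abs(bits - np.roll(bits, 1)).sum())


def riu2_code(pattern: np.ndarray) -> int:
    """Rotation-invariant uniform code: ones count if U <= 2, else P+1."""
    bits = np.asarray(pattern)
    if uniformity(bits) <= 2:
        return int(bits.sum())
    return bits.size + 1


def _riu2_code_map(gray: np.ndarray, n_points: int, radius: float) -> np.ndarray:
    """riu2 codes for every valid centre; vectorised over the whole image.

    Returns an (m - 2·margin, n - 2·margin) int array for the interior
    region, margin = ceil(radius).
    """
    gray = np.asarray(gray, dtype=np.float64)
    m, n = gray.shape
    margin = int(np.ceil(radius))
    h, w = m - 2 * margin, n - 2 * margin
    if h < 1 or w < 1:
        raise ValueError(
            f"image {gray.shape} too small for any centre at radius {radius}"
        )
    center = gray[margin : margin + h, margin : margin + w]
    offs = _sample_offsets(n_points, radius)

    ones = np.zeros((h, w), dtype=np.int32)
    transitions = np.zeros((h, w), dtype=np.int32)
    first_bit = prev_bit = None
    for p in range(n_points):
        dr, dc = offs[p]
        r0, c0 = int(np.floor(dr)), int(np.floor(dc))
        fr, fc = dr - r0, dc - c0
        base_r, base_c = margin + r0, margin + c0

        def shifted(dr_i: int, dc_i: int) -> np.ndarray:
            return gray[base_r + dr_i : base_r + dr_i + h, base_c + dc_i : base_c + dc_i + w]

        if fr == 0 and fc == 0:
            plane = shifted(0, 0)
        else:
            plane = (
                shifted(0, 0) * (1 - fr) * (1 - fc)
                + shifted(0, 1) * (1 - fr) * fc
                + shifted(1, 0) * fr * (1 - fc)
                + shifted(1, 1) * fr * fc
            )
        bit = plane >= center
        ones += bit
        if prev_bit is None:
            first_bit = bit
        else:
            transitions += bit ^ prev_bit
        prev_bit = bit
    transitions += prev_bit ^ first_bit

    return np.where(transitions <= 2, ones, n_points + 1)


def riu2_histogram(
    gray: np.ndarray, n_points: int = 8, radius: float = 1, normalize: bool = True
) -> np.ndarray:
    """Histogram of riu2 codes over all interior centres: P+2 bins.

    A border of width ceil(radius) is excluded (its circles would leave the
    image).  L1-normalised by default so images of different sizes compare.
    """
    codes = _riu2_code_map(gray, n_points, radius)
    hist = np.bincount(codes.ravel(), minlength=n_points + 2).astype(np.float64)
    if normalize:
        hist /= hist.sum()
    return hist


def cell_grid_features(gray: np.ndarray, cfg: LBPConfig) -> np.ndarray:
    """Concatenated per-cell riu2 histograms over the cfg grid.

    ``gray`` must already be image_size × image_size; cells are taken in
    raster order (left to right, top to bottom).
    """
    gray = np.asarray(gray)
    if gray.shape != (cfg.image_size, cfg.image_size):
        raise ValueError(
            f"expected a {cfg.image_size}×{cfg.image_size} grey image, got {gray.shape}"
        )
    k = cfg.cell_size
    blocks = []
    for r in range(0, cfg.image_size, k):
        for c in range(0, cfg.image_size, k):
            blocks.append(
                riu2_histogram(
                    gray[r : r + k, c : c + k],
                    cfg.n_points,
                    cfg.radius,
                    normalize=cfg.normalize,
                )
            )
    return np.concatenate(blocks)


def _resize_gray(gray: np.ndarray, size: int, keep_aspect: bool = False) -> np.ndarray:
    """Bilinear resize to size×size; optional aspect-preserving zero-pad."""
    if keep_aspect:
        m, n = gray.shape
        scale = size / max(m, n)
        h, w = max(1, round(m * scale)), max(1, round(n * scale))
        core = resize(gray.astype(np.float64), (h, w), order=1, anti_aliasing=False,
                      preserve_range=True)
        out = np.zeros((size, size), dtype=np.float64)
        out[(size - h) // 2 : (size - h) // 2 + h, (size - w) // 2 : (size - w) // 2 + w] = core
    else:
        out = resize(gray.astype(np.float64), (size, size), order=1,
                     anti_aliasing=False, preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def featurize_patch(
    patch, cfg: LBPConfig, keep_aspect: bool = False
) -> np.ndarray:
    """Full descriptor for one ROI patch.

    RGB (or an :class:`~weedvision.components.ROIPatch`) -> grey -> bilinear
    resize (stretch by default) to image_size² -> per-cell riu2 histograms.
    """
    pixels = getattr(patch, "pixels", patch)
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError("cannot featurize an empty patch")
    gray = to_grayscale(pixels) if pixels.ndim == 3 else pixels
    return cell_grid_features(_resize_gray(gray, cfg.image_size, keep_aspect), cfg)
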