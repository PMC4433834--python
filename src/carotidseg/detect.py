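"""Pre-processing and automatic artery detection.

The artery appears as an approximately circular dark lumen inside a bright
wall.  The detection chain is: contrast-limited adaptive histogram
equalization (CLAHE) to lift the low dynamic range typical of B-mode data,
a median filter against speckle, Sobel edge magnitude, an iterative
adaptive (ISODATA / Ridler–Calvard two-means) threshold to binarize the
edges, and a circle Hough transform over (centre, radius).

CLAHE is implemented here in its standard tiled form (clipped per-tile
histogram, excess redistributed, bilinear interpolation between tile
mappings) so that the one-tile, unclipped limit coincides with plain
histogram equalization — the behaviour the rest of the pipeline is
calibrated against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import hough_circle as _sk_hough_circle

from .errors import DegenerateInputError, DetectionError, ParameterError

#: Default median kernel (speckle suppression).
MEDIAN_KERNEL = 5
#: Minimum normalized Hough score accepted as a detection.
HOUGH_MIN_SCORE = 0.25


@dataclass(frozen=True)
class ClaheParams:
    """``tile_grid`` contextual regions; ``clip_limit`` bounds the slope of
    each tile's transfer function relative to the uniform histogram (the
    OpenCV convention; values > 1, larger = more contrast)."""

    tile_grid: tuple[int, int] = (8, 8)
    clip_limit: float = 2.0

    def validate(self) -> None:
        if min(self.tile_grid) < 1:
            raise ParameterError("tile counts must be >= 1")
        if self.clip_limit <= 1:
            raise ParameterError("clip_limit must be > 1")


@dataclass
class EdgeImage:
    """Sobel magnitude plus its binarization."""

    magnitude: np.ndarray
    binary: np.ndarray
    threshold: float


@dataclass(frozen=True)
class CircleDetection:
    """Artery hypothesis: centre (row, col), radius, accumulator score."""

    row: int
    col: int
    radius: int
    score: float

    @property
    def centre(self) -> tuple[int, int]:
        return (self.row, self.col)


# --------------------------------------------------------------------------
# CLAHE
# --------------------------------------------------------------------------

def clahe(img: np.ndarray, params: ClaheParams = ClaheParams()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of an 8-bit image."""
    params.validate()
    if img.dtype != np.uint8:
        raise ParameterError("clahe expects an 8-bit image")
    tr, tc = params.tile_grid
    rows, cols = img.shape
    th = int(np.ceil(rows / tr))
    tw = int(np.ceil(cols / tc))
    padded = np.pad(img, ((0, tr * th - rows), (0, tc * tw - cols)), mode="edge")

    # Per-tile clipped-histogram CDF mappings (256-level LUTs).
    luts = np.empty((tr, tc, 256))
    npix = th * tw
    clip = params.clip_limit * npix / 256.0
    for i in range(tr):
        for j in range(tc):
            tile = padded[i * th:(i + 1) * th, j * tw:(j + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=256).astype(float)
            excess = np.clip(hist - clip, 0, None).sum()
            hist = np.minimum(hist, clip) + excess / 256.0
            cdf = np.cumsum(hist) / npix
            luts[i, j] = cdf * 255.0

    # Bilinear interpolation between the four surrounding tile mappings.
    yy, xx = np.mgrid[0:rows, 0:cols]
    fy = (yy + 0.5) / th - 0.5
    fx = (xx + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(fy).astype(int), 0, tr - 1)
    x0 = np.clip(np.floor(fx).astype(int), 0, tc - 1)
    y1 = np.clip(y0 + 1, 0, tr - 1)
    x1 = np.clip(x0 + 1, 0, tc - 1)
    wy = np.clip(fy - y0, 0.0, 1.0)
    wx = np.clip(fx - x0, 0.0, 1.0)
    v = img
    out = ((1 - wy) * (1 - wx) * luts[y0, x0, v]
           + (1 - wy) * wx * luts[y0, x1, v]
           + wy * (1 - wx) * luts[y1, x0, v]
           + wy * wx * luts[y1, x1, v])
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# filtering, edges, thresholding
# --------------------------------------------------------------------------

def median_filter(img: np.ndarray, kernel: int = MEDIAN_KERNEL) -> np.ndarray:
    """Square median filter with edge replication; kernel must be odd."""
    if kernel < 3 or kernel % 2 == 0:
        raise ParameterError("kernel must be odd and >= 3")
    return ndimage.median_filter(img, size=kernel, mode="nearest")


def sobel_edges(img: np.ndarray) -> np.ndarray:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) with the standard 3x3 Sobel
    kernels (unnormalized: an interior unit step yields magnitude 4)."""
    f = img.astype(float)
    gx = ndimage.sobel(f, axis=1, mode="reflect")
    gy = ndimage.sobel(f, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def iterative_threshold(img: np.ndarray, shift: float = 0.0,
                        t0: float | None = None,
                        tol: float = 1e-6, max_iter: int = 500) -> float:
    """ISODATA (Ridler–Calvard) two-means threshold plus an optional shift.

    Starting from the global mean (or ``t0``), T is replaced by the
    midpoint of the means of the two classes ``< T`` and ``>= T`` until it
    stops moving.  The pipeline binarizes with ``value >= T + shift``; the
    segmentation stage uses ``shift=10`` to bias the boundary towards
    brighter tissue.
    """
    x = np.asarray(img, dtype=float).ravel()
    if x.max() == x.min():
        raise DegenerateInputError("constant image has no threshold")
    if t0 is None:
        t = x.mean()
    else:
        if not x.min() < t0 < x.max():
            raise ParameterError("t0 must lie strictly inside the intensity range")
        t = float(t0)
    for _ in range(max_iter):
        lo = x[x < t]
        hi = x[x >= t]
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    return float(t + shift)


def binarize(img: np.ndarray, threshold: float) -> np.ndarray:
    """0/255 raster: ON where value >= threshold."""
    return np.where(np.asarray(img, dtype=float) >= threshold, 255, 0).astype(np.uint8)


def edge_image(img: np.ndarray, threshold_shift: float = 0.0) -> EdgeImage:
    """Sobel magnitude binarized at its iterative adaptive threshold."""
    mag = sobel_edges(img)
    t = iterative_threshold(mag, shift=threshold_shift)
    return EdgeImage(magnitude=mag, binary=binarize(mag, t), threshold=t)


# --------------------------------------------------------------------------
# Hough circle detection
# --------------------------------------------------------------------------

def hough_circle(edges: np.ndarray, r_min: int, r_max: int, n_best: int = 1,
                 min_score: float = HOUGH_MIN_SCORE,
                 min_distance: int | None = None) -> list[CircleDetection]:
    """Top circles of the (centre, radius) Hough accumulator.

    Scores are normalized by circumference (1.0 = fully voted circle).
    Peaks are taken greedily with non-max suppression of ``min_distance``
    (default ``r_min``) around each accepted centre; score ties (within a
    small tolerance, so concentric fully-voted circles compare equal
    despite float jitter) break to the smallest row, then column, then
    radius — for an artery the lumen boundary, not the outer wall.  Raises
    :class:`DetectionError` (reason ``"hough_no_peak"``) when nothing
    reaches ``min_score``.
    """
    if r_min >= r_max:
        raise ParameterError("r_min must be < r_max")
    on = np.asarray(edges) > 0
    if not on.any():
        raise DetectionError("hough_no_peak", "empty edge image")
    radii = np.arange(r_min, r_max + 1)
    acc = _sk_hough_circle(on, radii)  # (n_radii, rows, cols), normalized
    if min_distance is None:
        min_distance = r_min
    found: list[CircleDetection] = []
    acc = acc.copy()
    for _ in range(n_best):
        best = float(acc.max())
        if best < min_score:
            break
        ri, yy, xx = np.nonzero(acc >= best - 1e-6)
        order = np.lexsort((radii[ri], xx, yy))  # row, then col, then radius
        k = order[0]
        y, x, r = int(yy[k]), int(xx[k]), int(radii[ri[k]])
        found.append(CircleDetection(row=y, col=x, radius=r, score=best))
        y0, y1 = max(0, y - min_distance), y + min_distance + 1
        x0, x1 = max(0, x - min_distance), x + min_distance + 1
        acc[:, y0:y1, x0:x1] = -1.0
    if not found:
        raise DetectionError("hough_no_peak", "no circle above the vote threshold")
    return found


def crop_around(img: np.ndarray, centre: tuple[int, int],
                half_size: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Square half-open crop ``[r-h, r+h) x [c-h, c+h)`` clamped to the
    image; returns the crop and its (row, col) offset into the full frame."""
    if half_size <= 0:
        raise ParameterError("half_size must be positive")
    r, c = int(centre[0]), int(centre[1])
    rows, cols = img.shape[:2]
    if not (0 <= r < rows and 0 <= c < cols):
        raise ParameterError("centre outside image")
    r0, r1 = max(0, r - half_size), min(rows, r + half_size)
    c0, c1 = max(0, c - half_size), min(cols, c + half_size)
    return img[r0:r1, c0:c1], (r0, c0)


def detect_artery(img: np.ndarray, clahe_params: ClaheParams = ClaheParams(),
                  median_kernel: int = MEDIAN_KERNEL,
                  r_min: int | None = None, r_max: int | None = None,
                  min_score: float = HOUGH_MIN_SCORE) -> CircleDetection:
    """Full detection chain: CLAHE → median → Sobel → iterative threshold →
    circle Hough.  Radius search defaults to [size/10, size/3]."""
    size = min(img.shape[:2])
    if r_min is None:
        r_min = max(5, size // 10)
    if r_max is None:
        r_max = size // 3
    enhanced = clahe(img, clahe_params)
    smooth = median_filter(enhanced, median_kernel)
    edges = edge_image(smooth)
    return hough_circle(edges.binary, r_min, r_max, n_best=1,
                        min_score=min_score)[0]
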