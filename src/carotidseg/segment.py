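"""Shadow-side reconstruction, GVF active-contour segmentation, plaque area.

Calcified plaque at the near wall casts an acoustic shadow that erases a
sector of the artery side.  Left as-is, the gap lets a parametric active
contour leak out of the lumen.  The repair works in polar coordinates
about the detected circle centre: for every angle the minimum distance to
an edge pixel is recorded; angles whose minimum exceeds ``t = r + 4`` (or
that have no edge at all) receive a synthetic edge pixel at distance
``r`` — both constants established for this pipeline, with ``r`` the Hough
radius in pixels.

Angular binning uses ray semantics: an edge pixel is a unit square, so it
covers the interval of angles spanned by its corners; a bin records the
minimum distance over the pixels whose footprint covers it.  This is what
"the minimum distance for the given angle" means for a raster — a ray cast
at the bin angle stops at the first pixel it enters — and it keeps the
reconstruction contract (every bin covered, added pixels within half a
pixel of radius r) satisfiable at clinical radii, which pointwise
`floor(atan2)` binning is not.

Segmentation evolves a closed snake (tension ``alpha``, rigidity ``beta``,
semi-implicit step ``gamma``) under a gradient-vector-flow (GVF) external
force computed from the (reconstructed) edge map.  The force is sampled
bilinearly and unit-normalized, the standard way to give a GVF snake a
capture range independent of distance from the edge.  Plaque area is the
difference between the faultless artery outline area and the converged
inner contour area (shoelace formula, scaled to mm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as _cc_label
from skimage.segmentation import find_boundaries

from .detect import (MEDIAN_KERNEL, binarize, crop_around, iterative_threshold,
                     median_filter)
from .errors import ParameterError

#: Acceptance bound offset: an angle is "completed" if its minimum edge
#: distance is within r + T_OFFSET.
T_OFFSET = 4
#: Threshold shift applied before segmentation (towards brighter tissue).
SEGMENT_THRESHOLD_SHIFT = 10.0
#: Snake / GVF defaults.
GVF_MU = 0.2
GVF_ITERATIONS = 80
SNAKE_ALPHA = 0.1
SNAKE_BETA = 0.05
SNAKE_GAMMA = 1.0
SNAKE_ITERATIONS = 400
SNAKE_TOL = 0.1
SNAKE_VERTICES = 100
INIT_RADIUS_FACTOR = 1.2


@dataclass
class PolarEdgeMap:
    """Per-angle minimum edge distance about ``origin``.

    ``distances[b]`` is the minimum distance (px) over ON pixels whose
    angular footprint covers bin ``b`` (bins of ``angular_step`` degrees,
    circular at 360°); NaN where no pixel covers the bin.
    """

    origin: tuple[float, float]
    distances: np.ndarray
    angular_step: float = 1.0

    @property
    def n_bins(self) -> int:
        return self.distances.size

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.distances)


@dataclass(frozen=True)
class ReconstructionParams:
    """``t_max``: largest accepted minimum distance; ``fill_radius``: where
    synthetic pixels are added for incomplete angles."""

    t_max: float
    fill_radius: float

    def validate(self) -> None:
        if not self.t_max > self.fill_radius >= 1:
            raise ParameterError("need t_max > fill_radius >= 1")

    @classmethod
    def for_radius(cls, r: float) -> "ReconstructionParams":
        return cls(t_max=r + T_OFFSET, fill_radius=r)


@dataclass
class ReconstructionResult:
    edges: np.ndarray               # input ON pixels plus the added ones
    added: np.ndarray               # (k, 2) integer (row, col) of added pixels
    params: ReconstructionParams


@dataclass
class GvfField:
    """GVF force components: ``u`` along columns, ``v`` along rows."""

    u: np.ndarray
    v: np.ndarray
    mu: float
    iterations: int


@dataclass
class ContourPolygon:
    """Closed contour: ordered sub-pixel (row, col) vertices, implicit
    closure (first vertex is not repeated)."""

    vertices: np.ndarray
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ParameterError("vertices must be an (n, 2) array")
        if len(np.unique(np.round(self.vertices, 9), axis=0)) < 3:
            raise ParameterError("polygon needs >= 3 distinct vertices")


@dataclass
class PlaqueMeasurement:
    outline_area_mm2: float
    contour_area_mm2: float
    plaque_area_mm2: float
    mm_per_px: float
    clamped: bool = False


# --------------------------------------------------------------------------
# polar edge map and reconstruction
# --------------------------------------------------------------------------

def _footprint_interval(dy: float, dx: float) -> tuple[float, float]:
    """Angular interval [lo, hi] (deg) covered by the unit-square footprint
    of a pixel whose centre is at offset (dy, dx) from the origin.  When the
    interval wraps 0°, hi < lo + 360 with hi taken modulo 360 by callers;
    a pixel containing the origin covers everything (returns (0, 360))."""
    if max(abs(dy), abs(dx)) <= 0.5:
        return 0.0, 360.0
    angs = np.array([np.degrees(np.arctan2(dy + a, dx + b)) % 360.0
                     for a in (-0.5, 0.5) for b in (-0.5, 0.5)])
    lo, hi = angs.min(), angs.max()
    if hi - lo > 180.0:  # wraps the 0/360 seam
        above = angs[angs >= 180.0].min()
        below = angs[angs < 180.0].max()
        return above, below + 360.0
    return lo, hi


def _covered_bins(lo: float, hi: float, step: float, n_bins: int) -> np.ndarray:
    """Bins whose [b*step, (b+1)*step) interval intersects [lo, hi]."""
    if hi - lo >= 360.0:
        return np.arange(n_bins)
    b0 = int(np.floor(lo / step))
    b1 = int(np.floor(hi / step))
    return np.arange(b0, b1 + 1) % n_bins


def to_polar_min(edges: np.ndarray, centre: tuple[float, float],
                 angular_step: float = 1.0) -> PolarEdgeMap:
    """Polar map of an edge raster: per-bin minimum distance from centre."""
    rows, cols = edges.shape
    cr, cc = centre
    if not (0 <= cr < rows and 0 <= cc < cols):
        raise ParameterError("centre outside image")
    if not (0 < angular_step <= 360) or 360.0 % angular_step != 0:
        raise ParameterError("angular_step must divide 360")
    n_bins = int(round(360.0 / angular_step))
    dist = np.full(n_bins, np.nan)
    ys, xs = np.nonzero(np.asarray(edges) > 0)
    for y, x in zip(ys.tolist(), xs.tolist()):
        dy, dx = y - cr, x - cc
        d = float(np.hypot(dy, dx))
        lo, hi = _footprint_interval(dy, dx)
        for b in _covered_bins(lo, hi, angular_step, n_bins):
            if np.isnan(dist[b]) or d < dist[b]:
                dist[b] = d
    return PolarEdgeMap(origin=(cr, cc), distances=dist, angular_step=angular_step)


def _fill_pixel(cr: float, cc: float, r: float, bin_index: int,
                step: float) -> tuple[int, int]:
    """Integer pixel representing radius ``r`` at the centre angle of a bin:
    among the four lattice pixels around the exact polar point, those whose
    footprint covers the bin, the one with the smallest radial error (ties
    to the smaller (row, col)).  The radial error of this choice stays
    below half a pixel for clinical radii."""
    theta = np.radians((bin_index + 0.5) * step)
    ey, ex = cr + r * np.sin(theta), cc + r * np.cos(theta)
    bin_lo, bin_hi = bin_index * step, (bin_index + 1) * step
    best: tuple[float, int, int] | None = None
    fallback: tuple[float, int, int] | None = None
    for py in (int(np.floor(ey)), int(np.floor(ey)) + 1):
        for px in (int(np.floor(ex)), int(np.floor(ex)) + 1):
            d = float(np.hypot(py - cr, px - cc))
            err = abs(d - r)
            key = (err, py, px)
            lo, hi = _footprint_interval(py - cr, px - cc)
            # footprint may extend past 360; test overlap in both windings
            covers = any(not (hi <= b_lo or lo >= b_hi)
                         for b_lo, b_hi in ((bin_lo, bin_hi),
                                            (bin_lo + 360.0, bin_hi + 360.0)))
            if covers and (best is None or key < best):
                best = key
            if fallback is None or key < fallback:
                fallback = key
    _, py, px = best if best is not None else fallback
    return py, px


def reconstruct_side(edges: np.ndarray, polar: PolarEdgeMap,
                     r: float) -> ReconstructionResult:
    """Complete the artery side: every bin that is absent or whose minimum
    distance exceeds ``t = r + 4`` gains one ON pixel at distance ``r``
    along the bin's angle; original ON pixels are always preserved."""
    if r <= 0:
        raise ParameterError("radius must be positive")
    params = ReconstructionParams.for_radius(r)
    params.validate()
    out = np.where(np.asarray(edges) > 0, 255, 0).astype(np.uint8)
    cr, cc = polar.origin
    rows, cols = out.shape
    added: list[tuple[int, int]] = []
    for b in range(polar.n_bins):
        d = polar.distances[b]
        if np.isnan(d) or d > params.t_max:
            py, px = _fill_pixel(cr, cc, params.fill_radius, b, polar.angular_step)
            py = int(np.clip(py, 0, rows - 1))
            px = int(np.clip(px, 0, cols - 1))
            if out[py, px] == 0:
                added.append((py, px))
            out[py, px] = 255
    return ReconstructionResult(
        edges=out,
        added=np.asarray(added, dtype=int).reshape(-1, 2),
        params=params,
    )


# --------------------------------------------------------------------------
# gradient vector flow
# --------------------------------------------------------------------------

def gvf(edge_map: np.ndarray, mu: float = GVF_MU,
        iterations: int = GVF_ITERATIONS, dt: float = 1.0) -> GvfField:
    """Gradient vector flow of an edge map by explicit diffusion.

    Minimizes ``∫ mu |∇u|² + |∇v|² + |∇f|² (|u - f_x|² + |v - f_y|²)`` by
    time-stepping ``u_t = mu ∇²u - |∇f|² (u - f_x)`` (same for v) from the
    raw gradient; ``iterations=0`` returns that initialization.  The step
    must satisfy the diffusion stability bound ``4 mu dt <= 1``.
    """
    if mu <= 0:
        raise ParameterError("mu must be positive")
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    if 4.0 * mu * dt > 1.0 + 1e-12:
        raise ParameterError("unstable step: require 4 * mu * dt <= 1")
    f = np.asarray(edge_map, dtype=float)
    if f.max() > 0:
        f = f / f.max()
    fy, fx = np.gradient(f)
    b = fx * fx + fy * fy
    u, v = fx.copy(), fy.copy()
    for _ in range(iterations):
        u += dt * (mu * ndimage.laplace(u) - b * (u - fx))
        v += dt * (mu * ndimage.laplace(v) - b * (v - fy))
    return GvfField(u=u, v=v, mu=mu, iterations=iterations)


# --------------------------------------------------------------------------
# snake evolution
# --------------------------------------------------------------------------

def circle_polygon(centre: tuple[float, float], radius: float,
                   n_vertices: int = SNAKE_VERTICES) -> ContourPolygon:
    """Closed circular polygon, the standard snake initialization."""
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    cr, cc = centre
    verts = np.stack([cr + radius * np.sin(th), cc + radius * np.cos(th)], axis=1)
    return ContourPolygon(vertices=verts)


def snake_evolve(init: ContourPolygon, field: GvfField,
                 alpha: float = SNAKE_ALPHA, beta: float = SNAKE_BETA,
                 gamma: float = SNAKE_GAMMA, iterations: int = SNAKE_ITERATIONS,
                 convergence_tol: float = SNAKE_TOL,
                 normalize_force: bool = True) -> ContourPolygon:
    """Semi-implicit evolution of a closed parametric active contour.

    Internal energy (tension ``alpha``, rigidity ``beta``) is solved
    implicitly through the cyclic pentadiagonal system ``(I - gamma A)``;
    the external GVF force is sampled bilinearly at the vertices each step
    and unit-normalized by default so the capture range does not depend on
    the distance to the edge.  Stops when the largest vertex displacement
    falls below ``convergence_tol`` or at the iteration cap.
    """
    if min(alpha, beta, gamma, convergence_tol) <= 0 or iterations < 1:
        raise ParameterError("snake parameters must be positive")
    x = np.asarray(init.vertices, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 8:
        raise ParameterError("initial contour needs >= 8 (row, col) vertices")
    n = x.shape[0]
    eye = np.eye(n)
    d2 = np.roll(eye, -1, axis=0) - 2 * eye + np.roll(eye, 1, axis=0)
    a = alpha * d2 - beta * (d2 @ d2)
    try:
        step_matrix = np.linalg.inv(eye - gamma * a)
    except np.linalg.LinAlgError as exc:
        raise ParameterError("singular internal-energy system") from exc

    u, v = field.u, field.v
    if normalize_force:
        mag = np.hypot(u, v)
        safe = np.maximum(mag, 1e-12)
        u = np.where(mag > 1e-10, u / safe, 0.0)
        v = np.where(mag > 1e-10, v / safe, 0.0)
    rows, cols = u.shape
    x = x.copy()
    for _ in range(iterations):
        fr = ndimage.map_coordinates(v, x.T, order=1, mode="nearest")
        fc = ndimage.map_coordinates(u, x.T, order=1, mode="nearest")
        x_new = step_matrix @ (x + gamma * np.stack([fr, fc], axis=1))
        x_new[:, 0] = np.clip(x_new[:, 0], 0, rows - 1)
        x_new[:, 1] = np.clip(x_new[:, 1], 0, cols - 1)
        disp = float(np.abs(x_new - x).max())
        x = x_new
        if disp < convergence_tol:
            break
    return ContourPolygon(vertices=x, params=dict(
        alpha=alpha, beta=beta, gamma=gamma, iterations=iterations,
        convergence_tol=convergence_tol))


# --------------------------------------------------------------------------
# areas
# --------------------------------------------------------------------------

def polygon_area(poly: ContourPolygon, mm_per_px: float = 1.0) -> float:
    """Absolute shoelace area scaled by ``mm_per_px**2``."""
    poly.validate()
    if mm_per_px <= 0:
        raise ParameterError("mm_per_px must be positive")
    y = poly.vertices[:, 0]
    x = poly.vertices[:, 1]
    area_px = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area_px * mm_per_px ** 2)


def plaque_area(outline: ContourPolygon, contour: ContourPolygon,
                mm_per_px: float) -> PlaqueMeasurement:
    """Plaque burden as the difference of two object areas: the faultless
    artery outline minus the segmented inner contour.  A negative
    difference (contour outside the outline) clamps to 0 with a flag."""
    a_out = polygon_area(outline, mm_per_px)
    a_in = polygon_area(contour, mm_per_px)
    diff = a_out - a_in
    clamped = diff < 0
    return PlaqueMeasurement(outline_area_mm2=a_out, contour_area_mm2=a_in,
                             plaque_area_mm2=max(diff, 0.0), mm_per_px=mm_per_px,
                             clamped=bool(clamped))


# --------------------------------------------------------------------------
# whole segmentation stage
# --------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    contour: ContourPolygon          # full-frame coordinates
    measurement: PlaqueMeasurement
    circle: tuple[int, int, int]     # (row, col, radius) used
    outline_kind: str                # "circle" (automatic) or "user"
    reconstruction_added: int


def _inner_edge_band(binary_wall: np.ndarray,
                     centre: tuple[int, int]) -> np.ndarray:
    """Two-pixel boundary band of the lumen-connected component.

    The thresholded crop is a bright wall ring around the dark lumen; the
    inner artery side is the boundary of the OFF component containing the
    centre.  The symmetric (thick) band keeps the GVF equilibrium on the
    true boundary instead of biasing it half a pixel to either side.
    Residual speckle flips dark pin-holes into the wall through which the
    lumen component would leak outward, so the wall is closed with a 3x3
    structuring element first — a symmetric closing does not move a smooth
    boundary.
    """
    closed = ndimage.binary_closing(binary_wall > 0, structure=np.ones((3, 3)),
                                    border_value=0)
    off = ~closed
    labels = _cc_label(off, connectivity=1)
    lumen_label = labels[int(round(centre[0])), int(round(centre[1]))]
    if lumen_label == 0:  # centre fell on the wall: no lumen component
        return np.zeros_like(binary_wall)
    lumen = labels == lumen_label
    band = find_boundaries(lumen, mode="thick")
    return np.where(band, 255, 0).astype(np.uint8)


def segment_artery(image: np.ndarray, circle: tuple[int, int, int],
                   mm_per_px: float,
                   outline: ContourPolygon | None = None,
                   median_kernel: int = MEDIAN_KERNEL,
                   threshold_shift: float = SEGMENT_THRESHOLD_SHIFT,
                   gvf_mu: float = GVF_MU, gvf_iterations: int = GVF_ITERATIONS,
                   alpha: float = SNAKE_ALPHA, beta: float = SNAKE_BETA,
                   gamma: float = SNAKE_GAMMA,
                   snake_iterations: int = SNAKE_ITERATIONS,
                   convergence_tol: float = SNAKE_TOL) -> SegmentationResult:
    """Inner-side segmentation and plaque measurement around a known circle.

    ``circle`` is (row, col, radius) — from the Hough detector (automatic)
    or marked by the user (semi-automatic).  ``outline`` is the faultless
    artery outline used as the plaque reference; by default the circle
    itself.  Steps: median filter → crop around the centre → iterative
    threshold shifted by +10 → inner-boundary edge band → polar
    reconstruction of shadowed angles → GVF → snake from a circle of
    1.2 r → area difference.
    """
    row, col, r = int(circle[0]), int(circle[1]), int(circle[2])
    if r <= 0:
        raise ParameterError("radius must be positive")
    smooth = median_filter(image, median_kernel)
    half = int(round(2.0 * r))
    crop, (off_r, off_c) = crop_around(smooth, (row, col), half)
    c_local = (row - off_r, col - off_c)
    t = iterative_threshold(crop, shift=threshold_shift)
    wall = binarize(crop, t)
    edges = _inner_edge_band(wall, c_local)
    polar = to_polar_min(edges, c_local)
    recon = reconstruct_side(edges, polar, r)
    # The binary band selects the inner artery side, but its exact position
    # inherits a small outward erosion of the thresholded wall under
    # speckle; weighting by the gradient magnitude of the log-compressed
    # intensity puts the GVF equilibrium back on the step itself.  The log
    # domain makes multiplicative speckle additive with equal variance on
    # both sides of the step, so the magnitude ridge stays centred.
    # Reconstructed (synthetic) pixels carry full weight.
    from .detect import sobel_edges as _sobel
    mag = _sobel(np.log1p(crop.astype(float)))
    band = ndimage.binary_dilation(recon.edges > 0, np.ones((3, 3)))
    gvf_input = np.where(band, mag, 0.0)
    if recon.added.size:
        gvf_input[recon.added[:, 0], recon.added[:, 1]] = max(gvf_input.max(), 1.0)
    field = gvf(gvf_input, mu=gvf_mu, iterations=gvf_iterations)
    init = circle_polygon(c_local, INIT_RADIUS_FACTOR * r)
    snake = snake_evolve(init, field, alpha=alpha, beta=beta, gamma=gamma,
                         iterations=snake_iterations,
                         convergence_tol=convergence_tol)
    contour = ContourPolygon(
        vertices=snake.vertices + np.array([off_r, off_c], dtype=float),
        params=snake.params)
    if outline is None:
        outline_poly = circle_polygon((row, col), r)
        kind = "circle"
    else:
        outline_poly = outline
        kind = "user"
    measurement = plaque_area(outline_poly, contour, mm_per_px)
    return SegmentationResult(contour=contour, measurement=measurement,
                              circle=(row, col, r), outline_kind=kind,
                              reconstruction_added=int(recon.added.shape[0]))
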