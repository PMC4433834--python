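"""Synthetic phantoms with analytic ground truth.

Two generators cover every input the pipeline consumes:

* :func:`make_artery_phantom` — a transverse B-mode-like view of a carotid
  artery: a dark lumen disc inside a bright wall annulus on a mid-grey
  background, optionally with a hyperechoic plaque bump protruding into the
  lumen and an acoustic-shadow sector in which the wall edge is lost.
  Speckle is emulated as multiplicative log-normal noise, a standard proxy
  for the granular interference pattern of coherent ultrasound.

* :func:`make_ecg_video` — a frame sequence carrying a monitor-style
  scrolling ECG strip chart inside a rectangular sub-region, with a moving
  redraw gap ahead of the "pen", optional opaque letter glyph occluding the
  chart, and QRS complexes at known global strip columns.

Both are deterministic for a fixed spec + seed, and both return an analytic
ground-truth record so downstream stages can be scored without any real
ultrasound data.  Neither attempts physical realism (no point-spread
function, no depth attenuation).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError

# Angular half-width of the raised-cosine plaque bump profile.
PLAQUE_HALFWIDTH_DEG = 45.0
# QRS glyph: triangular spike, 7 columns wide (within the <= 10-column contract).
QRS_WIDTH = 7
# Columns a variance window reaches past a beat; used as a placement margin.
VARIANCE_GUARD = 6
# Raster intensities of the rendered strip chart.
TRACE_INTENSITY = 255
CHART_BACKGROUND = 20
LETTER_INTENSITY = 200


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a circular artery cross-section phantom.

    ``plaque_bump`` is ``(angle_deg, depth_px)``: a raised-cosine intrusion of
    the wall into the lumen, centred at ``angle_deg`` with half-width
    :data:`PLAQUE_HALFWIDTH_DEG`.  ``shadow_arc`` is ``(start_deg, end_deg)``
    counter-clockwise (in image coordinates: angle from +col axis towards
    +row); inside the sector all edge contrast beyond the lumen is replaced
    by a gentle radial ramp, emulating the information loss under an
    acoustic shadow.
    """

    image_size: int = 128
    centre: tuple[int, int] = (64, 64)
    radius: int = 35
    lumen_intensity: int = 25
    wall_intensity: int = 170
    background_intensity: int = 80
    wall_px: int = 8
    speckle_sigma: float = 0.0
    shadow_arc: tuple[float, float] | None = None
    plaque_bump: tuple[float, float] | None = None
    mm_per_px: float = 0.1
    seed: int = 0

    _MARGIN = 4

    def validate(self) -> None:
        if self.image_size < 16:
            raise ParameterError("image_size must be >= 16")
        r0, c0 = self.centre
        if not (0 <= r0 < self.image_size and 0 <= c0 < self.image_size):
            raise ParameterError("centre must lie inside the image")
        if self.radius + self.wall_px >= self.image_size / 2 - self._MARGIN:
            raise ParameterError("radius too large for the image size")
        if self.radius < 8:
            raise ParameterError("radius must be >= 8 px")
        for name in ("lumen_intensity", "wall_intensity", "background_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ParameterError(f"{name} must be in [0, 255]")
        if self.speckle_sigma < 0:
            raise ParameterError("speckle_sigma must be >= 0")
        if self.shadow_arc is not None:
            a, b = self.shadow_arc
            if not (0 <= a < 360 and 0 <= b < 360):
                raise ParameterError("shadow arc angles must be in [0, 360)")
        if self.plaque_bump is not None:
            _, depth = self.plaque_bump
            if not (0 < depth < self.radius):
                raise ParameterError("plaque depth must be in (0, radius)")
        if self.mm_per_px <= 0:
            raise ParameterError("mm_per_px must be positive")


@dataclass(frozen=True)
class EcgVideoSpec:
    """Parameters of a synthetic ECG strip-chart video.

    The chart emulates a sweep monitor: each frame the pen advances
    ``scroll_speed`` columns and an erased redraw gap of ``gap_width``
    columns sits just ahead of it.  ``ecg_roi`` is ``(row0, col0, row1,
    col1)``, half-open.  The sweep width (ROI width) must be a multiple of
    ``scroll_speed`` so the gap advances through a fixed cycle of positions.
    ``qrs_columns_global`` are positions on the *global* (stitched) strip,
    which has ``n_frames * scroll_speed`` columns.
    """

    n_frames: int = 20
    frame_size: tuple[int, int] = (120, 200)
    ecg_roi: tuple[int, int, int, int] = (80, 10, 110, 190)
    qrs_columns_global: tuple[int, ...] = ()
    scroll_speed: int = 10
    gap_width: int = 6
    letter_position: int | None = None
    letter_width: int = 8
    baseline_noise: float = 3.0
    baseline_wiggle_px: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.frame_size
        r0, c0, r1, c1 = self.ecg_roi
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise ParameterError("ecg_roi outside frame or empty")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.gap_width < 1:
            raise ParameterError("gap_width must be >= 1")
        if self.scroll_speed < 1:
            raise ParameterError("scroll_speed must be >= 1")
        w = c1 - c0
        if w % self.scroll_speed != 0:
            raise ParameterError("ROI width must be a multiple of scroll_speed")
        if self.gap_width > self.scroll_speed:
            raise ParameterError("gap_width must not exceed scroll_speed")
        if self.letter_position is not None:
            if not (0 <= self.letter_position <= w - self.letter_width):
                raise ParameterError("letter must fit inside the ROI")
        q = np.asarray(self.qrs_columns_global, dtype=int)
        if q.size and not np.all(np.diff(q) > 0):
            raise ParameterError("qrs columns must be strictly increasing")
        total = self.n_frames * self.scroll_speed
        if q.size and (q.min() < QRS_WIDTH or q.max() >= total - QRS_WIDTH):
            raise ParameterError("qrs columns must lie inside the strip with margin")


def spec_from_yaml(path: str | Path, kind: str = "artery") -> PhantomSpec | EcgVideoSpec:
    """Load a :class:`PhantomSpec` (``kind='artery'``) or :class:`EcgVideoSpec`
    (``kind='ecg'``) from a YAML mapping; tuples may be given as lists."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cls = PhantomSpec if kind == "artery" else EcgVideoSpec
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise ParameterError(f"unknown spec keys: {sorted(unknown)}")
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    spec = cls(**coerced)
    spec.validate()
    return spec


# --------------------------------------------------------------------------
# artery phantom
# --------------------------------------------------------------------------

@dataclass
class ArteryGroundTruth:
    centre: tuple[int, int]
    radius: int
    lumen_polygon: np.ndarray        # (360, 2) sub-pixel (row, col) vertices
    plaque_area_mm2: float
    plaque_mask: np.ndarray          # analytic bump-region mask
    shadow_arc: tuple[float, float] | None


def _bump_depth(theta_deg: np.ndarray, bump: tuple[float, float] | None) -> np.ndarray:
    """Raised-cosine radial intrusion depth as a function of angle."""
    if bump is None:
        return np.zeros_like(theta_deg, dtype=float)
    angle, depth = bump
    delta = (theta_deg - angle + 180.0) % 360.0 - 180.0
    out = np.zeros_like(theta_deg, dtype=float)
    inside = np.abs(delta) < PLAQUE_HALFWIDTH_DEG
    out[inside] = depth * 0.5 * (1.0 + np.cos(np.pi * delta[inside] / PLAQUE_HALFWIDTH_DEG))
    return out


def _in_arc(theta_deg: np.ndarray, arc: tuple[float, float]) -> np.ndarray:
    start, end = arc
    return (theta_deg - start) % 360.0 <= (end - start) % 360.0


def make_artery_phantom(spec: PhantomSpec) -> tuple[np.ndarray, ArteryGroundTruth]:
    """Render the artery phantom and its analytic ground truth.

    The lumen boundary sits at radius ``rho(theta) = radius - bump(theta)``;
    the plaque ground-truth area is the pixel count of the analytic region
    between ``rho`` and the faultless circle, scaled by ``mm_per_px**2``.
    """
    spec.validate()
    n = spec.image_size
    cr, cc = spec.centre
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dy, dx = yy - cr, xx - cc
    dist = np.hypot(dy, dx)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0

    rho = spec.radius - _bump_depth(theta, spec.plaque_bump)
    img = np.full((n, n), float(spec.background_intensity))
    img[dist < spec.radius + spec.wall_px] = spec.wall_intensity
    img[dist < rho] = spec.lumen_intensity

    if spec.shadow_arc is not None:
        sector = _in_arc(theta, spec.shadow_arc) & (dist >= rho)
        # Gentle radial ramp: removes the wall edge without creating a new one.
        span = max(n / 2.0, 1.0)
        t = np.clip((dist - rho) / span, 0.0, 1.0)
        shadow_val = spec.lumen_intensity + t * (0.5 * spec.background_intensity
                                                 - spec.lumen_intensity)
        img[sector] = shadow_val[sector]

    if spec.speckle_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noise = np.exp(rng.normal(0.0, spec.speckle_sigma, size=img.shape))
        img = img * noise / np.exp(spec.speckle_sigma ** 2 / 2.0)

    frame = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    ang = np.arange(360, dtype=float)
    rr = spec.radius - _bump_depth(ang, spec.plaque_bump)
    poly = np.stack([cr + rr * np.sin(np.radians(ang)),
                     cc + rr * np.cos(np.radians(ang))], axis=1)
    plaque_mask = (dist >= rho) & (dist < spec.radius) & \
        (_bump_depth(theta, spec.plaque_bump) > 0)
    area_mm2 = float(plaque_mask.sum()) * spec.mm_per_px ** 2
    gt = ArteryGroundTruth(centre=spec.centre, radius=spec.radius,
                           lumen_polygon=poly, plaque_area_mm2=area_mm2,
                           plaque_mask=plaque_mask, shadow_arc=spec.shadow_arc)
    return frame, gt


# --------------------------------------------------------------------------
# ECG strip-chart video
# --------------------------------------------------------------------------

@dataclass
class EcgGroundTruth:
    qrs_columns_global: np.ndarray     # strictly increasing strip columns
    column_to_frame: np.ndarray        # global column -> frame that drew it
    strip_length: int
    gap_start_per_frame: np.ndarray    # on-screen gap start column, per frame
    hidden_gap_frames: np.ndarray      # frames whose gap is fully letter-covered
    letter_columns_global: np.ndarray  # global columns occluded by the letter


def global_trace(spec: EcgVideoSpec, pre_roll: int = 0) -> np.ndarray:
    """Ground-truth trace ordinate (ROI row, float) per global strip column.

    ``pre_roll`` prepends that many columns of plain baseline before column
    0: the monitor is already full of (QRS-free) trace when recording
    starts, as on a live sweep display.
    """
    h = spec.ecg_roi[2] - spec.ecg_roi[0]
    total = spec.n_frames * spec.scroll_speed
    t = np.arange(-pre_roll, total, dtype=float)
    # Baseline on the mid-row, which is also the centroid of the full-height
    # letter glyph: an occluded->trace transition then steps only by the wiggle.
    base = 0.5 * (h - 1) + spec.baseline_wiggle_px * np.sin(2 * np.pi * t / 60.0)
    amp = 0.30 * h
    half = QRS_WIDTH // 2
    for q in spec.qrs_columns_global:
        for i in range(-half, half + 1):
            c = q + i + pre_roll
            if 0 <= c < total + pre_roll:
                base[c] -= amp * (1.0 - abs(i) / (half + 1.0))
    return np.clip(np.rint(base), 1, h - 2)


def make_ecg_video(spec: EcgVideoSpec) -> tuple[list[np.ndarray], EcgGroundTruth]:
    """Render the frame sequence and ground truth of the scrolling chart.

    Sweep model: after frame ``k`` the pen has drawn global columns
    ``[0, (k+1)*scroll_speed)``; on-screen column ``j`` shows the most recent
    global column congruent to ``j`` modulo the sweep width, except for the
    erased gap of ``gap_width`` columns starting at the pen position.
    """
    spec.validate()
    rows, cols = spec.frame_size
    r0, c0, r1, c1 = spec.ecg_roi
    h, w = r1 - r0, c1 - c0
    s = spec.scroll_speed
    total = spec.n_frames * s
    trace = global_trace(spec, pre_roll=w)  # index with [t + w]
    rng = np.random.default_rng(spec.seed)

    frames: list[np.ndarray] = []
    gap_starts = np.empty(spec.n_frames, dtype=int)
    hidden: list[int] = []
    for k in range(spec.n_frames):
        pen = (k + 1) * s
        p = pen % w
        frame = np.clip(np.rint(
            40.0 + rng.normal(0.0, spec.baseline_noise, size=(rows, cols))),
            0, 255).astype(np.uint8)
        roi = np.clip(np.rint(
            CHART_BACKGROUND + rng.normal(0.0, spec.baseline_noise, size=(h, w))),
            0, 69).astype(np.uint8)  # keep chart background below the 72 threshold
        gap_cols = range(p, p + spec.gap_width)
        for j in range(w):
            if j in gap_cols:
                continue
            t = pen - ((p - j) % w)
            o1 = int(trace[t + w])
            o0 = int(trace[t - 1 + w]) if t - 1 >= -w else o1
            lo, hi = min(o0, o1), max(o0, o1)
            roi[lo:hi + 1, j] = TRACE_INTENSITY
        if spec.letter_position is not None:
            lp = spec.letter_position
            roi[:, lp:lp + spec.letter_width] = LETTER_INTENSITY
            if lp <= p and p + spec.gap_width <= lp + spec.letter_width:
                hidden.append(k)
        frame[r0:r1, c0:c1] = roi
        frames.append(frame)
        gap_starts[k] = p

    if spec.letter_position is not None:
        tcols = np.arange(total)
        letter_cols = tcols[((tcols % w) >= spec.letter_position)
                            & ((tcols % w) < spec.letter_position + spec.letter_width)]
    else:
        letter_cols = np.empty(0, dtype=int)

    gt = EcgGroundTruth(
        qrs_columns_global=np.asarray(spec.qrs_columns_global, dtype=int),
        column_to_frame=np.arange(total) // s,
        strip_length=total,
        gap_start_per_frame=gap_starts,
        hidden_gap_frames=np.asarray(hidden, dtype=int),
        letter_columns_global=letter_cols,
    )
    return frames, gt


def random_ecg_spec(rng: np.random.Generator, n_frames: int = 36,
                    n_qrs: int | None = None, min_spacing: int = 25,
                    letter: bool = True) -> EcgVideoSpec:
    """Draw an :class:`EcgVideoSpec` with randomly placed, detectable beats.

    QRS columns are sampled with a physiological minimum spacing and kept
    clear of the strip columns corrupted by the letter glyph (occluded
    content and the unknown spacer saved when the glyph hides the redraw
    gap) — a beat drawn under the occlusion is unrecoverable from the
    rendered chart by construction, so it is not a valid study condition.
    """
    base = EcgVideoSpec(n_frames=n_frames)
    r0, c0, r1, c1 = base.ecg_roi
    w, s = c1 - c0, base.scroll_speed
    total = n_frames * s
    if n_qrs is None:
        n_qrs = int(rng.integers(5, 9))
    letter_position = int(rng.integers(0, (w - base.letter_width) // s + 1)) * s \
        if letter else None

    bad = np.zeros(total, dtype=bool)
    if letter_position is not None:
        tcols = np.arange(total)
        bad |= ((tcols % w) >= letter_position) & \
               ((tcols % w) < letter_position + base.letter_width)
        for k in range(n_frames):
            p = ((k + 1) * s) % w
            if letter_position <= p and p + base.gap_width <= letter_position + base.letter_width:
                bad[k * s:(k + 1) * s] = True  # spacer block in the strip
    margin = QRS_WIDTH + VARIANCE_GUARD
    ok = ~np.convolve(bad.astype(int), np.ones(2 * margin + 1), mode="same").astype(bool)
    ok[:margin] = ok[total - margin:] = False

    # Greedy left-to-right placement; shrink the random jitter if the tail
    # of the strip runs out of room.
    cols: list[int] = []
    for max_jitter in (15, 8, 0):
        cols = []
        pos = margin + int(rng.integers(0, max_jitter + 1))
        while pos < total - margin and len(cols) < n_qrs:
            if ok[pos]:
                cols.append(pos)
                pos += min_spacing + int(rng.integers(0, max_jitter + 1))
            else:
                pos += 1
        if len(cols) == n_qrs:
            break
    if len(cols) < n_qrs:
        raise ParameterError("could not place the requested number of beats")
    return dataclasses.replace(base, n_frames=n_frames, seed=int(rng.integers(2 ** 31)),
                               qrs_columns_global=tuple(sorted(cols)),
                               letter_position=letter_position)


# --------------------------------------------------------------------------
# sidecar I/O
# --------------------------------------------------------------------------

def write_phantom_frames(frames: list[np.ndarray] | np.ndarray, out_dir: str | Path,
                         ground_truth=None) -> Path:
    """Write frames as zero-padded PNGs plus a JSON ground-truth sidecar."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(frames, np.ndarray):
        frames = [frames]
    for i, f in enumerate(frames):
        iio.imwrite(out / f"frame_{i:04d}.png", f)
    if ground_truth is not None:
        payload = {}
        for k, v in dataclasses.asdict(ground_truth).items():
            if isinstance(v, np.ndarray):
                if v.ndim > 1 and v.size > 1000:
                    continue  # raster masks stay in memory, not in the sidecar
                v = v.tolist()
            payload[k] = v
        (out / "ground_truth.json").write_text(json.dumps(payload, indent=1))
    return out
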