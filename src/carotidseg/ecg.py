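"""ECG strip-chart gating.

A B-mode acquisition renders a scrolling ECG strip chart inside each video
frame.  The artery dilates with every heartbeat, so frames must be selected
at a fixed cardiac phase.  This module extracts the chart from a
user-marked rectangle, binarizes it (the trace is bright on a dark chart),
stitches the per-frame sweeps into one continuous strip by following the
redraw gap, locates QRS complexes as maxima of a sliding-window sample
variance of the trace ordinate, splits the strip into cardiac periods, and
maps a chosen phase position into every period and back to frame indices.

The variance detector is deliberately simple: standard QRS detectors
(Pan–Tompkins and kin) assume a sampled voltage signal, whereas here the
only evidence is a low-resolution raster rendering of the chart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, ParameterError

#: Default binarization threshold for the rendered trace (intensity >= ON).
ECG_THRESHOLD = 72
#: Default sliding-variance window width in columns (step is fixed at 1).
VARIANCE_WINDOW = 5
#: Default number of columns kept left of the redraw gap when stitching.
KEEP_LEFT = 10
#: Default minimum run of empty columns accepted as the redraw gap.
MIN_GAP = 2
#: QRS search stops once the remaining maxima fall below this fraction of
#: the global variance maximum.
NOISE_FLOOR_FRACTION = 0.25


@dataclass(frozen=True)
class EcgRoi:
    """Half-open, 0-based pixel bounds of the chart rectangle."""

    row0: int
    col0: int
    row1: int
    col1: int

    def validate(self, frame_shape: tuple[int, int]) -> None:
        rows, cols = frame_shape[:2]
        if not (0 <= self.row0 < self.row1 <= rows
                and 0 <= self.col0 < self.col1 <= cols):
            raise ParameterError(f"ROI {self} out of bounds for frame {frame_shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row1 - self.row0, self.col1 - self.col0)


@dataclass
class BinarizedSegment:
    """Thresholded chart rectangle from one frame (values 0 / 255)."""

    data: np.ndarray
    frame_index: int
    threshold: int


@dataclass
class ECGStrip:
    """Stitched chart: binary raster + per-column provenance.

    ``known_mask[j]`` is False where the redraw gap was hidden (behind the
    occluding letter) and only an empty spacer could be saved.
    ``provenance[j]`` is ``(frame_index, frame_column)``; spacer columns
    carry ``(frame_index, -1)``.
    """

    data: np.ndarray
    known_mask: np.ndarray
    provenance: np.ndarray  # (W, 2) int

    @property
    def width(self) -> int:
        return self.data.shape[1]


@dataclass
class VarianceTrace:
    """Per-window sample variance of the trace ordinate (NaN = unusable)."""

    values: np.ndarray
    window: int
    step: int = 1


@dataclass
class QrsSet:
    qrs_columns: np.ndarray  # strictly increasing strip columns


@dataclass
class PeriodSet:
    periods: list[tuple[int, int]]  # [start, end) column intervals


# --------------------------------------------------------------------------
# extraction and stitching
# --------------------------------------------------------------------------

def binarize_ecg(frame: np.ndarray, roi: EcgRoi,
                 threshold: int = ECG_THRESHOLD,
                 frame_index: int = 0) -> BinarizedSegment:
    """Threshold the chart rectangle: intensity >= threshold becomes 255."""
    roi.validate(frame.shape)
    sub = frame[roi.row0:roi.row1, roi.col0:roi.col1]
    binary = np.where(sub >= threshold, 255, 0).astype(np.uint8)
    return BinarizedSegment(data=binary, frame_index=frame_index,
                            threshold=threshold)


def trace_ordinate(segment: BinarizedSegment, col: int) -> float | None:
    """Row of the rendered trace in one column: centroid of ON pixels, or
    None when the column is empty (possible redraw gap)."""
    if not 0 <= col < segment.data.shape[1]:
        raise ParameterError(f"column {col} outside segment")
    rows = np.flatnonzero(segment.data[:, col])
    if rows.size == 0:
        return None
    return float(rows.mean())


def _ordinates(binary: np.ndarray) -> np.ndarray:
    """Centroid ordinate per column; NaN where a column has no ON pixel."""
    on = binary > 0
    counts = on.sum(axis=0)
    rows = np.arange(binary.shape[0], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cent = (on * rows[:, None]).sum(axis=0) / counts
    cent[counts == 0] = np.nan
    return cent


def find_redraw_gap(segment: BinarizedSegment, min_gap: int = MIN_GAP) -> int | None:
    """First column starting a run of >= min_gap empty columns, else None
    (the gap is taken to be hidden behind the occluding letter)."""
    if min_gap < 1:
        raise ParameterError("min_gap must be >= 1")
    empty = ~(segment.data > 0).any(axis=0)
    run = 0
    for j, e in enumerate(empty):
        run = run + 1 if e else 0
        if run == min_gap:
            return j - min_gap + 1
    return None


def stitch_strip(segments: list[BinarizedSegment],
                 keep_left: int = KEEP_LEFT,
                 min_gap: int = MIN_GAP) -> ECGStrip:
    """Concatenate, per segment, the ``keep_left`` columns left of its
    redraw gap (circularly: when the gap sits at the left edge the newest
    content is at the right edge of the sweep).  Segments without a
    findable gap contribute an unknown-flagged empty spacer of the same
    width so the strip stays aligned.
    """
    if not segments:
        raise ParameterError("stitch_strip needs at least one segment")
    h, w = segments[0].data.shape
    if keep_left < 1 or keep_left > w:
        raise ParameterError("keep_left must be in [1, segment width]")
    chunks, known, prov = [], [], []
    for seg in segments:
        if seg.data.shape != (h, w):
            raise ParameterError("all segments must share one shape")
        g = find_redraw_gap(seg, min_gap=min_gap)
        if g is None:
            chunks.append(np.zeros((h, keep_left), dtype=np.uint8))
            known.append(np.zeros(keep_left, dtype=bool))
            prov.append(np.stack([np.full(keep_left, seg.frame_index),
                                  np.full(keep_left, -1)], axis=1))
        else:
            idx = (g - keep_left + np.arange(keep_left)) % w
            chunks.append(seg.data[:, idx])
            known.append(np.ones(keep_left, dtype=bool))
            prov.append(np.stack([np.full(keep_left, seg.frame_index), idx], axis=1))
    return ECGStrip(data=np.concatenate(chunks, axis=1),
                    known_mask=np.concatenate(known),
                    provenance=np.concatenate(prov, axis=0).astype(int))


# --------------------------------------------------------------------------
# QRS detection
# --------------------------------------------------------------------------

def variance_trace(strip: ECGStrip, window: int = VARIANCE_WINDOW) -> VarianceTrace:
    """Sample variance (divisor n-1) of the trace ordinate over every
    ``window``-column span, stepping one column at a time.  Windows touching
    unknown or trace-less columns yield NaN and are excluded from peak
    search."""
    if window < 2:
        raise ParameterError("window must be >= 2")
    if strip.width < window:
        raise ParameterError("strip narrower than the window")
    ords = _ordinates(strip.data)
    ords[~strip.known_mask] = np.nan
    n = strip.width - window + 1
    values = np.full(n, np.nan)
    for i in range(n):
        seg = ords[i:i + window]
        if not np.isnan(seg).any():
            values[i] = np.var(seg, ddof=1)
    return VarianceTrace(values=values, window=window)


def detect_qrs(trace: VarianceTrace, n_expected: int | None = None,
               refractory: int | None = None,
               noise_floor_fraction: float = NOISE_FLOOR_FRACTION) -> QrsSet:
    """Iterative "first biggest" peak picking on the variance trace.

    The global maximum (earliest column on ties) marks a QRS at window
    start + window/2; a refractory span around it is suppressed and the
    search repeats until ``n_expected`` peaks are found or nothing remains
    above the noise floor.  When ``refractory`` is None it is estimated as
    40% of the median spacing of a provisional peak pass.
    """
    if trace.values.size == 0:
        raise ParameterError("empty variance trace")
    if refractory is not None and refractory <= 0:
        raise ParameterError("refractory must be positive")
    values = trace.values.astype(float).copy()
    finite = np.isfinite(values)
    if not finite.any() or np.nanmax(values) <= 0:
        return QrsSet(qrs_columns=np.empty(0, dtype=int))
    floor = noise_floor_fraction * np.nanmax(values)

    def greedy(refr: int, cap: int | None) -> list[int]:
        work = values.copy()
        peaks: list[int] = []
        while cap is None or len(peaks) < cap:
            if not np.isfinite(work).any():
                break
            i = int(np.nanargmax(work))  # first occurrence on ties
            if work[i] < floor:
                break
            peaks.append(i)
            lo, hi = max(0, i - refr), min(work.size, i + refr + 1)
            work[lo:hi] = np.nan
        return peaks

    if refractory is None:
        # A spike elevates ~(window + spike width) consecutive windows, so the
        # provisional pass suppresses 2*window+1 to avoid counting one QRS twice.
        provisional = sorted(greedy(2 * trace.window + 1, cap=64))
        if len(provisional) >= 2:
            refractory = max(trace.window,
                             int(round(0.4 * float(np.median(np.diff(provisional))))))
        else:
            refractory = trace.window
    starts = greedy(refractory, n_expected)
    cols = np.sort(np.asarray(starts, dtype=int) + trace.window // 2)
    return QrsSet(qrs_columns=cols)


def split_periods(qrs: QrsSet) -> PeriodSet:
    """Cardiac periods: [q_i, q_{i+1}) for consecutive QRS columns."""
    cols = qrs.qrs_columns
    if cols.size < 2:
        raise InsufficientDataError("need >= 2 QRS complexes to form periods")
    return PeriodSet(periods=[(int(a), int(b)) for a, b in zip(cols[:-1], cols[1:])])


def map_relative_position(pos: int, periods: PeriodSet) -> list[int]:
    """Project a strip column onto the same relative phase of every period.

    Periods shorten when the heart rate rises, so the position is expressed
    as a fraction of its own period and re-applied to each period's length.
    """
    for start, end in periods.periods:
        if start <= pos < end:
            f = (pos - start) / (end - start)
            return [int(round(s + f * (e - s))) for s, e in periods.periods]
    raise ParameterError(f"position {pos} lies outside every period")


def columns_to_frames(cols, strip: ECGStrip) -> list[tuple[int, bool]]:
    """Map strip columns to source frame indices via provenance.

    Unknown (spacer) columns map to the nearest known column's frame and are
    flagged approximate in the second tuple element.
    """
    known_idx = np.flatnonzero(strip.known_mask)
    out: list[tuple[int, bool]] = []
    for c in np.atleast_1d(np.asarray(cols, dtype=int)):
        if not 0 <= c < strip.width:
            raise ParameterError(f"column {c} outside strip")
        if strip.known_mask[c]:
            out.append((int(strip.provenance[c, 0]), False))
        else:
            if known_idx.size == 0:
                raise ParameterError("strip has no known columns")
            nearest = known_idx[np.argmin(np.abs(known_idx - c))]
            out.append((int(strip.provenance[nearest, 0]), True))
    return out


# --------------------------------------------------------------------------
# convenience: whole gating stage
# --------------------------------------------------------------------------

@dataclass
class GatingResult:
    strip: ECGStrip
    trace: VarianceTrace
    qrs: QrsSet
    periods: PeriodSet | None
    position: int | None
    mapped_columns: list[int] = field(default_factory=list)
    frames: list[tuple[int, bool]] = field(default_factory=list)


def gate_video(frames: list[np.ndarray], roi: EcgRoi,
               threshold: int = ECG_THRESHOLD, window: int = VARIANCE_WINDOW,
               keep_left: int = KEEP_LEFT, min_gap: int = MIN_GAP,
               n_expected: int | None = None, refractory: int | None = None,
               position: int | None = None) -> GatingResult:
    """Run the full gating chain on a frame sequence.

    ``position`` is the strip column whose cardiac phase the caller wants in
    every period; by default the first QRS column is used, i.e. the frames
    returned sample the artery at the QRS phase of each beat.
    """
    segments = [binarize_ecg(f, roi, threshold=threshold, frame_index=i)
                for i, f in enumerate(frames)]
    strip = stitch_strip(segments, keep_left=keep_left, min_gap=min_gap)
    trace = variance_trace(strip, window=window)
    qrs = detect_qrs(trace, n_expected=n_expected, refractory=refractory)
    if qrs.qrs_columns.size < 2:
        return GatingResult(strip=strip, trace=trace, qrs=qrs, periods=None,
                            position=None)
    periods = split_periods(qrs)
    if position is None:
        position = int(qrs.qrs_columns[0])
    mapped = map_relative_position(position, periods)
    mapped_in = [c for c in mapped if 0 <= c < strip.width]
    return GatingResult(strip=strip, trace=trace, qrs=qrs, periods=periods,
                        position=position, mapped_columns=mapped,
                        frames=columns_to_frames(mapped_in, strip))
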