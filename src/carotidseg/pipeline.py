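"""Video I/O, configuration and the end-to-end pipeline.

``run_pipeline`` composes the stages in their operating order: ECG gating
selects frames at a fixed cardiac phase (optional), frame repair fixes
defective regions from references (optional), each selected frame is then
run through artery detection (or a user-supplied circle for the
semi-automatic path), shadow-side reconstruction, GVF-snake segmentation
and plaque-area measurement.  A failure on one frame is recorded with a
reason code and never aborts the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import detect as _detect
from . import ecg as _ecg
from . import segment as _segment
from .repair import (RepairSpec, defect_mask_from_references, estimate_shift,
                     repair as repair_image)
from .errors import CarotidSegError, DetectionError, ParameterError, VideoIOError

logger = logging.getLogger("carotidseg")

_FRAME_SUFFIXES = (".png", ".tif", ".tiff", ".bmp")


# --------------------------------------------------------------------------
# frame I/O
# --------------------------------------------------------------------------

def _to_gray8(arr: np.ndarray) -> np.ndarray:
    """Collapse to 8-bit single channel (ITU-R 601 luma for colour input)."""
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return arr


def read_video(path: str | Path) -> list[np.ndarray]:
    """Read an ordered grayscale frame sequence.

    Accepts a directory of frames (lexicographic order) or any container
    imageio can decode (multi-page TIFF, GIF, AVI where a decoder is
    available).  Raises :class:`VideoIOError` when nothing can be read.
    """
    import imageio.v3 as iio

    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise VideoIOError(f"no readable frames in directory {p}")
        return [_to_gray8(iio.imread(f)) for f in files]
    if not p.exists():
        raise VideoIOError(f"no such file: {p}")
    try:
        frames = [_to_gray8(f) for f in iio.imiter(p)]
    except Exception as exc:  # imageio raises plugin-specific types
        raise VideoIOError(f"cannot decode {p}: {exc}") from exc
    if not frames:
        raise VideoIOError(f"container {p} holds no frames")
    return frames


def read_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    p = Path(path)
    if not p.exists():
        raise VideoIOError(f"no such file: {p}")
    return _to_gray8(iio.imread(p))


def write_image(path: str | Path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), img)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ParameterError(f"unknown {where} keys: {sorted(unknown)}")
    return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})


@dataclass(frozen=True)
class EcgConfig:
    roi: tuple[int, int, int, int] = (0, 0, 1, 1)
    threshold: int = _ecg.ECG_THRESHOLD
    window: int = _ecg.VARIANCE_WINDOW
    keep_left: int = _ecg.KEEP_LEFT
    min_gap: int = _ecg.MIN_GAP
    n_expected: int | None = None
    refractory: int | None = None
    position: int | None = None


@dataclass(frozen=True)
class RepairConfig:
    """Optional pre-detection repair: defective pixels (those deviating from
    the mean of the reference frames by more than ``threshold``) are filled
    with the reference average, after phase-correlation alignment."""

    reference_indices: tuple[int, ...] = ()
    threshold: float = 40.0
    register: bool = True


@dataclass(frozen=True)
class DetectConfig:
    clahe_tile_grid: tuple[int, int] = (8, 8)
    clahe_clip_limit: float = 2.0
    median_kernel: int = _detect.MEDIAN_KERNEL
    r_min: int | None = None
    r_max: int | None = None
    min_score: float = _detect.HOUGH_MIN_SCORE


@dataclass(frozen=True)
class SegmentConfig:
    threshold_shift: float = _segment.SEGMENT_THRESHOLD_SHIFT
    gvf_mu: float = _segment.GVF_MU
    gvf_iterations: int = _segment.GVF_ITERATIONS
    alpha: float = _segment.SNAKE_ALPHA
    beta: float = _segment.SNAKE_BETA
    gamma: float = _segment.SNAKE_GAMMA
    snake_iterations: int = _segment.SNAKE_ITERATIONS
    convergence_tol: float = _segment.SNAKE_TOL


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; unknown keys are rejected on load."""

    input_path: str = ""
    output_dir: str | None = None
    mm_per_px: float = 0.1
    seed: int = 0
    detection: str = "auto"              # "auto" | "user"
    user_circle: tuple[int, int, int] | None = None
    ecg: EcgConfig | None = None
    repair: RepairConfig | None = None
    detect: DetectConfig = field(default_factory=DetectConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)

    def validate(self) -> None:
        if not self.input_path:
            raise ParameterError("input_path is required")
        if self.mm_per_px <= 0:
            raise ParameterError("mm_per_px must be positive")
        if self.detection not in ("auto", "user"):
            raise ParameterError("detection must be 'auto' or 'user'")
        if self.detection == "user" and self.user_circle is None:
            raise ParameterError("user detection mode needs user_circle")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sub = {}
        if raw.get("ecg") is not None:
            sub["ecg"] = _build(EcgConfig, raw.pop("ecg"), "ecg")
        elif "ecg" in raw:
            raw.pop("ecg")
        if raw.get("repair") is not None:
            sub["repair"] = _build(RepairConfig, raw.pop("repair"), "repair")
        elif "repair" in raw:
            raw.pop("repair")
        if "detect" in raw:
            sub["detect"] = _build(DetectConfig, raw.pop("detect"), "detect")
        if "segment" in raw:
            sub["segment"] = _build(SegmentConfig, raw.pop("segment"), "segment")
        cfg = _build(cls, {**raw, **sub}, "pipeline")
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

@dataclass
class FrameRecord:
    frame_index: int
    approximate_gating: bool = False
    circle: list | None = None           # [row, col, radius, score-or-None]
    contour: list | None = None          # [[row, col], ...]
    outline_kind: str | None = None
    outline_area_mm2: float | None = None
    contour_area_mm2: float | None = None
    plaque_area_mm2: float | None = None
    reconstruction_added: int | None = None
    failure_reason: str | None = None


@dataclass
class RunReport:
    config: dict
    frames: list[FrameRecord] = field(default_factory=list)
    qrs_columns: list[int] = field(default_factory=list)
    periods: list[list[int]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, indent: int = 1) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        raw = json.loads(text)
        frames = [FrameRecord(**f) for f in raw.pop("frames", [])]
        return cls(frames=frames, **raw)

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(self.to_json())


# --------------------------------------------------------------------------
# orchestrator
# --------------------------------------------------------------------------

def _jsonable_config(config: PipelineConfig) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return conv(dataclasses.asdict(obj))
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list)):
            return [conv(v) for v in obj]
        return obj

    return conv(config)


def process_frame(frame: np.ndarray, config: PipelineConfig,
                  frame_index: int, approximate: bool = False) -> FrameRecord:
    """Detection + segmentation + measurement for one frame."""
    rec = FrameRecord(frame_index=frame_index, approximate_gating=approximate)
    try:
        if config.detection == "user":
            row, col, radius = config.user_circle
            # no accumulator vote exists for a user-marked circle
            circle = _detect.CircleDetection(row=int(row), col=int(col),
                                             radius=int(radius), score=0.0)
            score_out = None
        else:
            d = config.detect
            circle = _detect.detect_artery(
                frame,
                clahe_params=_detect.ClaheParams(tile_grid=d.clahe_tile_grid,
                                                 clip_limit=d.clahe_clip_limit),
                median_kernel=d.median_kernel, r_min=d.r_min, r_max=d.r_max,
                min_score=d.min_score)
            score_out = float(circle.score)
        rec.circle = [circle.row, circle.col, circle.radius, score_out]
        s = config.segment
        seg = _segment.segment_artery(
            frame, (circle.row, circle.col, circle.radius), config.mm_per_px,
            median_kernel=config.detect.median_kernel,
            threshold_shift=s.threshold_shift, gvf_mu=s.gvf_mu,
            gvf_iterations=s.gvf_iterations, alpha=s.alpha, beta=s.beta,
            gamma=s.gamma, snake_iterations=s.snake_iterations,
            convergence_tol=s.convergence_tol)
        m = seg.measurement
        rec.contour = [[float(r), float(c)] for r, c in seg.contour.vertices]
        rec.outline_kind = seg.outline_kind
        rec.outline_area_mm2 = float(m.outline_area_mm2)
        rec.contour_area_mm2 = float(m.contour_area_mm2)
        rec.plaque_area_mm2 = float(m.plaque_area_mm2)
        rec.reconstruction_added = seg.reconstruction_added
    except DetectionError as exc:
        rec.failure_reason = exc.reason
    except CarotidSegError as exc:
        rec.failure_reason = f"{type(exc).__name__}: {exc}"
    return rec


def run_pipeline(config: PipelineConfig,
                 frames: list[np.ndarray] | None = None) -> RunReport:
    """Execute the configured stages; deterministic for a fixed config.

    ``frames`` may be supplied directly (e.g. from a phantom generator);
    otherwise they are read from ``config.input_path``.
    """
    config.validate()
    if frames is None:
        frames = read_video(config.input_path)
    report = RunReport(config=_jsonable_config(config))

    selected: list[tuple[int, bool]] = [(i, False) for i in range(len(frames))]
    if config.ecg is not None:
        e = config.ecg
        roi = _ecg.EcgRoi(*e.roi)
        gating = _ecg.gate_video(frames, roi, threshold=e.threshold,
                                 window=e.window, keep_left=e.keep_left,
                                 min_gap=e.min_gap, n_expected=e.n_expected,
                                 refractory=e.refractory, position=e.position)
        report.qrs_columns = [int(c) for c in gating.qrs.qrs_columns]
        if gating.periods is None:
            report.warnings.append("gating found < 2 QRS complexes; "
                                   "processing every frame")
        else:
            report.periods = [[int(a), int(b)] for a, b in gating.periods.periods]
            seen = set()
            selected = []
            for idx, approx in gating.frames:
                if idx not in seen:
                    seen.add(idx)
                    selected.append((idx, approx))

    for idx, approx in selected:
        logger.info("processing frame %d", idx)
        frame = frames[idx]
        if config.repair is not None and config.repair.reference_indices:
            refs = [frames[i] for i in config.repair.reference_indices
                    if 0 <= i < len(frames) and i != idx]
            if refs:
                shifts = [estimate_shift(frame, r) for r in refs] \
                    if config.repair.register else None
                if shifts is not None:
                    from .repair import align
                    refs = [align(r, s) for r, s in zip(refs, shifts)]
                mask = defect_mask_from_references(
                    frame, refs, threshold=config.repair.threshold)
                frame = repair_image(frame, refs, RepairSpec(defect_mask=mask))
        report.frames.append(process_frame(frame, config, idx, approx))
    return report
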