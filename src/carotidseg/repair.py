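"""Inter-frame registration and raster repair.

Consecutive ultrasound frames are related by small translations (probe and
tissue motion).  The offset between two frames is estimated by phase
correlation: the argmax of the inverse transform of the normalized
cross-power spectrum.  Defective regions (e.g. dropout under an artefact)
are then filled either with the per-pixel average of aligned reference
frames or with a user-chosen intensity.

Phase correlation here is the plain, unwindowed variant so that pure
integer translations are recovered exactly; an optional Hann window and
parabolic subpixel refinement are available for real data with strong edge
effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ParameterError


@dataclass(frozen=True)
class Shift:
    """Estimated translation: ``b ~ roll(a, (dy, dx))``."""

    dy: float
    dx: float
    peak_response: float = 1.0


@dataclass(frozen=True)
class RepairSpec:
    """What to repair and how.

    ``mode`` is ``"reference_average"`` (masked pixels become the rounded
    mean of the aligned references) or ``"user_colour"`` (masked pixels
    become ``user_colour``).
    """

    defect_mask: np.ndarray
    mode: str = "reference_average"
    user_colour: int = 0

    def validate(self, target_shape: tuple[int, int]) -> None:
        if self.defect_mask.shape != target_shape:
            raise ParameterError("defect mask shape must match the target")
        if self.mode not in ("reference_average", "user_colour"):
            raise ParameterError(f"unknown repair mode {self.mode!r}")
        if not 0 <= self.user_colour <= 255:
            raise ParameterError("user_colour must be in [0, 255]")


def estimate_shift(a: np.ndarray, b: np.ndarray, window: bool = False,
                   subpixel: bool = False) -> Shift:
    """Phase-correlation offset of ``b`` relative to ``a``.

    Returns the peak of ``ifft(F(b) * conj(F(a)) / |.|)`` wrapped to signed
    offsets, so ``estimate_shift(a, roll(a, (dy, dx))) == (dy, dx)``.
    ``peak_response`` is the correlation peak height (1.0 for a pure
    circular translation).
    """
    if a.shape != b.shape:
        raise ParameterError("images must share dimensions")
    af = a.astype(float)
    bf = b.astype(float)
    if af.std() == 0 or bf.std() == 0:
        raise DegenerateInputError("zero-variance image: offset undefined")
    if window:
        wy = np.hanning(a.shape[0])[:, None]
        wx = np.hanning(a.shape[1])[None, :]
        af = (af - af.mean()) * wy * wx
        bf = (bf - bf.mean()) * wy * wx
    fa = np.fft.fft2(af)
    fb = np.fft.fft2(bf)
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    corr = np.fft.ifft2(cross / mag).real
    peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
    dy, dx = float(peak[0]), float(peak[1])
    if subpixel:
        dy += _parabolic_offset(corr, peak, axis=0)
        dx += _parabolic_offset(corr, peak, axis=1)
    rows, cols = a.shape
    if dy > rows / 2:
        dy -= rows
    if dx > cols / 2:
        dx -= cols
    if not subpixel:
        dy, dx = float(int(dy)), float(int(dx))
    return Shift(dy=dy, dx=dx, peak_response=float(corr[peak]))


def _parabolic_offset(corr: np.ndarray, peak: tuple[int, ...], axis: int) -> float:
    """Three-point parabola fit through the peak along one axis (wrapped)."""
    n = corr.shape[axis]
    idx = list(peak)
    vals = []
    for d in (-1, 0, 1):
        idx[axis] = (peak[axis] + d) % n
        vals.append(corr[tuple(idx)])
    c_m, c_0, c_p = vals
    denom = c_m - 2 * c_0 + c_p
    if denom == 0:
        return 0.0
    return float(0.5 * (c_m - c_p) / denom)


def align(img: np.ndarray, shift: Shift, fill: int = 0) -> np.ndarray:
    """Undo a :class:`Shift`: translate by (-dy, -dx), filling the exposed
    border with ``fill``.  ``align(roll(a, d), Shift(*d))`` equals ``a``
    away from the border band."""
    dy, dx = int(round(shift.dy)), int(round(shift.dx))
    rows, cols = img.shape
    if abs(dy) >= rows or abs(dx) >= cols:
        raise ParameterError("shift exceeds image bounds")
    out = np.full_like(img, fill)
    src_r = slice(max(0, dy), rows + min(0, dy))
    src_c = slice(max(0, dx), cols + min(0, dx))
    dst_r = slice(max(0, -dy), rows + min(0, -dy))
    dst_c = slice(max(0, -dx), cols + min(0, -dx))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def repair(target: np.ndarray, references: list[np.ndarray],
           spec: RepairSpec, shifts: list[Shift] | None = None) -> np.ndarray:
    """Fill masked pixels from references (or a flat colour).

    In ``reference_average`` mode each masked pixel becomes the
    round-half-up mean of the aligned reference intensities.  Unmasked
    pixels are never touched, which also makes the operation idempotent.
    """
    spec.validate(target.shape)
    out = target.copy()
    mask = spec.defect_mask.astype(bool)
    if spec.mode == "user_colour":
        out[mask] = spec.user_colour
        return out
    if not references:
        raise ParameterError("reference_average mode needs >= 1 reference")
    if shifts is not None:
        if len(shifts) != len(references):
            raise ParameterError("one shift per reference required")
        references = [align(r, s) for r, s in zip(references, shifts)]
    for r in references:
        if r.shape != target.shape:
            raise ParameterError("references must match the target shape")
    stack = np.stack([r.astype(float) for r in references])
    mean = stack.mean(axis=0)
    filled = np.floor(mean + 0.5)  # round half up, as for intensity averaging
    out[mask] = np.clip(filled[mask], 0, 255).astype(target.dtype)
    return out


def histogram_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Reference-selection score: L1 distance between normalized 256-bin
    intensity histograms (0 = identical distributions, 2 = disjoint).

    Reference frames for repair should differ from the defective frame as
    little as possible in intensity distribution and contrast; this score
    reports that difference, leaving the choice to the caller.
    """
    ha = np.bincount(a.ravel().astype(np.uint8), minlength=256) / a.size
    hb = np.bincount(b.ravel().astype(np.uint8), minlength=256) / b.size
    return float(np.abs(ha - hb).sum())


def defect_mask_from_references(target: np.ndarray, references: list[np.ndarray],
                                threshold: float = 40.0) -> np.ndarray:
    """Heuristic defect mask: pixels deviating from the reference mean by
    more than ``threshold`` intensity levels."""
    if not references:
        raise ParameterError("need >= 1 reference")
    mean = np.stack([r.astype(float) for r in references]).mean(axis=0)
    return np.abs(target.astype(float) - mean) > threshold
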