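"""Response-vector labels and depth-translation augmentation.

The ROI detector is trained as a per-depth regressor against a "response
vector": a quadratic bump that equals 1 at the lumen center, falls to 0
at two cut-off points placed halfway between the center and each wall,
and is exactly 0 outside the open interval between the cut-offs. Indices
i strictly between the cut-offs get

    R_i = 1 - (i - P_C)^2 / (P_C - P_cutoff)^2

with the cut-off on the same side as i in the denominator. Wall
positions, centers and cut-offs are kept real-valued; R is evaluated at
integer depth indices, avoiding rounding bias in the labels.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, DataError

__all__ = ["lumen_center", "cutoff_points", "response_vector",
           "response_matrix", "augment_translate"]


def lumen_center(anterior: float, posterior: float) -> float:
    """Midpoint of the two wall positions (real-valued, no rounding)."""
    if posterior < anterior:
        raise DataError("posterior wall must not be shallower than anterior wall")
    return (anterior + posterior) / 2.0


def cutoff_points(center: float, anterior: float, posterior: float) -> tuple[float, float]:
    """Cut-off points halfway between the lumen center and each wall."""
    if not anterior <= center <= posterior:
        raise DataError("expected anterior <= center <= posterior")
    return (center + anterior) / 2.0, (center + posterior) / 2.0


def response_vector(anterior: float, posterior: float, length: int) -> np.ndarray:
    """Per-depth training label in [0, 1] peaking at the lumen center."""
    if not 0 <= anterior < posterior < length:
        if anterior == posterior:
            raise DataError("zero-width lumen: anterior equals posterior")
        raise DataError(
            f"walls ({anterior}, {posterior}) must satisfy 0 <= anterior < "
            f"posterior < {length}"
        )
    center = lumen_center(anterior, posterior)
    cut_a, cut_p = cutoff_points(center, anterior, posterior)
    i = np.arange(length, dtype=np.float64)
    r = np.zeros(length)
    lower = (i > cut_a) & (i <= center)
    upper = (i > center) & (i < cut_p)
    r[lower] = 1.0 - (i[lower] - center) ** 2 / (center - cut_a) ** 2
    r[upper] = 1.0 - (i[upper] - center) ** 2 / (cut_p - center) ** 2
    return r


def response_matrix(anterior: np.ndarray, posterior: np.ndarray, length: int) -> np.ndarray:
    """Vectorized response vectors for many frames; shape (n_frames, length)."""
    anterior = np.asarray(anterior, dtype=np.float64)[:, None]
    posterior = np.asarray(posterior, dtype=np.float64)[:, None]
    if np.any(anterior >= posterior) or np.any(anterior < 0) or np.any(posterior >= length):
        raise DataError("wall positions out of range for response labels")
    center = (anterior + posterior) / 2.0
    cut_a = (center + anterior) / 2.0
    cut_p = (center + posterior) / 2.0
    i = np.arange(length, dtype=np.float64)[None, :]
    denom_a = (center - cut_a) ** 2
    denom_p = (cut_p - center) ** 2
    denom = np.where(i <= center, denom_a, denom_p)
    r = 1.0 - (i - center) ** 2 / denom
    r[(i <= cut_a) | (i >= cut_p)] = 0.0
    return r


def augment_translate(frame: np.ndarray, anterior: float, posterior: float,
                      shift: int) -> tuple[np.ndarray, float, float]:
    """Translate an envelope frame and its wall annotation along depth.

    Shift is applied with zero fill (no wrap-around); the annotation moves
    by the same amount, so the response vector of the shifted annotation
    equals the shifted response vector.
    """
    length = frame.shape[0]
    if not (0 <= anterior + shift and posterior + shift < length):
        raise ConfigError(
            f"shift {shift} pushes walls ({anterior}, {posterior}) outside "
            f"[0, {length})"
        )
    out = np.zeros_like(frame)
    if shift >= 0:
        out[shift:] = frame[:length - shift]
    else:
        out[:length + shift] = frame[-shift:]
    return out, anterior + shift, posterior + shift


def shift_stack(frames: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Zero-fill shift of a batch of frames (n, length) by per-row shifts."""
    n, length = frames.shape
    out = np.zeros_like(frames)
    for s in np.unique(shifts):
        rows = shifts == s
        if s >= 0:
            out[rows, s:] = frames[rows, :length - s]
        else:
            out[rows, :length + s] = frames[rows, -s:]
    return out
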