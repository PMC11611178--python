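"""RF-to-envelope conversion and depth-axis conditioning.

The networks consume the magnitude of the analytic signal (Hilbert
envelope) of each A-mode frame, optionally block-max decimated along
depth and normalized to unit per-frame maximum.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .errors import ConfigError, DataError

__all__ = ["hilbert_envelope", "decimate_depth", "normalize_frame", "envelope_stack"]


def hilbert_envelope(rf: np.ndarray) -> np.ndarray:
    """Envelope |analytic signal| of RF data along the depth axis.

    Accepts a single frame (depth,) or an M-mode stack (depth, frames);
    the transform runs along axis 0.
    """
    rf = np.asarray(rf, dtype=np.float64)
    if rf.shape[0] < 8:
        raise DataError("frame too short for envelope extraction (need >= 8 samples)")
    if not np.all(np.isfinite(rf)):
        if rf.ndim == 1:
            raise DataError("non-finite values in RF frame")
        bad = np.where(~np.isfinite(rf).all(axis=0))[0]
        raise DataError(f"non-finite values in RF frames {bad[:5].tolist()}")
    return np.abs(hilbert(rf, axis=0))


def decimate_depth(env: np.ndarray, factor: int) -> np.ndarray:
    """Block-max reduction along depth by ``factor`` (keeps echo peaks).

    Output index i summarizes the input depth interval
    [i*factor, (i+1)*factor).
    """
    env = np.asarray(env)
    if factor < 1:
        raise ConfigError("decimation factor must be >= 1")
    if factor == 1:
        return env
    n = env.shape[0]
    if n % factor != 0:
        divisors = [f for f in range(1, n + 1) if n % f == 0]
        nearest = min(divisors, key=lambda f: abs(f - factor))
        raise ConfigError(
            f"decimation factor {factor} does not divide depth {n}; "
            f"nearest valid factor is {nearest}"
        )
    shape = (n // factor, factor) + env.shape[1:]
    return env.reshape(shape).max(axis=1)


def normalize_frame(env: np.ndarray) -> np.ndarray:
    """Divide each frame by its maximum so the peak amplitude is 1."""
    env = np.asarray(env, dtype=np.float64)
    peak = env.max(axis=0)
    if np.any(peak <= 0):
        raise DataError("degenerate all-zero frame cannot be normalized")
    return env / peak


def envelope_stack(rf: np.ndarray, decimation: int = 1, normalize: bool = True) -> np.ndarray:
    """Convenience composition: envelope -> decimate -> per-frame normalize."""
    env = hilbert_envelope(rf)
    env = decimate_depth(env, decimation)
    if normalize:
        env = normalize_frame(env)
    return env
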