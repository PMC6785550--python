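"""Time-domain EMG features: linear envelope, pattern variability, total power.

The linear envelope is the rectified EMG low-pass filtered at 4 Hz (4th-order
zero-phase Butterworth).  Pattern variability is the coefficient of variation
(SD/mean) of that envelope; it is large for burst-and-silence activation and
small for continuous activation.  Total power is the time-averaged squared
amplitude P = (1/T) * integral |x(t)|^2 dt, realized discretely as mean(x^2),
in microvolts squared; per participant and muscle it is normalized by the
maximum across that participant's events.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = ["linear_envelope", "pattern_variability", "total_power",
           "normalize_power", "time_feature_vector"]

#: seconds dropped at each end of the envelope before statistics, to avoid
#: filter edge transients biasing the CV
ENVELOPE_EDGE_TRIM_S = 0.5


def linear_envelope(x: np.ndarray, fs: float, cutoff_hz: float = 4.0,
                    order: int = 4) -> np.ndarray:
    """Linear envelope: rectify then zero-phase low-pass at ``cutoff_hz``.

    Forward-backward filtering doubles the effective order and removes phase
    lag; negative undershoot from filter ringing is clipped at zero.
    """
    x = np.asarray(x, dtype=float)
    if cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {fs/2} Hz")
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if len(x) <= padlen:
        raise ValueError(f"signal too short for the {order}th-order filter "
                         f"warm-up ({len(x)} <= {padlen} samples)")
    env = sosfiltfilt(sos, np.abs(x))
    return np.clip(env, 0.0, None)


def pattern_variability(x: np.ndarray, fs: float,
                        cutoff_hz: float = 4.0) -> float:
    """CV (SD/mean) of the linear envelope, edge-trimmed by 0.5 s per side.

    Returns NaN with a warning when the envelope mean is zero (silent
    channel), where the CV is undefined.
    """
    env = linear_envelope(x, fs, cutoff_hz=cutoff_hz)
    k = int(round(ENVELOPE_EDGE_TRIM_S * fs))
    if len(env) > 2 * k + 2:
        env = env[k:len(env) - k]
    m = env.mean()
    if m <= 0:
        warnings.warn("zero-mean envelope: pattern variability undefined")
        return float("nan")
    return float(env.std() / m)


def total_power(x: np.ndarray, fs: float | None = None) -> float:
    """Time-averaged squared amplitude, mean(x^2), in µV²."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("total_power needs at least 2 samples")
    return float(np.mean(x**2))


def normalize_power(values: Mapping[tuple, float]) -> dict[tuple, float]:
    """Normalize total power by the per-(participant, muscle) maximum.

    ``values`` maps (participant, muscle, event) keys to raw total power.
    Each value is divided by the maximum over that participant's events for
    that muscle, so the strongest event maps to 1.  A group whose maximum is
    zero is flagged with a ValueError naming the group.
    """
    groups: dict[tuple, float] = {}
    for (pid, muscle, _ev), v in values.items():
        key = (pid, muscle)
        groups[key] = max(groups.get(key, 0.0), v)
    for key, vmax in groups.items():
        if vmax <= 0:
            raise ValueError(f"group {key}: maximum power is zero")
    return {k: v / groups[(k[0], k[1])] for k, v in values.items()}


def time_feature_vector(x: np.ndarray, fs: float) -> dict[str, float]:
    """Both time-domain features of one trace as a named dict."""
    return {"pattern_variability": pattern_variability(x, fs),
            "total_power": total_power(x, fs)}
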