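"""Surface-EMG conditioning and MVC normalization.

The conditioning chain is: zero-phase 4th-order Butterworth high-pass at
100 Hz (removes motion artifact and baseline), full-wave rectification,
then zero-phase 4th-order Butterworth low-pass at 4 Hz to obtain the linear
envelope.  Envelopes are normalized by the peak envelope recorded during
maximum voluntary contractions; normalized values may exceed 1 and are
reported as-is.  Filter order and the forward-backward (zero-phase)
application follow standard surface-EMG processing convention and are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = ["EmgChannel", "emg_envelope", "normalize_mvc", "mvc_peak_from_trials"]


@dataclass
class EmgChannel:
    """One EMG channel: raw series (mV) and its processed envelope."""

    muscle: str
    fs: float
    raw: np.ndarray
    envelope: np.ndarray | None = None
    normalized: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def emg_envelope(
    raw,
    fs: float,
    highpass_hz: float = 100.0,
    lowpass_hz: float = 4.0,
    order: int = 4,
):
    """Linear envelope: zero-phase HP -> full-wave rectify -> zero-phase LP.

    ``raw`` may be (N,) or (N, n_channels).  The output is clamped at zero
    (low-pass ringing can produce small negative excursions).  Raises if the
    sampling rate leaves no room above the high-pass corner.
    """
    raw = np.asarray(raw, dtype=float)
    if fs <= 2.0 * highpass_hz:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {highpass_hz} Hz high-pass"
            " (corner at or above Nyquist)"
        )
    bh, ah = butter(order, highpass_hz, btype="high", fs=fs)
    bl, al = butter(order, lowpass_hz, btype="low", fs=fs)
    hp = filtfilt(bh, ah, raw, axis=0)
    env = filtfilt(bl, al, np.abs(hp), axis=0)
    return np.clip(env, 0.0, None)


def normalize_mvc(envelope, mvc_peak: float):
    """Normalize an envelope by the MVC peak (values may exceed 1)."""
    if mvc_peak <= 0:
        raise ValueError(f"MVC peak must be > 0, got {mvc_peak}")
    return np.asarray(envelope, dtype=float) / mvc_peak


def mvc_peak_from_trials(raw_trials, fs: float, **kwargs) -> float:
    """MVC value: maximum of the processed envelope across MVC trials."""
    return float(max(emg_envelope(r, fs, **kwargs).max() for r in raw_trials))
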