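"""Broadband filtering and analysis-window cropping of epoched EEG.

The standard preprocessing for motor-imagery decoding on these recordings:
a 4-40 Hz fifth-order Butterworth bandpass (applied zero-phase, forward and
backward, so no group delay shifts the event-related dynamics) and cropping
to the 500-4500 ms post-cue analysis window, dropping the reaction-time
portion at the start of the trial.

Conventions
-----------
* "Order" is the design order of the bandpass prototype before the
  forward-backward pass; the effective attenuation order doubles.
* Sample windows are half-open ``[start, end)`` with 0-based indices, so
  adjacent windows on a shared boundary never double-count a sample.
* Filtering pads each epoch by odd reflection (scipy's default pad length
  for the second-order-section filter) to suppress edge transients.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .epochs import EpochSet
from .errors import InvalidDataError, InvalidParameterError, OutOfRangeError

__all__ = ["bandpass_filter", "crop_window", "design_bandpass"]


def design_bandpass(low_hz: float, high_hz: float, order: int, fs: float) -> np.ndarray:
    """Second-order sections of a Butterworth bandpass; validates edges."""
    if order < 1:
        raise InvalidParameterError(f"filter order must be >= 1, got {order}")
    if not (0.0 < low_hz < high_hz < fs / 2.0):
        raise InvalidParameterError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < fs/2 = {fs / 2}"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(epochs: EpochSet, low_hz: float, high_hz: float,
                    order: int = 5) -> EpochSet:
    """Zero-phase Butterworth bandpass, each channel filtered independently.

    Returns a new :class:`EpochSet` of identical shape; labels, sampling
    rate and time origin are untouched.
    """
    sos = design_bandpass(low_hz, high_hz, order, epochs.fs)
    if not np.isfinite(epochs.data).all():
        raise InvalidDataError("epoch data contain non-finite samples")
    # odd-reflection padding spanning ~10 cycles of the low band edge: the
    # filter's transient is set by 1/low_hz, not the design order
    padlen = int(min(epochs.n_samples - 1, round(10.0 * epochs.fs / low_hz)))
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1,
                                  padtype="odd", padlen=padlen)
    return epochs.copy_with(np.ascontiguousarray(filtered))


def crop_window(epochs: EpochSet, t_start: float, t_end: float) -> EpochSet:
    """Crop every trial to the half-open window [t_start, t_end) ms.

    Times are relative to trial onset. The returned sample count is
    ``round((t_end - t_start) / 1000 * fs)`` and ``t0`` is updated to
    ``t_start``.
    """
    if not t_start < t_end:
        raise OutOfRangeError(f"empty window: t_start={t_start} >= t_end={t_end}")
    if t_start < epochs.t0 - 1e-9 or t_end > epochs.t_end + 1e-9:
        raise OutOfRangeError(
            f"window [{t_start}, {t_end}) ms outside epoch extent "
            f"[{epochs.t0}, {epochs.t_end}) ms"
        )
    start = int(round((t_start - epochs.t0) / 1000.0 * epochs.fs))
    n_out = int(round((t_end - t_start) / 1000.0 * epochs.fs))
    if start + n_out > epochs.n_samples:
        raise OutOfRangeError("window end exceeds the last sample")
    cropped = epochs.data[:, :, start:start + n_out].copy()
    return epochs.copy_with(cropped, t0=float(t_start))
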