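"""Synthetic two-class motor-imagery-like EEG with planted effects.

Every trial is 1/f-shaped background noise per channel plus sensor-level
white noise; class information is planted as band-limited Gaussian sources
(not sinusoids, so a variance-based spatial filter is exercised
realistically) that are amplitude-modulated to a time window with 50 ms
raised-cosine ramps, mixed into the channels by a fixed spatial pattern,
and scaled so the two classes differ by a stated log band-power ratio.
This emulates event-related (de)synchronization as a pure band-power
effect; it makes no claim to physiological forward modeling.

Defaults mirror a 22-channel, 250 Hz recording with 72 trials per class
and 7 s epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .epochs import EpochSet
from .errors import ContractError
from .tfbank import BandSpec, TFGrid, WindowSpec

__all__ = ["PlantedCell", "SynthSpec", "GroundTruth", "generate"]


@dataclass(frozen=True)
class PlantedCell:
    """One class-discriminative band/window source.

    ``effect`` is the natural-log band-power ratio of the second class over
    the first within this cell; ``spatial_pattern`` mixes the source into
    the channels (length = n_channels, not all zero).
    """
    band: BandSpec
    window: WindowSpec
    effect: float
    spatial_pattern: tuple

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ContractError("effect must be >= 0 (swap class roles instead)")
        if not np.any(np.asarray(self.spatial_pattern, dtype=float) != 0):
            raise ContractError("spatial_pattern must be non-zero")


@dataclass
class SynthSpec:
    """Stated world for the generator; defaults mirror the 22-channel setup."""
    n_trials_per_class: int = 72
    n_channels: int = 22
    fs: float = 250.0
    epoch_ms: float = 7000.0
    planted_cells: list[PlantedCell] = field(default_factory=list)
    background: float = 1.0        # RMS of the 1/f background per channel
    sensor_noise_sd: float = 0.5   # white sensor noise sd (uV)
    source_amplitude: float = 1.0  # first-class RMS of each planted source
    class_labels: tuple = ("left", "right")
    seed: int = 0
    ramp_ms: float = 50.0

    def validate(self) -> None:
        if self.n_trials_per_class < 1 or self.n_channels < 1:
            raise ContractError("need >= 1 trial per class and >= 1 channel")
        if self.fs <= 0 or self.epoch_ms <= 0:
            raise ContractError("fs and epoch_ms must be positive")
        nyq = self.fs / 2.0
        for pc in self.planted_cells:
            if not (0 < pc.band.low_hz < pc.band.high_hz < nyq):
                raise ContractError(f"planted band {pc.band} violates Nyquist {nyq}")
            if pc.window.t_start < 0 or pc.window.t_end > self.epoch_ms:
                raise ContractError(f"planted window {pc.window} outside epoch")
            if len(pc.spatial_pattern) != self.n_channels:
                raise ContractError("spatial_pattern length != n_channels")
        if len(set(self.class_labels)) != 2:
            raise ContractError("need two distinct class labels")


@dataclass
class GroundTruth:
    """What was planted, for end-to-end recovery checks."""
    spec: SynthSpec
    class_amplitudes: list[tuple]  # per planted cell: (rms class0, rms class1)

    def planted_cell_indices(self, grid: TFGrid) -> list[int]:
        """Grid cell index of each planted (band, window), -1 if absent."""
        out = []
        for pc in self.spec.planted_cells:
            idx = -1
            for i in range(grid.n_cells):
                band, window = grid.cell(i)
                if band == pc.band and window == pc.window:
                    idx = i
                    break
            out.append(idx)
        return out


def _pink_noise(rng: np.random.Generator, shape: tuple, n_samples: int) -> np.ndarray:
    """Unit-RMS 1/f-amplitude-shaped Gaussian noise along the last axis."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** -0.5
    scale[0] = 0.0  # no DC
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(pink ** 2, axis=-1, keepdims=True))
    return pink / rms


def _envelope(n_samples: int, fs: float, window: WindowSpec, ramp_ms: float) -> np.ndarray:
    """Raised-cosine-edged gate over the window, 0 elsewhere."""
    t_ms = np.arange(n_samples) / fs * 1000.0
    env = np.zeros(n_samples)
    inside = (t_ms >= window.t_start) & (t_ms < window.t_end)
    env[inside] = 1.0
    ramp = max(ramp_ms, 1e-9)
    rise = inside & (t_ms < window.t_start + ramp)
    fall = inside & (t_ms >= window.t_end - ramp)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (t_ms[rise] - window.t_start) / ramp))
    env[fall] = 0.5 * (1 - np.cos(np.pi * (window.t_end - t_ms[fall]) / ramp))
    return env


def generate(spec: SynthSpec) -> tuple[EpochSet, GroundTruth]:
    """Draw a reproducible two-class EpochSet from the stated world."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_per = spec.n_trials_per_class
    n_trials = 2 * n_per
    n_samples = int(round(spec.epoch_ms / 1000.0 * spec.fs))

    labels = np.asarray([spec.class_labels[0]] * n_per + [spec.class_labels[1]] * n_per)
    data = spec.background * _pink_noise(rng, (n_trials, spec.n_channels), n_samples)
    data += spec.sensor_noise_sd * rng.standard_normal(data.shape)

    amplitudes = []
    for pc in spec.planted_cells:
        sos = signal.butter(5, [pc.band.low_hz, pc.band.high_hz],
                            btype="bandpass", fs=spec.fs, output="sos")
        env = _envelope(n_samples, spec.fs, pc.window, spec.ramp_ms)
        pattern = np.asarray(pc.spatial_pattern, dtype=float)
        a0 = spec.source_amplitude
        a1 = a0 * np.exp(pc.effect / 2.0)  # power ratio = exp(effect)
        amplitudes.append((a0, a1))
        src = signal.sosfiltfilt(sos, rng.standard_normal((n_trials, n_samples)), axis=-1)
        src /= np.sqrt(np.mean(src ** 2, axis=-1, keepdims=True))
        amp = np.where(labels == spec.class_labels[0], a0, a1)
        data += amp[:, None, None] * pattern[None, :, None] * (src * env)[:, None, :]

    order = rng.permutation(n_trials)
    epochs = EpochSet(
        data=data[order], labels=labels[order], fs=spec.fs,
        channel_names=[f"ch{i}" for i in range(spec.n_channels)], t0=0.0,
    )
    return epochs, GroundTruth(spec=spec, class_amplitudes=amplitudes)
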