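"""Temporal-spectral grid: overlapping frequency bands x time windows.

Motor-imagery information is band- and time-localized (event-related
desynchronization in mu/beta rhythms over a portion of the trial), so each
trial is decomposed into a grid of cells — every combination of an
overlapping bandpass filter and an overlapping time window — and CSP
features are extracted per cell. The reference configuration is 17 bands
(4-40 Hz, 4 Hz wide, 2 Hz step) crossed with five 2-s windows
(500-4500 ms, 500 ms step): 85 cells.

Cell ordering is row-major over (band, window):
``cell = band_index * n_windows + window_index``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .epochs import EpochSet
from .errors import InvalidGridError, TfbcspError
from .preprocess import bandpass_filter, crop_window

__all__ = ["BandSpec", "WindowSpec", "TFGrid", "make_band_grid",
           "make_window_grid", "decompose"]


@dataclass(frozen=True)
class BandSpec:
    """Frequency band edges in Hz."""
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise InvalidGridError(f"band low {self.low_hz} >= high {self.high_hz}")


@dataclass(frozen=True)
class WindowSpec:
    """Time-window bounds in ms, relative to trial onset."""
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise InvalidGridError(f"window start {self.t_start} >= end {self.t_end}")


@dataclass(frozen=True)
class TFGrid:
    """Ordered bands x windows; cell i = (i // n_windows, i % n_windows)."""
    bands: tuple[BandSpec, ...]
    windows: tuple[WindowSpec, ...]

    def __init__(self, bands, windows):
        object.__setattr__(self, "bands", tuple(bands))
        object.__setattr__(self, "windows", tuple(windows))

    @property
    def n_cells(self) -> int:
        return len(self.bands) * len(self.windows)

    def cell(self, index: int) -> tuple[BandSpec, WindowSpec]:
        band, window = divmod(index, len(self.windows))
        return self.bands[band], self.windows[window]

    def cell_index(self, band_index: int, window_index: int) -> int:
        return band_index * len(self.windows) + window_index


def _grid_1d(lo: float, hi: float, size: float, step: float, what: str) -> list[tuple[float, float]]:
    if not lo < hi:
        raise InvalidGridError(f"{what}: lo {lo} >= hi {hi}")
    if not 0 < size <= hi - lo:
        raise InvalidGridError(f"{what}: size {size} must be in (0, {hi - lo}]")
    if step <= 0:
        raise InvalidGridError(f"{what}: step must be positive, got {step}")
    span = hi - lo - size
    n_steps = span / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise InvalidGridError(
            f"{what}: range {hi - lo} minus size {size} is not divisible by step {step}"
        )
    n = int(round(n_steps)) + 1
    return [(lo + i * step, lo + i * step + size) for i in range(n)]


def make_band_grid(f_lo: float, f_hi: float, width: float, step: float) -> list[BandSpec]:
    """Overlapping bands from f_lo, advancing by ``step``; the last band
    ends exactly at f_hi. (4, 40, 4, 2) -> the 17-band reference bank."""
    return [BandSpec(a, b) for a, b in _grid_1d(f_lo, f_hi, width, step, "band grid")]


def make_window_grid(t_lo: float, t_hi: float, length: float, step: float) -> list[WindowSpec]:
    """Overlapping time windows (ms). (500, 4500, 2000, 500) -> 5 windows."""
    return [WindowSpec(a, b) for a, b in _grid_1d(t_lo, t_hi, length, step, "window grid")]


def decompose(epochs: EpochSet, grid: TFGrid, order: int = 5,
              filter_order_mode: str = "filter_first") -> list[EpochSet]:
    """Per-cell band-limited, time-windowed segments of every trial.

    Each cell yields one EpochSet: the band filter applied to the full
    epoch, then the window cropped (default). Filtering before cropping
    keeps the 2-s windows free of per-window filter edge transients;
    ``filter_order_mode="window_first"`` reproduces the crop-then-filter
    ordering for comparison.
    """
    if filter_order_mode not in ("filter_first", "window_first"):
        raise ValueError(f"unknown filter_order_mode {filter_order_mode!r}")
    out: list[EpochSet] = []
    if filter_order_mode == "filter_first":
        for band in grid.bands:
            try:
                banded = bandpass_filter(epochs, band.low_hz, band.high_hz, order)
            except TfbcspError as exc:
                raise type(exc)(f"band {band}: {exc}") from exc
            for window in grid.windows:
                try:
                    out.append(crop_window(banded, window.t_start, window.t_end))
                except TfbcspError as exc:
                    raise type(exc)(f"cell ({band}, {window}): {exc}") from exc
    else:
        for band in grid.bands:
            for window in grid.windows:
                try:
                    seg = crop_window(epochs, window.t_start, window.t_end)
                    out.append(bandpass_filter(seg, band.low_hz, band.high_hz, order))
                except TfbcspError as exc:
                    raise type(exc)(f"cell ({band}, {window}): {exc}") from exc
    return out
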