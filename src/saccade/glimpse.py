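"""Multi-resolution foveated glimpse extraction.

A glimpse is a stack of ``k`` patches sharing a focal location: the innermost
patch reads the signal at native resolution, and each successive scale covers a
window ``scale_factor`` times wider on each axis, reduced back to the base
patch size by block mean pooling.  Locations live in normalized continuous
coordinates ``[-1, +1]^2`` with ``(-1, -1)`` at the top-left (first channel,
first sample) corner and ``(0, 0)`` at the center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Location",
    "GlimpseConfig",
    "GlimpseStack",
    "normalize_location",
    "denormalize_location",
    "extract_glimpse",
    "extract_glimpse_multichannel",
]


@dataclass(frozen=True)
class Location:
    """A focal point in normalized coordinates.

    Coordinates are clipped into ``[-1, +1]`` on construction; non-finite
    input is rejected.  ``row`` indexes the row/channel axis and ``col`` the
    column/time axis.
    """

    row: float
    col: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.row) and math.isfinite(self.col)):
            raise ValueError(f"non-finite location ({self.row}, {self.col})")
        object.__setattr__(self, "row", float(np.clip(self.row, -1.0, 1.0)))
        object.__setattr__(self, "col", float(np.clip(self.col, -1.0, 1.0)))

    def as_array(self) -> np.ndarray:
        return np.array([self.row, self.col], dtype=np.float64)


@dataclass(frozen=True)
class GlimpseConfig:
    """Geometry of the multi-scale sensor.

    ``k`` scales; the scale-``s`` window spans
    ``base_rows * scale_factor**(s-1)`` by ``base_cols * scale_factor**(s-1)``
    source cells (``s = 1..k``).  Cells read outside the signal take
    ``pad_value``.
    """

    k: int = 3
    base_rows: int = 2
    base_cols: int = 7
    scale_factor: int = 2
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.base_rows < 1 or self.base_cols < 1:
            raise ValueError("base patch dimensions must be positive")
        if self.scale_factor < 2:
            raise ValueError(f"scale_factor must be >= 2, got {self.scale_factor}")

    @property
    def patch_size(self) -> int:
        """Flattened length of the full stack: k * base_rows * base_cols."""
        return self.k * self.base_rows * self.base_cols


@dataclass(frozen=True)
class GlimpseStack:
    """``k`` patches of identical base shape plus the location they came from."""

    patches: np.ndarray  # (k, base_rows, base_cols)
    source_location: Location = field(default_factory=lambda: Location(0.0, 0.0))

    def __post_init__(self) -> None:
        patches = np.asarray(self.patches, dtype=np.float64)
        if patches.ndim != 3:
            raise ValueError(f"patches must be 3-D (k, rows, cols), got {patches.shape}")
        object.__setattr__(self, "patches", patches)

    def flatten(self) -> np.ndarray:
        return self.patches.reshape(-1)


def normalize_location(index_pair: tuple[int, int], grid_shape: tuple[int, int]) -> Location:
    """Map integer grid indices to the normalized coordinates of the cell center.

    Cell ``i`` of an axis with ``n`` cells maps to ``2*(i + 0.5)/n - 1``, so the
    center cell of an odd-extent axis lands exactly at 0.
    """
    (i, j), (nr, nc) = index_pair, grid_shape
    if nr < 1 or nc < 1:
        raise ValueError(f"grid shape must be positive, got {grid_shape}")
    if not (0 <= i < nr and 0 <= j < nc):
        raise ValueError(f"index {index_pair} outside grid {grid_shape}")
    return Location(2.0 * (i + 0.5) / nr - 1.0, 2.0 * (j + 0.5) / nc - 1.0)


def denormalize_location(loc: Location, grid_shape: tuple[int, int]) -> tuple[int, int]:
    """Map normalized coordinates back to the nearest grid cell indices.

    Exact inverse of :func:`normalize_location` on cell centers.
    """
    nr, nc = grid_shape
    i = int(np.clip(math.floor((loc.row + 1.0) / 2.0 * nr), 0, nr - 1))
    j = int(np.clip(math.floor((loc.col + 1.0) / 2.0 * nc), 0, nc - 1))
    return i, j


def _read_window(
    signal: np.ndarray, r0: int, c0: int, nr: int, nc: int, pad_value: float
) -> np.ndarray:
    """Read a window with out-of-bounds cells filled with ``pad_value``."""
    out = np.full((nr, nc), pad_value, dtype=np.float64)
    nrows, ncols = signal.shape
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r0 + nr, nrows), min(c0 + nc, ncols)
    if rr0 < rr1 and cc0 < cc1:
        out[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0] = signal[rr0:rr1, cc0:cc1]
    return out


def _pool_rows(window: np.ndarray, out_rows: int) -> np.ndarray:
    """Mean-reduce the row axis into ``out_rows`` contiguous groups."""
    if window.shape[0] == out_rows:
        return window
    groups = np.array_split(window, out_rows, axis=0)
    return np.stack([g.mean(axis=0) for g in groups])


def _pool_cols(window: np.ndarray, out_cols: int) -> np.ndarray:
    if window.shape[1] == out_cols:
        return window
    groups = np.array_split(window, out_cols, axis=1)
    return np.stack([g.mean(axis=1) for g in groups], axis=1)


def _window_start(center: int, width: int) -> int:
    # even widths center at index - 0.5, i.e. ties lean toward the index origin
    return center - width // 2


def _extract(
    signal: np.ndarray,
    loc: Location,
    config: GlimpseConfig,
    clamp_rows: bool,
) -> GlimpseStack:
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 2 or signal.size == 0:
        raise ValueError(f"signal must be a non-empty 2-D array, got shape {signal.shape}")
    nrows, ncols = signal.shape
    ci, cj = denormalize_location(loc, (nrows, ncols))
    patches = np.empty((config.k, config.base_rows, config.base_cols), dtype=np.float64)
    for s in range(config.k):
        factor = config.scale_factor**s
        wr = config.base_rows * factor
        wc = config.base_cols * factor
        c0 = _window_start(cj, wc)
        if clamp_rows and wr > nrows:
            window = _read_window(signal, 0, c0, nrows, wc, config.pad_value)
        else:
            window = _read_window(signal, _window_start(ci, wr), c0, wr, wc, config.pad_value)
        patches[s] = _pool_cols(_pool_rows(window, config.base_rows), config.base_cols)
    return GlimpseStack(patches=patches, source_location=loc)


def extract_glimpse(signal: np.ndarray, loc: Location, config: GlimpseConfig) -> GlimpseStack:
    """Extract a ``k``-scale glimpse stack from a 2-D signal (image semantics).

    The scale-1 patch is the raw ``base_rows x base_cols`` window centered at
    the denormalized location; coarser scales cover wider windows and are
    reduced to base size by non-overlapping block mean pooling.
    """
    return _extract(signal, loc, config, clamp_rows=False)


def extract_glimpse_multichannel(
    signal: np.ndarray, loc: Location, config: GlimpseConfig
) -> GlimpseStack:
    """Extract a glimpse from a channels-by-time signal.

    Identical to :func:`extract_glimpse` except that scale windows wider than
    the channel extent are clamped to the full channel range before pooling
    (the channel axis is short compared to time for EEG-like inputs).
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 2:
        raise ValueError(f"signal must be 2-D channels x time, got shape {signal.shape}")
    if config.base_rows > signal.shape[0]:
        raise ValueError(
            f"base_rows {config.base_rows} exceeds channel count {signal.shape[0]}"
        )
    return _extract(signal, loc, config, clamp_rows=True)
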