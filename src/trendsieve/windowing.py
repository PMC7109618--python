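"""Fixed-size non-overlapping windowing and piecewise aggregate approximation.

The prediction horizon is partitioned into ``m = horizon / width`` half-open
windows ``[i*width, (i+1)*width)``; a timestamp exactly at the horizon falls
in the last window.  The piecewise aggregate approximation (PAA) replaces
each window with the arithmetic mean of its samples; empty windows are filled
by a configurable imputation policy (default: carry the last observed window
mean forward, and the first observed mean backward over leading gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import ChannelSeries, CohortError

#: Window widths (hours) supported by the study design for a 48 h horizon.
SUPPORTED_WIDTHS: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0, 8.0)


class WindowingError(CohortError):
    pass


@dataclass(frozen=True)
class WindowGrid:
    """Segmentation scheme: ``m = horizon / width`` consecutive windows."""

    horizon: float = 48.0
    width: float = 2.0
    allowed_widths: tuple[float, ...] | None = SUPPORTED_WIDTHS

    def __post_init__(self) -> None:
        if self.width <= 0 or self.horizon <= 0:
            raise WindowingError("horizon and width must be positive")
        m = self.horizon / self.width
        if abs(m - round(m)) > 1e-9:
            raise WindowingError(
                f"horizon {self.horizon} not divisible by width {self.width}"
            )
        if self.allowed_widths is not None and self.width not in self.allowed_widths:
            raise WindowingError(
                f"width {self.width} not in supported set {self.allowed_widths}"
            )

    @property
    def m(self) -> int:
        return int(round(self.horizon / self.width))

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.horizon, self.m + 1)


@dataclass
class WindowedSeries:
    """One channel segmented on a grid: a (times, values) pair per window."""

    grid: WindowGrid
    channel: str
    windows: list[tuple[np.ndarray, np.ndarray]]

    def counts(self) -> np.ndarray:
        return np.array([t.size for t, _ in self.windows], dtype=int)


@dataclass
class AverageSeries:
    """PAA output: one (imputed) mean per window plus the observed mask."""

    values: np.ndarray
    grid: WindowGrid
    observed: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))


def segment(series: ChannelSeries, grid: WindowGrid) -> WindowedSeries:
    """Assign every sample to its half-open window; ``t == horizon`` goes to
    the last window; samples beyond the horizon are an error (truncate first).
    """
    t = series.times
    v = series.values
    if t.size and t.max() > grid.horizon + 1e-9:
        raise WindowingError(
            f"sample at t={t.max():g} beyond horizon {grid.horizon:g} in {series.channel!r}"
        )
    idx = np.minimum(np.floor(t / grid.width).astype(int), grid.m - 1)
    windows = [(t[idx == i], v[idx == i]) for i in range(grid.m)]
    return WindowedSeries(grid=grid, channel=series.channel, windows=windows)


def paa(ws: WindowedSeries, imputation: str = "carry") -> AverageSeries:
    """Per-window means with empty windows filled per the imputation policy.

    Policies: ``"carry"`` (forward-fill, back-fill leading gaps) or
    ``"linear"`` (linear interpolation between observed window means,
    constant extrapolation at the ends).
    """
    m = ws.grid.m
    means = np.full(m, np.nan)
    for i, (_, v) in enumerate(ws.windows):
        if v.size:
            means[i] = v.mean()
    observed = ~np.isnan(means)
    if not observed.any():
        raise WindowingError(f"channel absent: {ws.channel!r} has no samples")
    if imputation == "carry":
        filled = means.copy()
        last = np.nan
        for i in range(m):
            if observed[i]:
                last = filled[i]
            else:
                filled[i] = last
        first = means[observed.argmax()]
        filled[np.isnan(filled)] = first
    elif imputation == "linear":
        obs_idx = np.flatnonzero(observed)
        filled = np.interp(np.arange(m), obs_idx, means[obs_idx])
    else:
        raise WindowingError(f"unknown imputation policy {imputation!r}")
    return AverageSeries(values=filled, grid=ws.grid, observed=observed)


__all__ = [
    "SUPPORTED_WIDTHS",
    "WindowGrid",
    "WindowedSeries",
    "AverageSeries",
    "WindowingError",
    "segment",
    "paa",
]
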