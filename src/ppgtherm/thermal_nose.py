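"""Nose-tip thermal variability extraction.

Sympathetic vasoconstriction cools the nose tip over tens of seconds, but
breathing superimposes a 0.1-0.85 Hz oscillation on any thermal-camera
readout of the nasal region.  The pipeline here removes the breathing band
with a zero-phase 7th-order Butterworth low-pass at 0.08 Hz (below the
breathing band's low edge), resamples to a regular 1 Hz grid to tame the
camera's unsteady frame rate, and min-max scales each window to [0, 1] so
absolute temperature offsets between people and sessions drop out.  The
filtered °C values on the same grid are retained for the signed
start-to-end temperature difference.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import InvalidInputError
from .signals import ThermalSeries, ThermalVariabilitySequence

__all__ = [
    "roi_mean",
    "remove_breathing",
    "variability_sequence",
    "extract_thermal",
]

#: Default low-pass cutoff (Hz), below the 0.1-0.85 Hz breathing band.
BREATHING_CUTOFF_HZ = 0.08
FILTER_ORDER = 7


def roi_mean(blocks, timestamps) -> ThermalSeries:
    """Per-frame spatial mean of nose-tip ROI pixel blocks.

    Fixed-ROI fallback for upstream trackers: each element of ``blocks`` is
    the pixel temperatures (°C) of one frame's region of interest.
    """
    means = []
    for i, block in enumerate(blocks):
        arr = np.asarray(block, dtype=float)
        if arr.size == 0:
            raise InvalidInputError(f"ROI block {i} is empty")
        means.append(arr.mean())
    return ThermalSeries(np.asarray(means), np.asarray(timestamps, dtype=float))


def remove_breathing(series: ThermalSeries,
                     cutoff_hz: float = BREATHING_CUTOFF_HZ) -> ThermalSeries:
    """Zero-phase low-pass filtering of the breathing oscillation.

    The series is first linearly interpolated onto a uniform grid at the
    median native frame rate (Butterworth filtering assumes uniform
    sampling), then filtered forward-backward with a 7th-order Butterworth
    low-pass so the result has no phase lag.  Returns the filtered series on
    the uniform grid.
    """
    if len(series) < 8 * FILTER_ORDER:
        raise InvalidInputError(
            f"need at least {8 * FILTER_ORDER} samples for stable zero-phase "
            f"filtering, got {len(series)}"
        )
    t = series.timestamps
    dt = float(np.median(np.diff(t)))
    rate = 1.0 / dt
    if cutoff_hz >= rate / 2.0:
        raise InvalidInputError(
            f"cutoff {cutoff_hz} Hz is not below the Nyquist rate {rate / 2:.3f} Hz"
        )
    n = int(np.floor((t[-1] - t[0]) / dt * (1.0 + 1e-9))) + 1
    grid = t[0] + np.arange(n) * dt
    uniform = np.interp(grid, t, series.temps)
    # second-order sections keep the narrow-band design numerically stable;
    # full-length odd extension preserves slow trends at the edges
    sos = butter(FILTER_ORDER, cutoff_hz, btype="low", fs=rate, output="sos")
    filtered = sosfiltfilt(sos, uniform, padlen=n - 1)
    return ThermalSeries(filtered, grid)


def variability_sequence(filtered: ThermalSeries
                         ) -> ThermalVariabilitySequence:
    """1 Hz resampling and per-window min-max scaling to [0, 1].

    The grid is anchored at the first timestamp with one sample per integer
    second; length equals ``floor(span)``.  A constant filtered series maps
    to all 0.5 (degenerate scaling) with a warning attached.
    """
    span = filtered.span
    if span < 5.0:
        raise InvalidInputError(f"span {span:.2f} s is below the 5 s minimum")
    n = int(np.floor(span))
    grid = filtered.timestamps[0] + np.arange(n, dtype=float)
    raw = np.interp(grid, filtered.timestamps, filtered.temps)
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        msg = "filtered series is constant; scaled values set to 0.5"
        warnings.warn(msg, stacklevel=2)
        scaled = np.full(n, 0.5)
        return ThermalVariabilitySequence(scaled, raw, t0=float(grid[0]),
                                          warning=msg)
    scaled = (raw - lo) / (hi - lo)
    return ThermalVariabilitySequence(scaled, raw, t0=float(grid[0]))


def extract_thermal(series: ThermalSeries,
                    cutoff_hz: float = BREATHING_CUTOFF_HZ
                    ) -> ThermalVariabilitySequence:
    """Compose breathing removal and 1 Hz variability extraction."""
    return variability_sequence(remove_breathing(series, cutoff_hz))
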