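"""Blood-volume-pulse extraction from finger-on-camera frame stacks.

The pulse is read out of the *spatial Shannon entropy* of each red-channel
frame rather than its mean brightness: blood inflow changes the spread of the
brightness histogram even when averaging washes the change out.  The negated
per-frame entropy is taken as the raw BVP, spline-upsampled to a uniform
256 Hz grid, amplitude-equalised by subtracting a k-sample moving average,
and peaks are picked as strict maxima of a 0.5 s sliding window.  Successive
peak-time differences are the PP intervals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ConfigurationError, InvalidInputError, PipelineStageError
from .signals import (
    BvpSignal,
    EntropySignal,
    FrameStack,
    PPIntervalSeries,
    PP_MAX_MS,
    PP_MIN_MS,
)

__all__ = [
    "PpgConfig",
    "spatial_entropy",
    "estimate_raw_bvp",
    "resample_uniform",
    "equalize_amplitude",
    "detect_pp_intervals",
    "extract_ppg",
]


@dataclass(frozen=True)
class PpgConfig:
    """Tunable knobs of the PPG pipeline.

    ``rate``: uniform resampling rate in samples/s. ``ma_window_s``: width of
    the moving average subtracted to equalise peak amplitudes.
    ``peak_window_s``: width of the sliding window whose strict maximum
    defines a peak. ``method``: 'entropy' (spatial-entropy BVP) or
    'mean_intensity' (the conventional baseline). ``equalize_before_resample``
    applies the moving-average subtraction on the native camera clock instead
    of the uniform grid.
    """

    rate: float = 256.0
    ma_window_s: float = 1.0
    peak_window_s: float = 0.5
    nbins: int = 256
    method: str = "entropy"
    validity_filter: bool = True
    equalize_before_resample: bool = False


def spatial_entropy(frame: np.ndarray, nbins: int = 256) -> float:
    """Shannon entropy (bits) of a frame's brightness histogram.

    The histogram always covers the full 8-bit range 0..255 with ``nbins``
    equal bins, regardless of the observed value range, so entropies are
    comparable across frames. ``0 * log 0`` terms are dropped.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise InvalidInputError("cannot compute entropy of an empty frame")
    if nbins < 2:
        raise InvalidInputError("nbins must be at least 2")
    if nbins == 256:
        counts = np.bincount(
            frame.astype(np.int64).ravel(), minlength=256
        ).astype(float)
    else:
        counts, _ = np.histogram(frame, bins=nbins, range=(0.0, 256.0))
        counts = counts.astype(float)
    p = counts[counts > 0] / frame.size
    return float(-np.sum(p * np.log2(p)) + 0.0)  # +0.0 avoids -0.0


def estimate_raw_bvp(stack: FrameStack, method: str = "entropy",
                     nbins: int = 256) -> EntropySignal:
    """Per-frame raw BVP series from a frame stack.

    ``method='entropy'`` returns the negated spatial entropy -H_t(X);
    ``method='mean_intensity'`` returns the spatial mean brightness, the
    conventional camera-PPG estimator kept as a comparison baseline.
    """
    if method == "entropy":
        values = np.array(
            [-spatial_entropy(f, nbins) for f in stack.frames]
        )
    elif method == "mean_intensity":
        values = stack.frames.reshape(len(stack), -1).mean(axis=1)
    else:
        raise ConfigurationError(
            f"unknown BVP method {method!r}; use 'entropy' or 'mean_intensity'"
        )
    return EntropySignal(values, stack.timestamps)


def resample_uniform(signal: EntropySignal, rate: float = 256.0) -> BvpSignal:
    """Cubic-spline interpolation onto a uniform grid spanning the record."""
    if len(signal) < 4:
        raise InvalidInputError("need at least 4 samples for spline resampling")
    t = signal.timestamps
    span = t[-1] - t[0]
    native_rate = (len(t) - 1) / span
    if rate < native_rate * (1.0 - 1e-9):
        raise InvalidInputError(
            f"target rate {rate} would downsample below the native rate "
            f"{native_rate:.1f}"
        )
    n_out = int(np.floor(span * rate * (1.0 + 1e-9))) + 1
    grid = t[0] + np.arange(n_out) / rate
    spline = CubicSpline(t, signal.values)
    return BvpSignal(spline(grid), rate=rate, t0=float(t[0]))


def _centered_moving_average(x: np.ndarray, k: int) -> np.ndarray:
    """Centered k-sample moving average with shrinking edge windows."""
    n = len(x)
    half_lo = (k - 1) // 2
    half_hi = k // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def equalize_amplitude(signal: BvpSignal, window_s: float = 1.0) -> BvpSignal:
    """Subtract the centered k-sample moving average (k = window_s * rate).

    Detrends the BVP so every heartbeat peak sits on a comparable baseline;
    edge windows shrink so the output keeps the input length.
    """
    if window_s <= 0:
        raise InvalidInputError("window_s must be positive")
    k = int(round(window_s * signal.rate))
    if k >= len(signal):
        raise InvalidInputError(
            f"moving-average window ({k} samples) must be shorter than the "
            f"signal ({len(signal)} samples)"
        )
    ma = _centered_moving_average(signal.values, k)
    return BvpSignal(signal.values - ma, rate=signal.rate, t0=signal.t0)


def detect_pp_intervals(bvp: BvpSignal, window_s: float = 0.5,
                        validity_filter: bool = True) -> PPIntervalSeries:
    """Local-maxima peak picking and PP interval measurement.

    A sample is a peak iff it is the strict maximum of the centered window of
    width ``window_s``; ties break toward the earlier sample, implying a
    minimum inter-peak distance of half the window.  Successive peak-time
    differences (in ms) are the PP intervals.  With ``validity_filter`` on,
    intervals outside the physiologic 500-1250 ms band are flagged invalid
    (kept in the series, excluded from features downstream).
    """
    x = bvp.values
    n = len(x)
    half = int(round(window_s * bvp.rate / 2.0))
    if half < 1:
        raise InvalidInputError("peak window shorter than two samples")
    peaks = []
    # candidates: samples equal to the window max (cheap pre-filter)
    from scipy.ndimage import maximum_filter1d

    winmax = maximum_filter1d(x, size=2 * half + 1, mode="nearest")
    for i in np.flatnonzero(x >= winmax):
        if i < half or i >= n - half:
            continue  # edge samples have no full centered window
        w = x[i - half:i + half + 1]
        # strict max with ties broken toward the earlier sample
        if np.all(w[:half] < x[i]) and np.all(w[half + 1:] <= x[i]):
            peaks.append(i)
    if len(peaks) < 2:
        msg = f"found {len(peaks)} peak(s); need at least 2 for PP intervals"
        warnings.warn(msg, stacklevel=2)
        return PPIntervalSeries.empty(warning=msg)
    peak_times = bvp.t0 + np.asarray(peaks) / bvp.rate
    intervals = np.diff(peak_times) * 1000.0
    if validity_filter:
        valid = (intervals >= PP_MIN_MS) & (intervals <= PP_MAX_MS)
    else:
        valid = np.ones(len(intervals), dtype=bool)
    return PPIntervalSeries(intervals, peak_times, valid)


def extract_ppg(stack: FrameStack, config: PpgConfig = PpgConfig()
                ) -> tuple[BvpSignal, PPIntervalSeries]:
    """Full frame-stack -> (BVP, PP intervals) pipeline.

    Stages: per-frame estimator (entropy negated, or mean intensity) ->
    256 Hz spline resampling -> moving-average equalisation -> windowed
    local-maxima peak detection.  Stage failures are re-raised with the stage
    name attached.
    """
    stages: list[tuple[str, object]] = []

    def run(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineStageError(stage, exc) from exc

    raw = run("estimate_raw_bvp", estimate_raw_bvp, stack,
              config.method, config.nbins)
    if config.equalize_before_resample:
        # moving average on the native clock; k from the median frame rate
        native_rate = 1.0 / float(np.median(np.diff(raw.timestamps)))
        k = max(2, int(round(config.ma_window_s * native_rate)))
        if k >= len(raw):
            raise PipelineStageError(
                "equalize_amplitude",
                InvalidInputError("moving-average window exceeds record"),
            )
        raw = EntropySignal(
            raw.values - _centered_moving_average(raw.values, k),
            raw.timestamps,
        )
        bvp = run("resample_uniform", resample_uniform, raw, config.rate)
    else:
        bvp = run("resample_uniform", resample_uniform, raw, config.rate)
        bvp = run("equalize_amplitude", equalize_amplitude, bvp,
                  config.ma_window_s)
    pp = run("detect_pp_intervals", detect_pp_intervals, bvp,
             config.peak_window_s, config.validity_filter)
    return bvp, pp
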