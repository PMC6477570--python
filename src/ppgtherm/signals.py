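"""Domain containers for the multimodal cardiovascular pipeline.

All containers are thin frozen views over numpy arrays with the invariants a
20-second smartphone measurement window implies: frame stacks are ordered and
time-stamped, uniformly sampled signals carry an explicit rate and origin,
and peak-to-peak (PP) interval series keep per-interval physiologic validity
flags so downstream features can ignore artefactual beats.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

#: Physiologic PP-interval range in ms: 48-120 beats per minute.
PP_MIN_MS = 500.0
PP_MAX_MS = 1250.0


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class FrameStack:
    """Time-stamped stack of single-channel 8-bit frames (red channel).

    Parameters
    ----------
    frames : ndarray, shape (n, h, w)
        Brightness values in 0..255.
    timestamps : ndarray, shape (n,)
        Capture times in seconds, strictly increasing.
    """

    frames: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self):
        frames = np.asarray(self.frames)
        ts = _as_float_array(self.timestamps, "timestamps")
        if frames.ndim != 3:
            raise InvalidInputError(
                f"frames must be (n, h, w), got shape {frames.shape}"
            )
        if len(frames) < 2:
            raise InvalidInputError("a frame stack needs at least 2 frames")
        if len(frames) != len(ts):
            raise InvalidInputError("frames and timestamps must have equal length")
        if np.any(np.diff(ts) <= 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        if frames.min() < 0 or frames.max() > 255:
            raise InvalidInputError("frame values must lie in 0..255")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "timestamps", ts)

    @property
    def span(self) -> float:
        """Recording span in seconds."""
        return float(self.timestamps[-1] - self.timestamps[0])

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class EntropySignal:
    """Per-frame scalar series (entropy in bits, negated entropy, or mean
    brightness) on the native, possibly irregular, camera clock."""

    values: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self):
        v = _as_float_array(self.values, "values")
        t = _as_float_array(self.timestamps, "timestamps")
        if len(v) != len(t):
            raise InvalidInputError("values and timestamps must have equal length")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "timestamps", t)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BvpSignal:
    """Uniformly sampled blood-volume-pulse signal.

    ``values`` are dimensionless amplitudes, ``rate`` in samples/s, ``t0``
    the absolute time of the first sample in seconds.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        v = _as_float_array(self.values, "values")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("BVP values must be finite")
        if self.rate <= 0:
            raise InvalidInputError("rate must be positive")
        object.__setattr__(self, "values", v)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.rate

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PPIntervalSeries:
    """Peak-to-peak intervals in ms with one peak time (s) per detected peak.

    ``intervals[i]`` is the gap between ``peak_times[i]`` and
    ``peak_times[i+1]``; ``valid[i]`` flags intervals inside the physiologic
    500-1250 ms band. ``warning`` carries a human-readable reason when the
    series is empty (fewer than two peaks found).
    """

    intervals: np.ndarray
    peak_times: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    warning: str | None = None

    def __post_init__(self):
        iv = _as_float_array(self.intervals, "intervals")
        pt = _as_float_array(self.peak_times, "peak_times")
        if len(pt) and len(iv) != len(pt) - 1:
            raise InvalidInputError("need exactly one interval per peak pair")
        if np.any(iv <= 0):
            raise InvalidInputError("intervals must be positive")
        valid = self.valid
        if valid is None:
            valid = (iv >= PP_MIN_MS) & (iv <= PP_MAX_MS)
        valid = np.asarray(valid, dtype=bool)
        if len(valid) != len(iv):
            raise InvalidInputError("valid flags must match interval count")
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "peak_times", pt)
        object.__setattr__(self, "valid", valid)

    @classmethod
    def empty(cls, warning: str | None = None) -> "PPIntervalSeries":
        return cls(np.empty(0), np.empty(0), np.empty(0, dtype=bool), warning)

    @property
    def valid_intervals(self) -> np.ndarray:
        return self.intervals[self.valid]

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class ThermalSeries:
    """Nose-tip ROI mean temperature (°C) on a possibly irregular clock."""

    temps: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self):
        temps = _as_float_array(self.temps, "temps")
        ts = _as_float_array(self.timestamps, "timestamps")
        if len(temps) != len(ts):
            raise InvalidInputError("temps and timestamps must have equal length")
        if len(temps) and np.any(np.diff(ts) <= 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(temps)):
            raise InvalidInputError("temperatures must be finite")
        if len(temps) and (temps.min() < 10.0 or temps.max() > 45.0):
            warnings.warn(
                "temperatures outside the plausible skin range 10-45 °C",
                stacklevel=2,
            )
        object.__setattr__(self, "temps", temps)
        object.__setattr__(self, "timestamps", ts)

    @property
    def span(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def __len__(self) -> int:
        return len(self.temps)


@dataclass(frozen=True)
class ThermalVariabilitySequence:
    """1 Hz, min-max-scaled, respiration-filtered thermal variability.

    ``values`` are dimensionless in [0, 1] (all 0.5 for a constant window);
    ``raw_filtered`` keeps the filtered °C values on the same 1 Hz grid so the
    signed start-to-end temperature difference can be computed in °C.
    """

    values: np.ndarray
    raw_filtered: np.ndarray
    t0: float = 0.0
    rate: float = 1.0
    warning: str | None = None

    def __post_init__(self):
        v = _as_float_array(self.values, "values")
        r = _as_float_array(self.raw_filtered, "raw_filtered")
        if len(v) != len(r):
            raise InvalidInputError("scaled and raw series must have equal length")
        if len(v) and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise InvalidInputError("scaled values must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "raw_filtered", r)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.rate

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class MeasurementWindow:
    """One 20-second multimodal recording tied to a participant and session."""

    participant_id: str
    session_id: str
    pp: PPIntervalSeries | None = None
    tv: ThermalVariabilitySequence | None = None
    vas: float | None = None
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pp is None and self.tv is None:
            raise InvalidInputError("a window needs at least one modality")
        if self.vas is not None and not 0.0 <= self.vas <= 10.0:
            raise InvalidInputError("VAS score must lie in [0, 10]")
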