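"""Relative power signal quality index (pSQI).

pSQI is the fraction of a signal's spectral power that falls inside an
expected physiological band: integrated PSD over [f_low, f_high] divided by
the total PSD over (0, Nyquist].  Values near 1 mean the record is dominated
by the rhythm of interest.  Two standard configurations are provided: the
cardiac band 0.8-2.0 Hz (48-120 bpm, after a 0.7-4.0 Hz band-pass that
strips baseline wander and high-frequency noise) and the respiratory band
0.1-0.85 Hz (no prefilter).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, periodogram, sosfiltfilt, welch

from .errors import InvalidInputError, UndefinedRatioError
from .signals import BvpSignal

__all__ = [
    "BandSpec",
    "CARDIAC_BAND",
    "RESPIRATORY_BAND",
    "psqi",
    "cardiac_psqi",
    "respiratory_psqi",
]


@dataclass(frozen=True)
class BandSpec:
    """A physiological frequency band with an optional band-pass prefilter."""

    f_low: float
    f_high: float
    prefilter_low: float | None = None
    prefilter_high: float | None = None

    def __post_init__(self):
        if not 0 < self.f_low < self.f_high:
            raise InvalidInputError("need 0 < f_low < f_high")
        has_lo, has_hi = self.prefilter_low is not None, self.prefilter_high is not None
        if has_lo != has_hi:
            raise InvalidInputError("prefilter needs both edges or neither")
        if has_lo and not (self.prefilter_low <= self.f_low
                           and self.f_high <= self.prefilter_high):
            raise InvalidInputError("prefilter band must contain [f_low, f_high]")

    @property
    def has_prefilter(self) -> bool:
        return self.prefilter_low is not None


#: Expected heart-rate band 48-120 bpm with the baseline-wander prefilter.
CARDIAC_BAND = BandSpec(0.8, 2.0, prefilter_low=0.7, prefilter_high=4.0)
#: Healthy-adult breathing band.
RESPIRATORY_BAND = BandSpec(0.1, 0.85)

#: Welch segment length in seconds (one segment of a 20 s record, 50% overlap).
WELCH_SEGMENT_S = 10.0


def _psd(x: np.ndarray, rate: float, estimator: str):
    if estimator == "welch":
        nperseg = min(len(x), int(round(WELCH_SEGMENT_S * rate)))
        return welch(x, fs=rate, nperseg=nperseg, detrend="constant")
    if estimator == "periodogram":
        # Hann window: boxcar leakage from below-band drifts would swamp
        # the narrow respiratory band on short records
        return periodogram(x, fs=rate, window="hann", detrend="constant")
    raise InvalidInputError(f"unknown PSD estimator {estimator!r}")


def psqi(signal, rate: float, band: BandSpec,
         estimator: str = "welch") -> float:
    """Relative in-band spectral power, in [0, 1].

    The mean is removed before PSD estimation so DC cannot inflate the
    denominator; band power is the trapezoid integral over PSD bins whose
    centers fall in [f_low, f_high], the total over all positive
    frequencies.  When the band carries a prefilter, the signal is band-pass
    filtered (zero-phase Butterworth) first.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 32:
        raise InvalidInputError("need a 1-D signal of at least 32 samples")
    if band.f_high >= rate / 2.0:
        raise InvalidInputError("band must lie below the Nyquist frequency")
    x = x - x.mean()
    if band.has_prefilter:
        hi = min(band.prefilter_high, 0.99 * rate / 2.0)
        sos = butter(4, [band.prefilter_low, hi], btype="band",
                     fs=rate, output="sos")
        x = sosfiltfilt(sos, x)
    freqs, psd = _psd(x, rate, estimator)
    pos = freqs > 0
    total = np.trapezoid(psd[pos], freqs[pos])
    if total <= 0 or not np.isfinite(total):
        raise UndefinedRatioError("signal has no spectral power")
    in_band = pos & (freqs >= band.f_low) & (freqs <= band.f_high)
    if in_band.sum() < 2:
        raise InvalidInputError("fewer than 2 PSD bins fall inside the band")
    band_power = np.trapezoid(psd[in_band], freqs[in_band])
    return float(np.clip(band_power / total, 0.0, 1.0))


def cardiac_psqi(bvp: BvpSignal, estimator: str = "welch") -> float:
    """pSQI of a BVP signal in the 0.8-2.0 Hz heart-rate band."""
    return psqi(bvp.values, bvp.rate, CARDIAC_BAND, estimator)


def respiratory_psqi(thermal, rate: float, estimator: str = "welch") -> float:
    """pSQI of a uniform thermal series in the 0.1-0.85 Hz breathing band."""
    values = getattr(thermal, "temps", thermal)
    return psqi(values, rate, RESPIRATORY_BAND, estimator)
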