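"""Hand-engineered pulse-rate-variability and thermal features.

Six PRV features from the PP intervals — LF power, HF power, LF/HF ratio,
SDPP, RMSSD, pPP50 — and three thermal features from the variability
sequence — TD (signed start-to-end temperature difference in °C, negative
when the nose tip cools), SDSTV and SDTV.  These are the classical
"high-level" descriptors the low-level learned representation is compared
against.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.signal import periodogram

from .errors import InvalidInputError
from .signals import PPIntervalSeries, ThermalVariabilitySequence

__all__ = [
    "PrvFeatureVector",
    "ThermalFeatureVector",
    "prv_features",
    "thermal_features",
    "LF_BAND",
    "HF_BAND",
]

#: Classical spectral HRV bands (Hz).
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Tachogram interpolation rate (Hz) for spectral PRV.
TACHOGRAM_RATE = 4.0

MIN_INTERVALS_TIME_DOMAIN = 4
MIN_INTERVALS_FREQ_DOMAIN = 8


@dataclass(frozen=True)
class PrvFeatureVector:
    """PRV features; entries are NaN when too few valid intervals exist."""

    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    sdpp: float
    rmssd: float
    ppp50: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @property
    def missing(self) -> bool:
        return bool(np.any(np.isnan(self.as_array())))


@dataclass(frozen=True)
class ThermalFeatureVector:
    """Thermal features; ``warning`` propagates degenerate-window notices."""

    td: float
    sdstv: float
    sdtv: float
    warning: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.td, self.sdstv, self.sdtv])


def _band_power(freqs: np.ndarray, psd: np.ndarray,
                band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        return float("nan")
    return float(np.trapezoid(psd[mask], freqs[mask]))


def prv_features(pp: PPIntervalSeries,
                 ppp50_denominator: str = "intervals",
                 normalized_power: bool = False) -> PrvFeatureVector:
    """Compute the six PRV features from valid PP intervals.

    Time-domain features need >= 4 valid intervals, spectral features >= 8;
    below that the corresponding entries are NaN (missing), never zero.
    SDPP is the sample (n-1) standard deviation; RMSSD the root mean square
    of successive differences; pPP50 the count of absolute successive
    differences exceeding 50 ms divided by the number of intervals
    (``ppp50_denominator='differences'`` selects the conventional pNN50
    denominator).  LF/HF powers come from the PSD of the tachogram linearly
    interpolated at 4 Hz over the beat-time axis; ``normalized_power``
    divides both by their sum.
    """
    if ppp50_denominator not in ("intervals", "differences"):
        raise InvalidInputError(
            f"unknown pPP50 denominator {ppp50_denominator!r}"
        )
    iv = pp.valid_intervals
    nan = float("nan")
    sdpp = rmssd = ppp50 = nan
    if len(iv) >= MIN_INTERVALS_TIME_DOMAIN:
        sdpp = float(np.std(iv, ddof=1))
        diffs = np.diff(iv)
        rmssd = float(np.sqrt(np.mean(diffs**2)))
        over = int(np.sum(np.abs(diffs) > 50.0))
        denom = len(iv) if ppp50_denominator == "intervals" else len(diffs)
        ppp50 = over / denom
    lf = hf = ratio = nan
    if len(iv) >= MIN_INTERVALS_FREQ_DOMAIN:
        # tachogram: interval value at the time of its closing beat
        beat_times = pp.peak_times[1:][pp.valid]
        order = np.argsort(beat_times)
        bt, bi = beat_times[order], iv[order]
        span = bt[-1] - bt[0]
        n = int(math.floor(span * TACHOGRAM_RATE)) + 1
        if n >= 16:
            grid = bt[0] + np.arange(n) / TACHOGRAM_RATE
            tach = np.interp(grid, bt, bi)
            freqs, psd = periodogram(tach, fs=TACHOGRAM_RATE,
                                     detrend="constant")
            lf = _band_power(freqs, psd, LF_BAND)
            hf = _band_power(freqs, psd, HF_BAND)
            if normalized_power and np.isfinite(lf) and np.isfinite(hf):
                total = lf + hf
                if total > 0:
                    lf, hf = lf / total, hf / total
            ratio = lf / hf if hf and np.isfinite(hf) and hf > 0 else nan
    return PrvFeatureVector(lf, hf, ratio, sdpp, rmssd, ppp50)


def thermal_features(tv: ThermalVariabilitySequence) -> ThermalFeatureVector:
    """Compute TD, SDSTV and SDTV from a thermal variability sequence.

    TD is end-minus-start of the retained *filtered °C* series (a
    temperature difference, so the [0,1] scaling must not touch it); the two
    standard deviations are computed on the scaled sequence.
    """
    if len(tv) < 3:
        raise InvalidInputError("need at least 3 samples for thermal features")
    td = float(tv.raw_filtered[-1] - tv.raw_filtered[0])
    sdstv = float(np.std(np.diff(tv.values), ddof=1))
    sdtv = float(np.std(tv.values, ddof=1))
    return ThermalFeatureVector(td, sdstv, sdtv, warning=tv.warning)
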