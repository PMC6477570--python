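"""Synthetic study inputs: pulse-rendered frame stacks, thermal series, and
a multi-participant scored cohort with planted stress effects.

The generators emulate the three raw inputs of a 20-second multimodal
measurement so the full pipeline is testable without recordings:

* ``generate_rr`` plants a beat-to-beat PP interval series (stationary AR(1)
  with SDPP / RMSSD calibrated analytically).
* ``render_ppg_frames`` draws red-channel frames whose brightness-histogram
  *spread* — hence spatial entropy — pulses with the planted beats while the
  spatial mean stays flat, so only the entropy estimator carries the pulse.
  A mean-modulated variant encodes the pulse in the mean instead.
* ``simulate_thermal`` superimposes breathing oscillation, a vasoconstriction
  cooling trend and noise on an irregular camera clock.
* ``generate_cohort`` lazily yields a 17-participant, 6-session study with
  planted stress structure: under stress RMSSD drops, the nose-tip cooling
  trend steepens, mean pulse quickens, and the self-reported VAS rises with
  participant-specific bias and range compression.

Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .signals import FrameStack, PPIntervalSeries, ThermalSeries

__all__ = [
    "RRParams",
    "ThermalSimConfig",
    "CohortConfig",
    "CohortWindow",
    "generate_rr",
    "render_ppg_frames",
    "simulate_thermal",
    "generate_cohort",
    "SESSION_STRESS",
]


@dataclass(frozen=True)
class RRParams:
    """Targets for the planted PP-interval series (ms / s)."""

    mean_rr: float = 850.0
    sdpp_target: float = 50.0
    rmssd_target: float = 40.0
    duration: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not 500.0 <= self.mean_rr <= 1250.0:
            raise InvalidInputError("mean_rr must lie in [500, 1250] ms")
        if self.sdpp_target < 0 or self.rmssd_target < 0:
            raise InvalidInputError("variability targets must be >= 0")
        if self.duration <= 0:
            raise InvalidInputError("duration must be positive")


def generate_rr(params: RRParams) -> PPIntervalSeries:
    """Planted PP intervals from a stationary AR(1) interval model.

    For AR(1) with lag-1 correlation rho and marginal SD sigma,
    SDPP = sigma and RMSSD = sigma * sqrt(2 (1 - rho)); the targets are
    inverted analytically (rho = 1 - rmssd^2 / (2 sdpp^2)), so realized
    sample statistics track the targets up to sampling noise.  RMSSD targets
    above 2*SDPP are infeasible for this family.  Intervals are clipped to
    the physiologic 500-1250 ms band.
    """
    s, r = params.sdpp_target, params.rmssd_target
    if s == 0.0:
        if r > 0.0:
            raise InvalidInputError("rmssd target requires nonzero sdpp target")
        rho = 1.0
    else:
        rho = 1.0 - r * r / (2.0 * s * s)
        if rho < -1.0:
            raise InvalidInputError(
                f"infeasible targets: rmssd {r} exceeds the 2*sdpp bound {2 * s}"
            )
    rng = np.random.default_rng(params.seed)
    total_ms = params.duration * 1000.0
    n_max = int(np.ceil(total_ms / 500.0)) + 2
    if rho >= 1.0 - 1e-12:
        intervals = np.full(n_max, params.mean_rr + s * rng.standard_normal())
    else:
        sigma_e = s * np.sqrt(1.0 - rho * rho)
        x = np.empty(n_max)
        x[0] = params.mean_rr + s * rng.standard_normal()
        eps = sigma_e * rng.standard_normal(n_max - 1)
        for i in range(1, n_max):
            x[i] = params.mean_rr + rho * (x[i - 1] - params.mean_rr) + eps[i - 1]
        intervals = x
    intervals = np.clip(intervals, 500.0, 1250.0)
    # keep beats inside the recording span
    csum = np.cumsum(intervals)
    keep = int(np.searchsorted(csum, total_ms))
    intervals = intervals[:max(keep, 1)]
    peak_times = np.concatenate(([0.0], np.cumsum(intervals) / 1000.0))
    return PPIntervalSeries(intervals, peak_times)


def _pulse_waveform(t: np.ndarray, beat_times: np.ndarray,
                    width_s: float) -> np.ndarray:
    """Sum of Gaussian bumps centered on the beat instants, peak height 1."""
    pulse = np.zeros_like(t)
    for tb in beat_times:
        near = np.abs(t - tb) < 5.0 * width_s
        pulse[near] += np.exp(-((t[near] - tb) ** 2) / (2.0 * width_s**2))
    return pulse


def render_ppg_frames(rr: PPIntervalSeries, fps: float = 30.0,
                      frame_shape: tuple[int, int] = (96, 96),
                      modulation_depth: float = 0.5, seed: int = 0,
                      mean_modulated: bool = False,
                      pulse_width_s: float = 0.12,
                      base_spread: float = 24.0,
                      lead_s: float = 0.4) -> FrameStack:
    """Render a frame stack whose spatial entropy pulses with the beats.

    Each frame is ``128 + s(t) * z`` with ``z`` a fresh zero-mean unit-SD
    noise field and ``s(t) = base_spread * (1 - depth * pulse(t))``: at each
    beat the histogram narrows, entropy dips, and the negated-entropy BVP
    peaks exactly at the planted beat time.  The spatial mean stays at 128,
    so mean-intensity PPG sees (almost) nothing.  ``mean_modulated=True``
    instead encodes the pulse in the mean at fixed spread — the variant on
    which both estimators succeed.  Beats are shifted ``lead_s`` into the
    record so the first peak is detectable.
    """
    if fps < 20:
        raise InvalidInputError("fps must be at least 20")
    if not 0.0 < modulation_depth <= 1.0:
        raise ConfigurationError("modulation_depth must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    beat_times = rr.peak_times + lead_s
    duration = beat_times[-1] + lead_s
    n_frames = int(np.floor(duration * fps)) + 1
    t = np.arange(n_frames) / fps
    pulse = _pulse_waveform(t, beat_times, pulse_width_s)
    h, w = frame_shape
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for i in range(n_frames):
        z = rng.standard_normal(h * w)
        z = (z - z.mean()) / z.std()
        if mean_modulated:
            level = 128.0 + 12.0 * modulation_depth * pulse[i]
            spread = base_spread
        else:
            level = 128.0
            spread = base_spread * (1.0 - modulation_depth * pulse[i])
        frames[i] = np.clip(np.round(level + spread * z), 0, 255
                            ).reshape(h, w).astype(np.uint8)
    return FrameStack(frames, t)


@dataclass(frozen=True)
class ThermalSimConfig:
    """Nose-tip temperature simulation parameters.

    ``trend_slope`` in °C/s and ``trend_curvature`` in °C/s² (negative =
    vasoconstriction cooling; curvature models its gradual onset);
    ``breathing_hz`` must lie inside the 0.1-0.85 Hz breathing band;
    ``timestamp_jitter_sd`` models the camera's unsteady frame rate.
    """

    base_temp: float = 34.0
    breathing_hz: float = 0.3
    breathing_amp: float = 0.1
    trend_slope: float = 0.0
    trend_curvature: float = 0.0
    noise_sd: float = 0.01
    timestamp_jitter_sd: float = 0.005
    nominal_fps: float = 9.0
    duration: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not 0.1 <= self.breathing_hz <= 0.85:
            raise InvalidInputError(
                "breathing_hz must lie in the 0.1-0.85 Hz breathing band"
            )
        if self.duration < 10.0:
            raise InvalidInputError("duration must be at least 10 s")
        if self.noise_sd < 0 or self.breathing_amp < 0:
            raise InvalidInputError("amplitudes must be >= 0")


def simulate_thermal(config: ThermalSimConfig) -> ThermalSeries:
    """Breathing + cooling-trend + noise temperature series, jittered clock."""
    rng = np.random.default_rng(config.seed)
    # overshoot the nominal duration slightly so the downstream 1 Hz grid
    # (length = floor(span)) covers the full window even after jitter
    n = int(np.ceil(config.duration * config.nominal_fps)) + 2
    t = np.arange(n) / config.nominal_fps
    if config.timestamp_jitter_sd > 0:
        t = t + config.timestamp_jitter_sd * rng.standard_normal(n)
        t = np.sort(t)
        t -= t[0]
        # enforce strict monotonicity after jitter
        eps = 1e-6
        t = np.maximum.accumulate(t + eps * np.arange(n))
    temps = (config.base_temp
             + config.trend_slope * t
             + config.trend_curvature * t**2
             + config.breathing_amp * np.sin(2 * np.pi * config.breathing_hz * t)
             + config.noise_sd * rng.standard_normal(n))
    return ThermalSeries(temps, t)


#: Mean latent stress level by session type (rest < easy < hard).
SESSION_STRESS = {
    "Rest1": 0.10, "Rest2": 0.10,
    "Se": 0.40, "Me": 0.40,
    "Sh": 0.80, "Mh": 0.80,
}


@dataclass(frozen=True)
class CohortConfig:
    """Planted-effect study design (17 participants x 6 sessions).

    Effect sizes at full stress (latent level 1): ``rmssd_decrement`` is the
    fraction by which RMSSD shrinks, ``slope_decrement`` the °C/s cooling
    trend, ``mean_rr_decrement_ms`` the pulse quickening, ``vas_increment``
    the VAS rise in cm.  ``vas_bias_sd`` / ``vas_range_sd`` control
    participant-specific self-report bias and range compression.
    """

    n_participants: int = 17
    sessions: tuple[str, ...] = ("Rest1", "Se", "Sh", "Rest2", "Me", "Mh")
    rmssd_decrement: float = 0.5
    slope_decrement: float = 0.05
    slope_noise_sd: float = 0.01
    mean_rr_decrement_ms: float = 150.0
    vas_increment: float = 7.0
    vas_bias_sd: float = 1.0
    vas_range_sd: float = 1.0
    vas_noise_sd: float = 0.15
    stress_noise_sd: float = 0.06
    base_rmssd: float = 55.0
    base_sdpp: float = 60.0
    base_mean_rr: float = 900.0
    frame_shape: tuple[int, int] = (48, 48)
    fps: float = 30.0
    duration: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 3:
            raise InvalidInputError("need at least 3 participants")
        if min(self.rmssd_decrement, self.slope_decrement,
               self.vas_increment, self.mean_rr_decrement_ms) < 0:
            raise InvalidInputError("effect sizes must be >= 0")
        unknown = set(self.sessions) - set(SESSION_STRESS)
        if unknown:
            raise InvalidInputError(f"unknown session ids: {sorted(unknown)}")


@dataclass
class CohortWindow:
    """Raw inputs plus ground truth for one participant-session window."""

    participant_id: str
    session_id: str
    frames: FrameStack
    thermal: ThermalSeries
    vas: float
    latent_stress: float
    true_label: int
    planted_rr: PPIntervalSeries = field(repr=False, default=None)  # type: ignore[assignment]


def generate_cohort(config: CohortConfig) -> Iterator[CohortWindow]:
    """Yield one fully rendered window per participant-session.

    Lazy by design: a full cohort holds ~100 frame stacks, so windows are
    generated (deterministically, from ``config.seed``) as they are consumed.
    Latent stress is the session mean plus participant-session noise, clipped
    to [0, 1]; it drives the PP-interval targets, the thermal cooling trend
    and the VAS self-report.  ``true_label`` is 1 where latent stress
    exceeds 0.5 (hard sessions, in the main).
    """
    root = np.random.default_rng(config.seed)
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        vas_bias = config.vas_bias_sd * root.standard_normal()
        vas_range = max(2.0, config.vas_increment
                        + config.vas_range_sd * root.standard_normal())
        for session in config.sessions:
            stress = float(np.clip(
                SESSION_STRESS[session]
                + config.stress_noise_sd * root.standard_normal(), 0.0, 1.0))
            rmssd = config.base_rmssd * (1.0 - config.rmssd_decrement * stress)
            sdpp = config.base_sdpp * (1.0 - 0.5 * config.rmssd_decrement * stress)
            mean_rr = config.base_mean_rr - config.mean_rr_decrement_ms * stress
            seed_rr, seed_frames, seed_thermal = root.integers(0, 2**31, size=3)
            rr = generate_rr(RRParams(mean_rr, sdpp, rmssd,
                                      config.duration, int(seed_rr)))
            frames = render_ppg_frames(rr, fps=config.fps,
                                       frame_shape=config.frame_shape,
                                       seed=int(seed_frames))
            # half the stress cooling is linear, half accelerates
            # (gradual vasoconstriction onset): same net drop, different shape
            slope = (-0.5 * config.slope_decrement * stress
                     + config.slope_noise_sd * root.standard_normal())
            curvature = (-0.5 * config.slope_decrement * stress
                         / config.duration)
            thermal = simulate_thermal(ThermalSimConfig(
                trend_slope=slope, trend_curvature=curvature,
                duration=config.duration, seed=int(seed_thermal)))
            vas = float(np.clip(
                2.0 + vas_bias + vas_range * (stress - 0.1)
                + config.vas_noise_sd * root.standard_normal(), 0.0, 10.0))
            yield CohortWindow(pid, session, frames, thermal, vas, stress,
                               int(stress > 0.5), rr)
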