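# Methods

`ppgtherm` implements a 20-second perceived-stress detection
pipeline built on two low-cost smartphone imaging channels: fingertip
photoplethysmography (PPG) through the phone camera, and nose-tip
temperature from an add-on thermal camera. This note documents the models,
the numerical choices, and what the synthetic data generator does and does
not emulate.

## Spatial-entropy blood-volume pulse

With a fingertip pressed on the camera, each red-channel frame is a noisy
image whose brightness *distribution* is modulated by blood volume in the
capillaries. The conventional estimator — the spatial mean of the frame —
discards distributional changes. We instead compute the Shannon entropy of
the per-frame brightness histogram,

    H_t(X) = − Σ_x p(x) log2 p(x),

with a 256-bin histogram over the full 8-bit range (bins fixed regardless of
the observed range so entropies are comparable across frames; `0·log 0 = 0`).
The raw BVP sample at time *t* is `−H_t(X)`: blood inflow narrows the
histogram, entropy dips, and the negated entropy peaks once per beat.

The per-frame series (native camera clock, ~30 fps, possibly irregular) is

1. cubic-spline resampled to a uniform 256 Hz grid — a high rate makes the
   subsequent peak-time quantisation error small (±3.9 ms);
2. amplitude-equalised by subtracting a centered k-sample moving average
   with a 1.0 s window (k = 256 at 256 Hz). One second covers at least one
   beat of any physiologic rhythm, so the subtraction levels the baseline
   under every peak without erasing the beat itself. Edge windows shrink so
   the output keeps the input length;
3. peak-picked: a sample is a peak iff it is the strict maximum of the
   centered 0.5 s window, ties broken toward the earlier sample, and edge
   samples (no full window) are excluded. This implies a minimum inter-peak
   distance of 0.25 s.

Successive peak times give the PP intervals in ms. A validity filter flags
intervals outside 500–1250 ms (48–120 bpm); flagged intervals stay in the
series but are excluded from features. Fewer than two peaks yields an empty
series with a warning status rather than an exception, so a batch run can
log and skip degenerate windows.

Two orderings of steps 2 and 3 are defensible (the moving average could be
applied on the native clock before resampling); we equalise after
resampling, where "k samples" has a well-defined meaning in seconds on a
uniform grid. The alternative is available via
`PpgConfig(equalize_before_resample=True)`.

## Nose-tip thermal variability

Sympathetic vasoconstriction cools the nose tip over tens of seconds;
breathing adds a 0.1–0.85 Hz oscillation. The input contract is a
time-stamped ROI-mean temperature series (tracking the ROI in thermal video
is out of scope; `roi_mean` is the fixed-ROI fallback). Processing:

1. linear interpolation onto a uniform grid at the median native frame rate
   (the thermal camera's frame rate is unsteady, and IIR filtering assumes
   uniform sampling);
2. zero-phase (forward–backward) 7th-order Butterworth low-pass at
   0.08 Hz — just below the breathing band's low edge — implemented in
   second-order sections because the narrow normalized band makes the
   transfer-function form ill-conditioned. Padding uses full-length odd
   extension so slow trends survive the record edges. The net amplitude
   response is |H(f)|² = 1/(1 + (f/0.08)^14);
3. linear interpolation at integer seconds from the first timestamp
   (length = floor(span)) — the 1 Hz grid defines "successive temperature
   differences" on regular steps;
4. per-window min–max scaling to [0, 1], removing between-person and
   between-session temperature offsets. A constant window maps to all 0.5
   with a warning. The filtered °C values on the same grid are retained,
   because the temperature-difference feature is a difference in °C, not in
   scaled units.

Scaling after downsampling (rather than before) makes the scaled extrema
exactly 0 and 1 on the grid the features see.

## Signal quality (pSQI)

The power signal quality index is the fraction of spectral power inside an
expected physiological band: ∫ PSD over [f_L, f_U] divided by the total over
(0, Nyquist]. The mean is removed first so DC cannot inflate the
denominator. Two standard configurations:

* cardiac: band 0.8–2.0 Hz (48–120 bpm), after a 0.7–4.0 Hz zero-phase
  band-pass (4th-order Butterworth) that strips baseline wander and
  high-frequency noise;
* respiratory: band 0.1–0.85 Hz, no prefilter.

The PSD estimator is Welch with a 10 s Hann segment and 50% overlap by
default (variance reduction on 20 s records); a full-length Hann-windowed
periodogram is available via `estimator="periodogram"`. The periodogram is
the right choice when the quantity of interest is the *separation of
below-band power from the band* — e.g. judging breathing removal, where the
0.08 Hz cutoff sits one Welch bin away from the 0.1 Hz band edge. Note that
distinguishing sub-0.08 Hz energy from the 0.1 Hz edge requires a spectral
resolution finer than 0.02 Hz, i.e. ≥ 50 s of data; breathing-removal
assessments in the tests therefore use 60 s records, while the 20 s
measurement windows themselves are never assessed this way. Band
integration is by trapezoid over PSD bins whose centers fall in the band,
boundary bins included.

## Engineered features

From the valid PP intervals (n ≥ 4 for time domain, ≥ 8 for spectral;
otherwise the entry is NaN — missing, never zero):

* SDPP: sample (n−1) standard deviation of the intervals (ms);
* RMSSD: root mean square of successive differences (ms);
* pPP50: count of |successive difference| > 50 ms divided by the number of
  *intervals* (a config flag selects the conventional
  number-of-differences denominator);
* LF and HF power (ms²): the tachogram (interval value at the time of its
  closing beat) is linearly interpolated at 4 Hz over the beat-time axis
  and a full-length periodogram integrated over 0.04–0.15 Hz and
  0.15–0.40 Hz; LF/HF is their ratio. Absolute powers are reported by
  default with normalized powers available by config. On a 20 s record the
  LF resolution is acknowledged to be marginal (≈ 2–3 LF-band bins); no
  sliding window is used.

From the thermal variability sequence:

* TD (°C): last − first of the retained filtered °C series; negative
  means nose-tip cooling, the stress signature;
* SDSTV: sample SD of successive differences of the scaled sequence;
* SDTV: sample SD of the scaled sequence.

Mean heart rate is deliberately not an engineered feature.

## Labeling

Self-reports are on a 10 cm visual analog scale (VAS). Per participant,
scores are min–max normalized to [0, 1] (zero-range participants are an
error naming the participant), then all participants' normalized scores are
pooled and clustered with an exact 1-D k-means: dynamic programming over
contiguous partitions of the sorted values, O(k n²) with prefix sums —
deterministic, globally SSE-optimal, no initialization sensitivity, cheap at
n ≈ 100. Clusters are indexed by ascending centroid. Strategies:

* L1: k = 3, lowest cluster → NoStress, upper two → Stress (the main
  strategy);
* L2: k = 3, lower two clusters → NoStress;
* L3: k = 2, lower cluster → NoStress;
* L4: raw (unnormalized) VAS threshold at exactly 10/3 cm — the scale cut
  into three equal sections, the lowest being NoStress.

Pooling scope: clustering is applied jointly to all participants'
normalized scores (not per participant); a per-participant variant would be
a straightforward sensitivity analysis.

## Classifiers and evaluation

Low-level feature rows are fixed-length encodings: PP intervals linearly
interpolated over beat index to 40 points (ms), the scaled thermal sequence
truncated/edge-padded to 20 points; multimodal rows concatenate both (60
columns). Interpolation is preferred over zero-padding because padding
injects spurious magnitude structure.

The neural networks are single-hidden-layer sigmoid networks (80 hidden
units = NN1, 260 = NN2) with a single sigmoid output, binary cross-entropy
loss and a 0.5 decision threshold. Training is plain per-sample SGD at a
fixed learning rate of 0.5 for 100 epochs, samples reshuffled each epoch;
weights start uniform(−0.1, 0.1) from the given seed. Inputs are z-scored
by the *training* split's mean/SD, stored in the model and applied verbatim
to test data; constant columns pass through unscaled. The benchmark is a
1-nearest-neighbour classifier on the nine engineered features (Euclidean
distance on the same z-scored features; ties go to the earliest training
row).

Evaluation is leave-one-subject-out (LOSO): one fold per participant, train
on the rest, test on the held-out participant. Reports carry per-fold
accuracy, mean and SD, a confusion matrix accumulated over folds, and mean
F1 — macro-averaged over the two classes within each fold, then averaged
over folds, skipping (and logging) folds where macro F1 is undefined
because a class is absent and never predicted. Named sessions (e.g.
`Rest1`) can be excluded before folding. The whole pipeline is
bit-reproducible given data and seed; per-fold NN seeds are derived as
`seed + fold_index`.

## Synthetic data generator

The generator produces the three raw inputs with planted ground truth.

**PP intervals** are a stationary AR(1) sequence: for marginal SD σ and
lag-1 correlation ρ, SDPP = σ and RMSSD = σ√(2(1−ρ)), so target (SDPP,
RMSSD) pairs are inverted analytically. RMSSD > 2·SDPP is infeasible for
this family (it would need ρ < −1) and raises an error. Intervals are
clipped to 500–1250 ms.

**Frame stacks**: each frame is `128 + s(t)·z` with `z` a fresh zero-mean,
unit-SD noise field and `s(t) = 24·(1 − 0.5·pulse(t))`, where `pulse` is a
train of Gaussian bumps (σ = 0.12 s) at the planted beat times. The
histogram spread — hence entropy — pulses with the heartbeat while the
spatial mean stays at 128, so the entropy estimator, not the mean, carries
the pulse; a mean-modulated variant exercises the case where both succeed.
The 0.12 s bump width concentrates spectral power at the cardiac
fundamental (harmonics fall outside the 0.8–2.0 Hz band) the way a smooth
systolic upstroke does; default frames are 96×96 (≈ 9200 pixels), enough
that histogram-sampling noise in the entropy (≈ 0.01 bits) is small against
the ≈ 1-bit beat modulation.

**Thermal series**: base temperature + linear trend + quadratic term +
breathing sinusoid + white noise, on a jittered ~9 fps clock. The quadratic
term models the gradual onset of vasoconstriction (cooling accelerates over
the window).

**Cohort**: 17 participants × 6 sessions (Rest1, Stroop-easy, Stroop-hard,
Rest2, Math-easy, Math-hard). Each window draws a latent stress level
(session mean 0.1 / 0.4 / 0.8 for rest / easy / hard, participant-session
noise SD 0.06, clipped to [0, 1]) which drives:

* RMSSD: 55 ms at rest, halved at full stress (SDPP 60 ms, reduced at half
  that rate so the pair stays feasible);
* mean PP: 900 ms at rest, −150 ms at full stress (pulse quickening —
  visible to the low-level sequence encoding but deliberately absent from
  the engineered feature set, which excludes heart-rate-level features);
* nose-tip cooling: a net −0.05 °C/s × stress drop split half linear, half
  accelerating, plus an ambient drift noise (slope SD 0.01 °C/s) of the
  kind uncontrolled room-temperature changes produce;
* VAS: participant-specific bias (SD 1 cm) and range (≈ 7 ± 1 cm),
  within-session noise SD 0.15 cm, clipped to [0, 10] — interpersonal
  reporting variability that per-participant normalization must absorb.

The defaults are the "strongly planted" study conditions used by the
acceptance checks. Cohort frames default to 48×48 to keep a full 102-window
study extractable in a few seconds; the entropy noise penalty raises PP
recovery error from ≈ 2 ms to ≈ 5 ms, which the classifiers tolerate.

What the generator does **not** emulate: motion artifacts and ambient-light
changes beyond timestamp jitter, realistic PPG waveform morphology
(dicrotic notch), respiratory sinus arrhythmia coupling between channels,
ROI-tracking failures, or multi-day nonstationarity. Passing tests
demonstrate that the pipeline recovers planted structure through the
stated observation models — not that these effect sizes match any real
population.

## Numerical choices and degenerate inputs

* Histograms: 256 bins over 0..255 always; entropy of an empty frame is an
  error, a constant frame gives exactly 0 bits.
* Spline resampling requires ≥ 4 samples; resampling below the native rate
  is rejected; the uniform grid length uses a 1e-9 relative tolerance in
  the floor to avoid float flakiness at exact spans.
* The moving-average window must be shorter than the signal.
* Zero-phase filtering needs ≥ 56 samples (8× the filter order).
* pSQI of an identically-zero signal raises an undefined-ratio error;
  amplitude scaling leaves pSQI invariant by construction.
* k-means requires at least k distinct values; pPP50 of all-equal intervals
  is 0; a constant thermal window yields TD = 0 and all-0.5 scaled values.
* LOSO requires ≥ 3 participants and ≥ 2 classes in every training split.

## Problem sizes used in the checks

The acceptance checks run the full pipeline at the study's native scale
(17 participants × 6 sessions, 20 s windows at 30 fps): 10 cohort seeds for
the ordering claims in the test suite, 5 in the standalone script; 20
rendered stacks for PP recovery in the suite, 10 in the script; 60 s
records for breathing-removal assessment (spectral resolution, above).
These sizes keep the whole suite in the minutes range on one CPU while
leaving the per-window problem exactly as the method defines it.

## Known limitations

* LF/HF on 20 s windows is low-resolution by construction; treat it as a
  rough index, not a validated sympathovagal measure.
* The exact k-means is O(k n²); fine for hundreds of scores, not for
  millions (Lloyd's algorithm or the SMAWK-based O(k n) DP would be the
  scalable substitutes).
* The NN training regime (per-sample SGD, lr 0.5, sigmoid) is faithful to
  the method being implemented rather than to modern practice; it is
  sensitive to feature scaling, which is why the train-split z-scoring is
  part of the model contract.
* `remove_breathing` assumes the median frame rate is representative; a
  camera that alternates between two very different rates would need
  explicit resampling first.
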