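# ppgtherm

Perceived-stress inference from 20-second smartphone photoplethysmography
(PPG) and nose-tip thermal measurements.

Long physiological recordings are impractical on phones: a fingertip must
stay on the camera, the flash LED heats up, and people move. `ppgtherm`
implements a pipeline that works from a single **20-second** multimodal
measurement — red-channel camera frames with a fingertip on the lens, plus
a nose-tip temperature sequence from an add-on thermal camera — and infers
a binary perceived-stress state that generalises across people. It is aimed
at researchers in mobile health and psychophysiology who want a fully
scripted, reproducible reference implementation of this measurement model,
including a synthetic-data generator so every stage is testable without any
recordings.

## The method

**Spatial-entropy BVP.** Instead of the conventional mean-brightness PPG,
the blood-volume pulse is read from the Shannon entropy of each frame's
brightness histogram:

    BVP(t) = −H_t(X),   H_t(X) = − Σ_x p(x) log₂ p(x)

(256-bin histogram of the 8-bit red channel). Blood inflow changes the
brightness *distribution* even when averaging hides it. The per-frame
series is spline-resampled to 256 Hz, equalised by subtracting a 1 s
moving average, and peaks are strict maxima of a 0.5 s sliding window;
successive peak times give the PP intervals (the PPG analogue of RR
intervals), validity-filtered to 500–1250 ms.

**Thermal variability.** Stress-induced vasoconstriction cools the nose
tip, but breathing (0.1–0.85 Hz) contaminates the measurement. A zero-phase
7th-order Butterworth low-pass at 0.08 Hz removes it; the series is then
resampled at 1 Hz and min–max scaled per window.

**Signal quality.** The power signal quality index
pSQI = ∫_band PSD / ∫ PSD ∈ [0, 1] quantifies each channel: cardiac band
0.8–2.0 Hz (after a 0.7–4.0 Hz band-pass), respiratory band 0.1–0.85 Hz.

**Features and models.** Nine engineered features (LF, HF, LF/HF, SDPP,
RMSSD, pPP50; TD, SDSTV, SDTV) feed a 1-nearest-neighbour benchmark, while
single-hidden-layer sigmoid networks (80 or 260 hidden units, per-sample
SGD, lr 0.5, 100 epochs) learn directly from the low-level sequences.
Self-reports on a 10-cm visual analog scale are normalized per participant
and labelled by an exact 1-D k-means (strategies L1–L4). Everything is
evaluated under 17-fold leave-one-subject-out cross-validation.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

`examples/01_extract_ppg.py` plants a beat sequence, renders 20 s of
synthetic fingertip frames, and runs the extraction pipeline:

```text
planted 24 intervals, mean 814.8 ms
recovered 24 intervals (24 valid)
mean absolute recovery error: 1.56 ms (one 256 Hz sample = 3.91 ms)
cardiac pSQI of the extracted BVP: 0.929 (fraction of power in the
0.8-2.0 Hz heart-rate band; 1 = clean)
```

The planted beat-to-beat intervals come back with sub-sample error, and
>90% of the extracted signal's power sits in the heart-rate band.
`examples/02_thermal_variability.py` shows the breathing-removal mirror
(respiratory pSQI 0.953 raw → 0.000 filtered on a 60 s record, with the
planted cooling trend preserved as TD = −0.27 °C);
`examples/04_cohort_loso.py` runs a full 17-participant synthetic study and
prints the LOSO accuracies of the NN and kNN models per modality.

A thin CLI mirrors the stages:

```bash
ppgtherm simulate ppg --seed 1 --out sim/
ppgtherm extract-ppg --frames sim/ --out out/
ppgtherm quality --in out/bvp.csv --mode cardiac --out q.json
ppgtherm loso --model nn2 --modality multi --seed 7 --out report.json
```

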