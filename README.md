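# pcg-emotion

A toolkit for emotion recognition from heart-sound (phonocardiogram, PCG)
recordings. It covers the full pipeline:

1. **synth** — synthetic labeled PCG corpora: per-emotion AR(1) RR-interval
   and lognormal diastole/systole-ratio (DS) dynamics, rendered as WAV
   waveforms (Gaussian-windowed S1/S2 tone bursts plus white noise) with
   ground-truth boundary annotations.
2. **preprocess** — zero-phase Butterworth low-pass filtering, normalized
   Shannon-energy envelopes, and a quality gate rejecting aperiodic,
   broadband-noisy or clipped recordings.
3. **segment** — S1/S2 boundary detection on the envelope (adaptive
   threshold lobes, interval-alternation labeling, duration-constrained
   correction), emitting paired onset/offset arrays (`thb`/`tha`, length 2N
   for N cycles).
4. **indicators** — heart-sound HRV (successive S1-midpoint differences)
   and heart-sound DSV (per-cycle diastole/systole ratio), plus ECG RR for
   comparison.
5. **features** — time-domain, Lomb–Scargle frequency-domain and
   lagged-Poincaré (SD1/SD2/SD12, lags 1–22) features: 79 per RR series,
   75 per DS series, 154 combined.
6. **classify** — Russell-circumplex label mapping (valence / arousal /
   four-class), GA-wrapped feature selection with top-20% aggregation over
   repeated runs, RBF-SVM c/g grid tuning, stratified 5-fold evaluation.

## CLI

```bash
pcg-emotion synth    --seed 1 --out out                      # write corpus
pcg-emotion extract  --corpus out/corpus --out out/features  # feature matrices
pcg-emotion classify --features out/features --out out/cls   # GA-SVM models
pcg-emotion all      --seed 1 --out out                      # full pipeline
```

All commands accept `--config cfg.yaml` overriding the defaults in
`pcg_emotion.config.DEFAULT_CONFIG` (unknown keys are rejected). Every
output directory receives the resolved config and a provenance record;
reruns with identical inputs and seeds are byte-identical.

Example config:

```yaml
synth:
  counts: {relaxed: 43, happy: 21, sad: 18, angry: 14}
  segment_seconds: 150.0
classify:
  tasks: [valence, arousal, four_class]
  n_runs: 30
  ga: {population: 30, generations: 50}
```

`classify` writes a comparison table (rows = indicator blocks, columns =
tasks, entries = 5-fold CV accuracy in percent), per-model JSON artifacts
(selected subset, weights, c/g, seeds, confusion metrics) and per-run GA
fitness traces as CSV.

## Library use

```python
from pcg_emotion import (DEFAULT_PROFILES, sample_interval_series, render_pcg,
                         PcgRecording, lowpass, shannon_envelope, segment_pcg,
                         hs_hrv, hs_dsv, feature_block)

prof = DEFAULT_PROFILES["relaxed"].with_beats(61)
rr, ds = sample_interval_series(prof, seed=1)
wave, truth = render_pcg(rr, ds, rate=2000.0, snr_db=20.0, seed=1)
rec = lowpass(PcgRecording(samples=wave, rate=2000.0))
seg = segment_pcg(rec, shannon_envelope(rec))
features = feature_block(hs_hrv(seg))   # 79 named values
```
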