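# wakemap

Spatio-temporal EEG analysis of the transition from sleep to
wakefulness.  The package maps, second by second around the moment a
sleeper starts to move (or an alarm sounds), how spectral power in the
canonical sleep bands rises and travels across the scalp and the
cortical source space — and relates those dynamics to how sleepy
people say they feel on waking.

It is written for sleep/EEG researchers who want the full analysis
chain as tested, reusable code: a synthetic high-density-EEG generator
stands in for clinical recordings, so every stage can be exercised and
validated without patient data.

## What it computes

* **Band-power peak dynamics.**  FFT power on non-overlapping 1-s
  epochs in delta (1–4 Hz), theta (5–7), alpha (8–11.5), sigma
  (12–16) and beta (18–29.5 Hz), normalized per subject to an
  eyes-closed quiet-wakefulness reference.  Per-trial peaks are maxima
  exceeding background (−45 to −30 s) mean + 2 SD.  In NREM
  awakenings, low-frequency power peaks first (delta near −1 s),
  followed by alpha (≈0 s) and beta (≈+6 s); in REM, only beta shows a
  well-defined group peak (≈+8 s).
* **Source-space latency maps.**  A Tikhonov-regularized sLORETA
  inverse (λ = 10⁻², toy spherical head) projects scalp data onto a
  source grid; per voxel, the latency of maximum band power in a
  −10…+45 s window is ranked and mapped to a 1–10 scale, with
  group-median maps and two randomization controls.  Anterior-leading
  latency gradients are recovered as strong negative correlations
  between rank and the anterior–posterior coordinate.
* **Slow waves.**  Zero-crossing detection (mastoid reference, 128 Hz,
  Chebyshev-II 0.5–4 Hz band-pass) of negative half-waves with
  durations 0.25–1 s; densities, amplitudes, slopes and negative-peak
  counts per analysis window, split at 75 µV peak-to-peak into large
  (type-I / K-complex-like) and small (type-II) waves.
* **Statistics.**  Per-unit linear mixed models (random intercepts for
  subject and time-of-night bin) with Wald statistics
  `W = (β̂/SE)²`, corrected family-wise by within-subject
  cluster permutation: clusters of adjacent units with p < .05 are
  scored by ΣW / cluster size against the 95th percentile of the
  max-cluster null from within-subject response shuffles.  Stage
  effects on sleepiness use a likelihood-ratio test with Holm-corrected
  pairwise contrasts.

## Worked example

```python
import numpy as np
from wakemap.fixtures import fixture
from wakemap.preprocessing import preprocess
from wakemap.spectral import band_power, channel_mean, detect_band_peak

cohort = fixture("nrem_spontaneous_74", seed=1)   # 74 NREM awakenings
latencies = {"delta": [], "alpha": [], "beta": []}
for trial in cohort:
    tc = channel_mean(band_power(preprocess(trial)), layout=cohort.layout)
    for band in latencies:
        ev = detect_band_peak(tc, band)           # > background mean + 2 SD
        if ev.detected:
            latencies[band].append(ev.latency)
for band, lat in latencies.items():
    print(band, len(lat), np.median(lat))
```

prints

```
delta 71 -0.5
alpha 74 -0.5
beta 72 5.5
```

i.e. delta peaks are detected in 71 of 74 trials with a median latency
half an epoch before movement onset, alpha peaks around onset, and
beta peaks about six seconds after — the low-before-high frequency
sequence of the NREM awakening, at the 1-s epoch resolution of the
band-power time courses.

The same pipeline is scriptable from the shell:

```sh
wakemap all --seed 1 --out runs/demo        # simulate → … → report
```

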