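# Methods

## Analysis model

Trials are 120-s multichannel epochs at 500 Hz, centered on an
alignment event at t = 0 (movement onset for spontaneous awakenings,
alarm onset for provoked ones, EEG shift onset for arousals).  All
scalp analyses run on band-passed (0.5–45 Hz, zero-phase Butterworth)
and average-referenced data; mastoid and EMG channels never enter
scalp statistics.

**Band power.**  Discrete Fourier transform on non-overlapping 1-s
epochs, rectangular window.  With 1-Hz bin spacing the band edges
(delta 1–4, theta 5–7, alpha 8–11.5, sigma 12–16, beta 18–29.5 Hz)
fall on bin centers; a bin belongs to a band when its center lies in
[lo, hi] inclusive, so a sinusoid of amplitude A at a bin center
contributes A²/2.  Epochs tile the trial from −60 s, putting an epoch
boundary exactly at t = 0; epoch timestamps are bin centers, which is
why a transient at −1 s is reported at −0.5 or −1.5 s — the epoch grid
cannot resolve better than ±0.5 s.  Wake normalization divides each
channel × band value by the subject's eyes-closed resting mean
(ratio 1 = wake level); the time-frequency display path uses natural
log followed by per-channel/band z-scoring over epochs.

**Peak detection.**  Per trial and band, background mean m and SD s
come from the −45…−30 s window of the innermost-channel-average time
course; the maximum inside the search window (default −15…+15 s,
configurable) is a peak iff it exceeds m + 2s; ties resolve to the
first occurrence.  A *group* peak additionally has to clear the wake
reference: the group-median peak ratio must exceed 1.2 and a one-sided
paired test across subjects must put the peak above wake (p < .05).
The 20% margin operationalizes "well-defined increase above waking
levels"; without it, any band that merely *reaches* its wake level
after the transition (alpha, typically) would qualify on the sleep
criterion alone.

**Source space.**  The toy head is a unit sphere with radial dipoles
on an interior Fibonacci grid (default 300 sources, central core and
lower hemisphere excluded); gains are infinite-medium dipole
potentials — deliberately minimal physics, as the inverse only needs a
full-rank, geometrically plausible lead field.  The inverse is
standardized minimum norm (sLORETA): K = Gᵀ(GGᵀ + λcI)⁻¹ with
c = trace(GGᵀ)/n_channels so λ = 10⁻² is dimensionless, an
average-reference projector on the channel side, and each source
estimate divided by the square root of its resolution-matrix diagonal.
Because the resolution matrix is positive semidefinite, noiseless
point sources localize exactly for any λ — the property the test
suite asserts for every grid source.  Numerical parity with commercial
source-localization software is explicitly not a goal.

**Latency maps.**  Per unit (voxel or channel), the latency of maximum
band power within −10…+45 s (first occurrence on ties), then
average-ranking and the affine map 1 + 9(rank−1)/(V−1) onto 1–10.
Per-trial maps are averaged within subject before the group median —
the intermediate step is a package decision; rank maps are invariant
under any strictly monotone latency transform.  Two controls:
the same machinery on a pre-awakening sleep window (−45…−30 s), and
the median of 19 rank maps of i.i.d. uniform latencies, which
concentrates at the scale midpoint 5.5.

**Slow waves.**  Mastoid-average reference, polyphase resample to
128 Hz, zero-phase Chebyshev-II band-pass (pass 0.5–4 Hz, stop edges
0.1/10 Hz, minimum order reaching 20 dB stop-band attenuation, 0.5 dB
pass-band loss).  Events are negative half-waves between a down-going
and the next up-going zero crossing (linear-interpolated crossing
times), kept iff the duration lies in [0.25, 1] s.  Parameters:
signed negative-peak amplitude, slopes zc1→trough (negative) and
trough→zc2 (positive), count of sub-zero local minima, and
peak-to-peak amplitude pairing the trough with the maximum positive
value before the next down-going crossing (the p2p pairing is a
package decision).  Waves with p2p ≥ 75 µV are "large"
(type-I/K-complex-like).  Window aggregation uses half-open windows
[start, end) keyed by trough time over −45…−30, −30…−5, −5…0, 0…5,
5…30 s; empty windows have density 0 and undefined means.  An
optional detector-internal amplitude floor exists and defaults to 0.

**Mixed models and cluster permutation.**  Per unit, sleepiness (1–5)
is modeled on one EEG feature with random intercepts for subject and
time-of-night bin (thirds of the observed range — a continuous
variable cannot act as a grouping factor verbatim; binning is
configurable).  The Wald statistic is (β̂/SE)².  Family-wise
correction: units with p < .05 form connected clusters in the
adjacency graph (channel neighborhood, source grid, or the epoch
chain); cluster score = ΣWald / size; the null shuffles the response
within subjects and refits every unit per permutation, keeping each
permutation's maximum |score|; observed clusters are significant above
the empirical 95th percentile.  Two fitters implement the per-unit
model: statsmodels MixedLM with crossed variance components (the
reference, used for single fits), and an exact GLS whose subject
variance ratio is REML-profiled on the intercept-only model with
time-of-night bins absorbed as fixed dummies — vectorized across
units, which is what makes per-permutation refits affordable.  The two
agree closely on estimates and standard errors (asserted in the test
suite); the permutation layer, not Wald asymptotics, carries the final
inference.  Paired time-course and window comparisons use the same
clustering with sign-flip permutations of subject-wise differences and
ΣT²/size scores.  Stage effects on sleepiness use an ML
likelihood-ratio χ² (df = stages − 1, reported transparently) with
Holm-corrected pairwise Wald contrasts; time of night can enter as a
fixed covariate.

## Synthetic data: what it emulates, and what it does not

The generator produces stage-appropriate backgrounds (NREM: 1/f noise,
an amplitude-modulated 1.25-Hz delta oscillation, periodic 13-Hz
spindle bursts; REM: weaker 1/f plus 6-Hz activity), a smoothstep
crossfade over the first 4 s after t0 into a wake profile (9-Hz alpha,
broadband beta, 1/f floor), per-band Tukey-windowed band-limited
bursts at configurable latent latencies with a linear
anterior→posterior latency gradient, biphasic inserted slow waves
(negative-then-positive half-waves, trough = 0.6 × p2p), EMG channels
with optional 100–245 Hz activation from t0, per-subject eyes-closed
wake references drawn from the same wake profile, and sleepiness
ratings from a stated linear model (stage intercept − b_beta ·
z(pre-onset beta) + b_delta · z(post-onset delta) + subject intercept
+ noise, rounded and clipped to 1–5).  Rating-model features are
standardized *within stage*: absolute band power differs grossly
between stages (post-onset delta carry-over in NREM), and the stage
effect is specified through the intercepts, not through feature
confounds.

Two generator choices are deliberate idealizations rather than
physiology:

* **Bounded background power modulation.**  Epoch-to-epoch band-power
  variation of the sleep background is dominated by a shared
  sinusoidal power modulation (depth 0.4, period 5 s) rather than by
  the heavy-tailed χ² fluctuation of unstructured noise.  The 2-SD
  peak rule compares a 30-epoch search maximum against 15 background
  epochs; on an unstructured background that maximum exceeds
  mean + 2 SD about half the time regardless of scale, and no
  transient-presence bookkeeping could survive.  The bounded
  modulation keeps the false-alarm rate of the detector near zero, so
  fixture composition (which trials carry which transients) is
  recoverable.  Consequently, passing detection tests certify the
  pipeline's behavior under controlled peak structure — not the
  detector's false-alarm rate on real sleep EEG.
* **Cross-channel incoherence.**  Oscillations carry per-channel
  random phases and band noise is channel-independent, so average
  referencing is approximately power-preserving.  Real EEG has
  substantial cross-channel coherence; the average reference then
  removes common-mode signal, and absolute power levels on real data
  will differ from the synthetic case.

Not emulated at all: realistic head-tissue conductivity, sleep
microstructure (cyclic alternating pattern), ocular/cardiac artifacts,
and inter-subject anatomical variability.  Passing tests therefore
validate algorithmic correctness and statistical calibration, not
clinical performance.

## Fixtures and problem sizes

The study-condition fixtures pin their composition exactly:
`nrem_spontaneous_74` (74 trials — 55 N2, 19 N3 — over 19 subjects;
69 trials with both delta and beta transients, 63 of those
delta-first at −1 s vs +6 s and 6 delta-late at +8 s; 3 beta-only,
2 delta-only; alpha at 0 s throughout) and `rem_spontaneous_37`
(37 REM trials over 17 subjects, beta at +8 s, no delta/alpha
transient).  The gradient cohort uses 12 subjects × 2 trials with an
anterior-leading 4-s beta-latency slope on a 300-source grid.  The
slow-wave fixture inserts steep canonical waves (p2p 100–140 µV,
negative half-wave 0.45–0.65 s) into a quiet light-N2 background
(5-µV delta oscillation, 6-µV 1/f): against a full-amplitude
background, superposed delta shifts filtered trough times by about
0.1 s — a physical effect, not a detector defect — which would defeat
trough-level truth matching.  Sleepiness cohorts use 15 subjects × 6
provoked trials (2 per stage); stage intercepts 2.0/2.6/3.2
(N2/N3/REM, REM sleepiest) are spaced so the ordering is recoverable
at this cohort size; effect sizes b_beta = 0.8, b_delta = 0.5 on
standardized features, subject SD 0.5, residual SD 0.6.  Permutation
calibration runs 200 null simulations at n_perm = 200 (scaled from
the production default of 1000) on 16-unit feature tables; these sizes
are the package's desk-scale defaults and are configurable.

## Numerical choices and degenerate inputs

Zero-phase (forward-backward) filtering everywhere, so no filter delay
biases latencies.  The EMG envelope is the analytic-signal magnitude
smoothed with a 0.2-s moving average; the screen threshold adds the
baseline mean to the 1-SD term (threshold = mean + 1 SD), and any
post-onset sample above threshold (default window 0…+15 s) rejects.
The any-sample rule has a structurally high false-positive rate on
stationary EMG — the 15-s maximum essentially always exceeds
mean + 1 SD of a quiet 10-s baseline — and is therefore used to
*exclude* only arousal trials, which must be movement-free;
awakenings are movement-aligned by definition.  Zero false negatives
on activated trials are asserted; the false-positive rate is reported,
not asserted.  Flat signals: zero background SD means a peak is
detected only if the maximum strictly exceeds the mean; zero baseline
EMG SD means no exceedance; all-equal latencies rank to 5.5; constant
power makes the log-z transform an error, not a NaN.  Bad-channel
repair is inverse-distance neighbor averaging (spherical splines
deliberately avoided: synthetic data rarely need interpolation and the
dependency surface stays small).  ICA/ASR cleaning is a pass-through
hook for real-data users.  The Methods-vs-figure discrepancy in the
latency window (−10…+45 s vs −15…+15 s) is resolved in favor of
−10…+45 as the default; every window and threshold is echoed to the
run manifest.

## Known limitations

Real-data ingest is HDF5/TSV/JSON only (EDF readers exist in the
wider ecosystem and can feed the same containers); no anatomical
labeling of sources; the 1–5 rating is modeled as Gaussian (no ordinal
link); the fast GLS fitter supports a single random-intercept grouping
factor exactly, treating time-of-night bins as fixed effects, which is
a deliberate approximation inside the permutation engine only.
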