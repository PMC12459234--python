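"""Synthetic high-density-EEG awakening trials.

Every trial is 120 s at 500 Hz (60 s of signal before and after the
alignment event at t = 0: movement, alarm-sound, or arousal onset).
The generator emulates the statistical structure the downstream
analyses assume, with full ground-truth bookkeeping:

* stage-appropriate background before t0 — NREM: 1/f noise, a slowly
  amplitude-modulated delta oscillation, and periodic 13-Hz spindle
  bursts; REM: low-amplitude mixed-frequency activity;
* a crossfade to a wake profile (9-Hz alpha plus broadband beta) over
  the first seconds after t0;
* per-band Tukey-windowed band-limited transient bursts around
  configurable latent latencies, with a linear anterior→posterior
  latency gradient (effective latency = latent + slope * (1 - ap));
* optional inserted biphasic slow waves (K-complex-like);
* EMG channels with an optional high-frequency activation from t0;
* per-subject eyes-closed wake references;
* sleepiness ratings drawn from a stated linear model on the trial's
  own EEG features (provoked awakenings only).

The sleep background's band power is dominated by a shared, bounded
sinusoidal power modulation (depth 0.4, period 5 s) rather than by
heavy-tailed stochastic fluctuation, so that the 2-SD peak detector
fires on inserted transients and essentially never on background
alone — the generator is calibrated to reproduce detection behavior,
not sleep physiology in full.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .bands import BAND_NAMES
from .layout import ChannelLayout

FS = 500
TRIAL_DURATION_S = 120.0
N_SAMPLES = int(TRIAL_DURATION_S * FS)
T0_INDEX = N_SAMPLES // 2

#: sleep-background power modulation (shared across channels and bands)
MOD_DEPTH = 0.4
MOD_PERIOD_S = 5.0

#: wake (eyes-closed rest) profile, shared by post-t0 trial signal and
#: the wake-reference generator so that wake-normalized post-t0 power
#: sits at ratio ~1 unless a transient pushes it higher
WAKE_PINK_RMS = 10.0     # µV
WAKE_ALPHA_AMP = 10.0    # µV, 9-Hz sinusoid
WAKE_BETA_RMS = 3.0      # µV, 18-29.5 Hz noise
CROSSFADE_S = 4.0

STAGES = ("N2", "N3", "REM")
CONDITIONS = ("spontaneous_awakening", "provoked_awakening", "arousal")


@dataclass
class TrialGroundTruth:
    latent_peak_latency: dict      # band -> latency s, absent band omitted
    ap_gradient_slope: float
    inserted_waves: list           # (channel_id, trough_time_s, p2p_uv, neg_halfwave_s)
    has_delta_peak: bool
    has_beta_peak: bool
    delta_before_beta: bool
    emg_activation: bool


@dataclass
class Trial:
    data: np.ndarray               # (n_channels_total, N_SAMPLES) float32, µV
    fs: int
    t0_index: int
    condition: str
    stage: str
    subject_id: str
    trial_id: str
    time_of_night: float           # hours since recording start
    layout: ChannelLayout
    sleepiness: int | None = None
    truth: TrialGroundTruth | None = None

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.data.shape[1]) - self.t0_index) / self.fs


@dataclass
class WakeReference:
    subject_id: str
    band_power: np.ndarray         # (n_scalp, n_bands) µV², order BAND_NAMES
    band_names: tuple = BAND_NAMES


@dataclass
class TrialConfig:
    stage: str = "N2"
    condition: str = "spontaneous_awakening"
    # band -> latent transient latency (s rel. t0); omit band for no transient
    transient_latency: dict = field(default_factory=dict)
    # band -> burst RMS amplitude µV
    transient_amp: dict = field(
        default_factory=lambda: {"delta": 35.0, "theta": 20.0, "alpha": 30.0,
                                 "sigma": 20.0, "beta": 15.0}
    )
    transient_duration: float = 3.0
    ap_gradient_slope: float = 0.0     # s of extra latency per unit (1 - ap_coord)
    noise_sd: float = 3.0              # µV white sensor noise
    pink_rms: float = 10.0             # µV sleep-background 1/f noise
    delta_osc_amp: float | None = None  # µV; default per stage
    spindle_amp: float = 8.0           # µV (NREM only)
    theta_osc_amp: float = 5.0         # µV (REM only)
    wake_alpha_amp: float = WAKE_ALPHA_AMP
    wake_beta_rms: float = WAKE_BETA_RMS
    wake_pink_rms: float = WAKE_PINK_RMS
    inserted_waves: list = field(default_factory=list)
    emg_activation: bool = False

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for band, lat in self.transient_latency.items():
            if band not in BAND_NAMES:
                raise ValueError(f"unknown band {band!r}")
            if lat is not None and not (-60.0 < lat < 60.0):
                raise ValueError(f"latency {lat} s for {band!r} outside (-60, 60)")


_BAND_EDGES = {"delta": (1.0, 4.0), "theta": (5.0, 7.0), "alpha": (8.0, 11.5),
               "sigma": (12.0, 16.0), "beta": (18.0, 29.5)}


def _parseval_rms(spec: np.ndarray, n: int) -> np.ndarray:
    """Per-channel RMS of irfft(spec) computed on the spectrum (no DC/Nyquist)."""
    return np.sqrt(2.0 * (np.abs(spec) ** 2).sum(axis=-1, keepdims=True)) / n


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int) -> np.ndarray:
    """Unit-RMS 1/f-power noise, per channel, band-limited to 0.5-45 Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / FS)
    shape = np.zeros_like(freqs)
    sel = (freqs >= 0.5) & (freqs <= 45.0)
    shape[sel] = 1.0 / np.sqrt(freqs[sel])
    spec = (rng.standard_normal((n_ch, freqs.size), dtype=np.float32)
            + 1j * rng.standard_normal((n_ch, freqs.size), dtype=np.float32))
    spec *= shape.astype(np.float32)
    spec /= _parseval_rms(spec, n).astype(np.float32)
    return np.fft.irfft(spec, n=n, axis=1).astype(np.float32)


def _band_noise(rng: np.random.Generator, n: int, lo: float, hi: float,
                n_ch: int | None = None) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise, optionally per channel.

    Synthesized in the frequency domain (flat spectrum inside [lo, hi],
    zero outside).  Channels are mutually independent: incoherent-
    across-channels signals survive average referencing nearly
    unchanged, whereas a common-mode signal would be cancelled by it.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / FS)
    sel = (freqs >= lo) & (freqs <= hi)
    shape = (1 if n_ch is None else n_ch, freqs.size)
    spec = np.zeros(shape, dtype=np.complex64)
    m = int(sel.sum())
    spec[:, sel] = (rng.standard_normal((shape[0], m), dtype=np.float32)
                    + 1j * rng.standard_normal((shape[0], m), dtype=np.float32))
    spec /= _parseval_rms(spec, n).astype(np.float32)
    x = np.fft.irfft(spec, n=n, axis=-1).astype(np.float32)
    return x[0] if n_ch is None else x


def _osc(freq: float, t: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """sin(2π f t + φ_c) per channel via the angle-addition identity
    (two 1-D sinusoids instead of a 2-D ``np.sin``)."""
    s = np.sin(2 * np.pi * freq * t).astype(np.float32)
    c = np.cos(2 * np.pi * freq * t).astype(np.float32)
    return (np.cos(phases)[:, None].astype(np.float32) * s[None, :]
            + np.sin(phases)[:, None].astype(np.float32) * c[None, :])


def _smoothstep(t: np.ndarray, start: float, width: float) -> np.ndarray:
    u = np.clip((t - start) / width, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def biphasic_wave(p2p: float, neg_halfwave_s: float, fs: int = FS) -> np.ndarray:
    """K-complex-like biphasic waveform: negative then positive half-wave.

    Trough depth is 0.6 * p2p, rebound 0.4 * p2p; the positive half-wave
    lasts 0.8 times the negative one.
    """
    d_neg = neg_halfwave_s
    d_pos = 0.8 * neg_halfwave_s
    n_neg = int(round(d_neg * fs))
    n_pos = int(round(d_pos * fs))
    w = np.empty(n_neg + n_pos)
    w[:n_neg] = -0.6 * p2p * np.sin(np.pi * np.arange(n_neg) / n_neg)
    w[n_neg:] = 0.4 * p2p * np.sin(np.pi * np.arange(n_pos) / n_pos)
    return w


def simulate_trial(layout: ChannelLayout, cfg: TrialConfig, seed: int,
                   subject_id: str = "S1", trial_id: str = "T1",
                   time_of_night: float = 3.0) -> Trial:
    """Generate one 120-s trial. Deterministic given (layout, cfg, seed)."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    n_scalp = layout.n_scalp
    n_total = len(layout.channel_id)
    t = (np.arange(N_SAMPLES) - T0_INDEX) / FS

    data = np.zeros((n_total, N_SAMPLES), dtype=np.float32)

    # shared bounded power modulation of the sleep background
    mod_phase = rng.uniform(0, 2 * np.pi)
    g_amp = np.sqrt(1.0 + MOD_DEPTH * np.sin(
        2 * np.pi * t / MOD_PERIOD_S + mod_phase)).astype(np.float32)
    w = _smoothstep(t, 0.0, CROSSFADE_S).astype(np.float32)  # sleep -> wake crossfade
    sleep_w = 1.0 - w

    # --- 1/f background (sleep modulated, wake steady) ------------------
    pink = _pink_noise(rng, n_total, N_SAMPLES)
    sleep_pink = cfg.pink_rms if cfg.stage != "REM" else 0.9 * cfg.pink_rms
    amp = sleep_pink * g_amp * sleep_w + cfg.wake_pink_rms * w
    data[:n_scalp] += pink[:n_scalp] * amp
    # mastoids: attenuated independent background
    data[layout.mastoid_index] += 0.3 * pink[layout.mastoid_index] * amp

    # --- stage-specific sleep oscillations ------------------------------
    if cfg.stage in ("N2", "N3"):
        a_delta = cfg.delta_osc_amp if cfg.delta_osc_amp is not None else \
            (25.0 if cfg.stage == "N3" else 15.0)
        phases = rng.uniform(0, 2 * np.pi, n_scalp)
        osc = _osc(1.25, t, phases)
        data[:n_scalp] += a_delta * osc * (g_amp * sleep_w)[None, :]
        # periodic spindle bursts (13 Hz, 1-s Tukey), pre-t0 only
        sp_env = np.zeros(N_SAMPLES)
        win = sps.windows.tukey(FS, 0.5)
        for c in np.arange(-58.0, -1.0, 4.0):
            c_jit = c + rng.uniform(-0.4, 0.4)
            i0 = int((c_jit - 0.5 + 60.0) * FS)
            sp_env[i0:i0 + FS] = np.maximum(sp_env[i0:i0 + FS], win)
        sp_phases = rng.uniform(0, 2 * np.pi, n_scalp)
        data[:n_scalp] += cfg.spindle_amp * sp_env.astype(np.float32)[None, :] * _osc(
            13.0, t, sp_phases)
    else:  # REM: low-amplitude mixed frequency
        phases = rng.uniform(0, 2 * np.pi, n_scalp)
        osc = _osc(6.0, t, phases)
        data[:n_scalp] += cfg.theta_osc_amp * osc * (g_amp * sleep_w)[None, :]

    # --- wake profile after the transition ------------------------------
    alpha_phases = rng.uniform(0, 2 * np.pi, n_scalp)
    data[:n_scalp] += cfg.wake_alpha_amp * w[None, :] * _osc(9.0, t, alpha_phases)
    if cfg.wake_beta_rms > 0:
        data[:n_scalp] += cfg.wake_beta_rms * w[None, :] * _band_noise(
            rng, N_SAMPLES, 18.0, 29.5, n_ch=n_scalp)

    # --- band-limited transient bursts with AP latency gradient ---------
    ap = layout.ap_coord
    half = cfg.transient_duration / 2.0
    for band, lat in cfg.transient_latency.items():
        if lat is None:
            continue
        lo, hi = _BAND_EDGES[band]
        centers = lat + cfg.ap_gradient_slope * (1.0 - ap)
        tukey_n = int(cfg.transient_duration * FS)
        win = sps.windows.tukey(tukey_n, 0.5).astype(np.float32)
        # synthesize noise only over the segment the gradient spans
        seg0 = int((centers.min() - half + 60.0) * FS)
        seg1 = int((centers.max() + half + 60.0) * FS) + 1
        if seg0 < 0 or seg1 > N_SAMPLES:
            raise ValueError(
                f"effective {band} transient latencies leave the trial window")
        u = _band_noise(rng, seg1 - seg0, lo, hi, n_ch=n_scalp)
        for c in range(n_scalp):
            i0 = int((centers[c] - half + 60.0) * FS)
            data[c, i0:i0 + tukey_n] += (cfg.transient_amp[band] * win
                                         * u[c, i0 - seg0:i0 - seg0 + tukey_n])

    # --- inserted biphasic slow waves ------------------------------------
    for (ch_id, trough_t, p2p, d_neg) in cfg.inserted_waves:
        ci = layout.channel_id.index(ch_id)
        wav = biphasic_wave(p2p, d_neg)
        i0 = int((trough_t - d_neg / 2.0 + 60.0) * FS)
        data[ci, i0:i0 + wav.size] += wav

    # --- EMG channels -----------------------------------------------------
    emg = layout.emg_index
    data[emg] = 2.0 * rng.standard_normal((emg.size, N_SAMPLES), dtype=np.float32)
    if cfg.emg_activation:
        burst = _band_noise(rng, N_SAMPLES, 100.0, 245.0)
        env = _smoothstep(t, 0.0, 0.5) * (1.0 - _smoothstep(t, 12.0, 2.0))
        data[emg] += 20.0 * burst * env

    # --- sensor noise -----------------------------------------------------
    if cfg.noise_sd > 0:
        data[:n_scalp] += cfg.noise_sd * rng.standard_normal(
            (n_scalp, N_SAMPLES), dtype=np.float32)
        data[layout.mastoid_index] += cfg.noise_sd * rng.standard_normal(
            (2, N_SAMPLES), dtype=np.float32)

    lat = {b: v for b, v in cfg.transient_latency.items() if v is not None}
    has_d, has_b = "delta" in lat, "beta" in lat
    truth = TrialGroundTruth(
        latent_peak_latency=lat,
        ap_gradient_slope=cfg.ap_gradient_slope,
        inserted_waves=list(cfg.inserted_waves),
        has_delta_peak=has_d,
        has_beta_peak=has_b,
        delta_before_beta=(has_d and has_b and lat["delta"] < lat["beta"]),
        emg_activation=cfg.emg_activation,
    )
    return Trial(data=data.astype(np.float32), fs=FS, t0_index=T0_INDEX,
                 condition=cfg.condition, stage=cfg.stage, subject_id=subject_id,
                 trial_id=trial_id, time_of_night=time_of_night, layout=layout,
                 truth=truth)


def make_wake_reference(layout: ChannelLayout, subject_id: str, seed: int,
                        duration_s: float = 60.0) -> WakeReference:
    """Eyes-closed quiet-wakefulness band power, per channel per band."""
    from .spectral import epoch_band_power  # local import to avoid cycle at import time

    rng = np.random.default_rng(seed)
    n = int(duration_s * FS)
    n_scalp = layout.n_scalp
    x = WAKE_PINK_RMS * _pink_noise(rng, n_scalp, n)
    phases = rng.uniform(0, 2 * np.pi, n_scalp)
    x += WAKE_ALPHA_AMP * np.sin(2 * np.pi * 9.0 * np.arange(n)[None, :] / FS
                                 + phases[:, None])
    x += WAKE_BETA_RMS * _band_noise(rng, n, 18.0, 29.5, n_ch=n_scalp)
    pw = epoch_band_power(x, FS)            # (n_scalp, n_bands, n_epochs)
    return WakeReference(subject_id=subject_id, band_power=pw.mean(axis=2))


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class RatingModel:
    """Sleepiness = intercept(stage) - b_beta * z(pre-t0 beta power)
    + b_delta * z(post-t0 delta power) + subject intercept + noise,
    rounded and clipped to the 1-5 interview scale."""
    intercepts: dict = field(default_factory=lambda: {"N2": 2.0, "N3": 2.6, "REM": 3.2})
    b_beta: float = 0.8
    b_delta: float = 0.5
    subject_sd: float = 0.5
    noise_sd: float = 0.6


@dataclass
class CohortConfig:
    n_subjects: int = 10
    # stage -> trials per subject
    trials_per_subject: dict = field(default_factory=lambda: {"N2": 2, "N3": 1})
    condition: str = "spontaneous_awakening"
    trial_cfg: TrialConfig = field(default_factory=TrialConfig)
    # optional per-trial overrides: list of TrialConfig, cycled over trials
    trial_cfg_sequence: list | None = None
    rating_model: RatingModel | None = None
    name: str = "cohort"


@dataclass
class Cohort:
    name: str
    layout: ChannelLayout
    trials: list
    wake_refs: dict                 # subject_id -> WakeReference

    def __iter__(self):
        return iter(self.trials)

    def __len__(self):
        return len(self.trials)


def simulate_cohort(layout: ChannelLayout, cfg: CohortConfig, seed: int) -> Cohort:
    """Generate a cohort of trials plus per-subject wake references."""
    from .spectral import epoch_band_power

    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    wake_refs: dict[str, WakeReference] = {}
    seq = cfg.trial_cfg_sequence
    k = 0
    for s in range(cfg.n_subjects):
        sid = f"S{s + 1:02d}"
        wake_refs[sid] = make_wake_reference(
            layout, sid, seed=int(rng.integers(2**31)))
        for stage, n_tr in cfg.trials_per_subject.items():
            for j in range(n_tr):
                tc = seq[k % len(seq)] if seq else cfg.trial_cfg
                tc = replace(tc, stage=stage, condition=cfg.condition)
                tr = simulate_trial(
                    layout, tc, seed=int(rng.integers(2**31)),
                    subject_id=sid, trial_id=f"{sid}_{stage}_{j + 1}",
                    time_of_night=float(rng.uniform(0.5, 7.5)))
                trials.append(tr)
                k += 1

    if cfg.rating_model is not None and cfg.condition == "provoked_awakening":
        _attach_ratings(trials, layout, cfg.rating_model, rng)
    return Cohort(name=cfg.name, layout=layout, trials=trials, wake_refs=wake_refs)


def _attach_ratings(trials, layout, model: RatingModel, rng) -> None:
    from .spectral import epoch_band_power

    inner = np.flatnonzero(layout.innermost)
    b_i = BAND_NAMES.index("beta")
    d_i = BAND_NAMES.index("delta")
    pre_beta, post_delta = [], []
    for tr in trials:
        pw = epoch_band_power(tr.data[inner], tr.fs)   # inner x band x 120
        pre_beta.append(pw[:, b_i, 30:60].mean())      # (-30, 0) s
        post_delta.append(pw[:, d_i, 60:80].mean())    # (0, +20) s

    # standardize features within stage: band power differs grossly between
    # stages, and the stage effect is carried by the intercepts, not smuggled
    # in through stage-confounded features
    def _z(v: np.ndarray) -> np.ndarray:
        out = np.empty_like(v)
        stages = np.array([tr.stage for tr in trials])
        for s in np.unique(stages):
            sel = stages == s
            sd = v[sel].std()
            out[sel] = (v[sel] - v[sel].mean()) / (sd if sd > 0 else 1.0)
        return out

    zb = _z(np.array(pre_beta))
    zd = _z(np.array(post_delta))
    subj_ids = sorted({tr.subject_id for tr in trials})
    u = {s: rng.normal(0, model.subject_sd) for s in subj_ids}
    for i, tr in enumerate(trials):
        y = (model.intercepts[tr.stage] - model.b_beta * zb[i]
             + model.b_delta * zd[i] + u[tr.subject_id]
             + rng.normal(0, model.noise_sd))
        tr.sleepiness = int(np.clip(round(y), 1, 5))
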