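"""Band power on 1-s epochs and per-trial / group peak detection.

Power is computed by discrete Fourier transform on non-overlapping 1-s
epochs (rectangular window, 1-Hz bin spacing), summing the one-sided
power of bins whose center frequency lies in [lo, hi] inclusive.  A
pure sinusoid of amplitude A at a bin center therefore contributes
A²/2 to its band.  Epochs are tiled from -60 s so an epoch boundary
falls exactly at the alignment event; epoch times are bin centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as ss

from .bands import BAND_NAMES, DEFAULT_BANDS, BandDefinition
from .simulate import Trial, WakeReference


def epoch_band_power(x: np.ndarray, fs: int,
                     bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> np.ndarray:
    """Per-epoch band power of ``x`` (..., n_samples) -> (..., n_bands, n_epochs)."""
    n = x.shape[-1]
    n_epochs = n // fs
    xe = x[..., : n_epochs * fs].reshape(*x.shape[:-1], n_epochs, fs)
    spec = np.fft.rfft(xe, axis=-1)
    # one-sided power per bin; DC and Nyquist carry no doubling
    p = (2.0 / fs**2) * np.abs(spec) ** 2
    p[..., 0] /= 2.0
    p[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(fs, d=1.0 / fs)
    out = np.empty((*x.shape[:-1], len(bands), n_epochs))
    for i, b in enumerate(bands):
        sel = (freqs >= b.lo) & (freqs <= b.hi)
        out[..., i, :] = p[..., sel].sum(axis=-1)
    return out


@dataclass
class BandPowerTimecourse:
    """channel x band x epoch power for one trial."""
    values: np.ndarray             # (n_channels, n_bands, n_epochs)
    epoch_times: np.ndarray        # epoch centers, s relative to t0
    normalization: str             # absolute | wake_ratio | log_z
    subject_id: str
    channel_ids: list[str]
    band_names: tuple = BAND_NAMES


@dataclass
class BandTimecourse:
    """band x epoch power averaged over a channel subset."""
    values: np.ndarray             # (n_bands, n_epochs)
    epoch_times: np.ndarray
    normalization: str
    band_names: tuple = BAND_NAMES


@dataclass
class PeakEvent:
    band: str
    latency: float                 # s relative to t0 (epoch center)
    height: float                  # peak minus background mean, in background SDs
    detected: bool


def band_power(trial: Trial, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
               filter_band: tuple[float, float] = (0.5, 45.0)) -> BandPowerTimecourse:
    """1-s-epoch band power of the scalp channels of a (preprocessed) trial."""
    for b in bands:
        if b.lo < filter_band[0] or b.hi > filter_band[1]:
            warnings.warn(f"band {b.name!r} extends outside the filter passband")
    n_scalp = trial.layout.n_scalp
    vals = epoch_band_power(np.asarray(trial.data[:n_scalp], dtype=np.float64),
                            trial.fs, bands)
    n_epochs = vals.shape[-1]
    t_start = -trial.t0_index / trial.fs
    times = t_start + 0.5 + np.arange(n_epochs)
    return BandPowerTimecourse(values=vals, epoch_times=times,
                               normalization="absolute", subject_id=trial.subject_id,
                               channel_ids=trial.layout.scalp_ids,
                               band_names=tuple(b.name for b in bands))


def normalize_wake(bpt: BandPowerTimecourse, wake_ref: WakeReference) -> BandPowerTimecourse:
    """Express power as a ratio to the subject's eyes-closed wake level.

    A value of 1.0 means wake level.  Requires matching subject and
    strictly positive wake power.
    """
    if bpt.subject_id != wake_ref.subject_id:
        raise ValueError(f"subject mismatch: {bpt.subject_id} vs {wake_ref.subject_id}")
    if bpt.normalization != "absolute":
        raise ValueError("normalize_wake expects absolute power")
    ref = wake_ref.band_power
    if np.any(ref <= 0):
        raise ValueError("wake reference power must be strictly positive")
    return replace(bpt, values=bpt.values / ref[..., None], normalization="wake_ratio")


def log_zscore_tf(bpt: BandPowerTimecourse) -> BandPowerTimecourse:
    """Natural log, then z-score over the epoch axis per channel and band."""
    if np.any(bpt.values <= 0):
        raise ValueError("log_zscore_tf requires strictly positive values")
    lv = np.log(bpt.values)
    sd = lv.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant power time course: z-score undefined")
    return replace(bpt, values=(lv - lv.mean(axis=-1, keepdims=True)) / sd,
                   normalization="log_z")


def channel_mean(bpt: BandPowerTimecourse, subset: np.ndarray | None = None,
                 layout=None) -> BandTimecourse:
    """Arithmetic mean over a channel subset (default: innermost channels)."""
    if subset is None:
        if layout is None:
            raise ValueError("need a layout to resolve the innermost subset")
        subset = np.flatnonzero(layout.innermost)
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("empty channel subset")
    return BandTimecourse(values=bpt.values[subset].mean(axis=0),
                          epoch_times=bpt.epoch_times,
                          normalization=bpt.normalization,
                          band_names=bpt.band_names)


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (times >= window[0]) & (times < window[1])


def detect_band_peak(tc: BandTimecourse, band: str,
                     background_window: tuple[float, float] = (-45.0, -30.0),
                     k: float = 2.0,
                     search_window: tuple[float, float] = (-15.0, 15.0)) -> PeakEvent:
    """Detect a band-power peak exceeding background mean + k SD.

    Background statistics come from ``background_window``; the peak is
    the maximum over ``search_window`` (first occurrence on ties).
    """
    if background_window[1] > 0:
        raise ValueError("background window must end before t0")
    bi = tc.band_names.index(band)
    bg = tc.values[bi, _window_mask(tc.epoch_times, background_window)]
    if bg.size == 0:
        raise ValueError("background window outside the trial")
    sel = _window_mask(tc.epoch_times, search_window)
    if not np.any(sel):
        raise ValueError("empty search window")
    seg = tc.values[bi, sel]
    seg_t = tc.epoch_times[sel]
    i = int(np.argmax(seg))                 # argmax takes the first maximum
    m, s = float(bg.mean()), float(bg.std(ddof=0))
    peak = float(seg[i])
    if s == 0.0:
        detected = peak > m
        height = np.inf if detected else 0.0
    else:
        height = (peak - m) / s
        detected = height > k
    return PeakEvent(band=band, latency=float(seg_t[i]), height=height,
                     detected=bool(detected))


def group_peak_above_references(
        subject_tc: np.ndarray, epoch_times: np.ndarray,
        background_window: tuple[float, float] = (-45.0, -30.0),
        search_window: tuple[float, float] = (-15.0, 15.0),
        k: float = 2.0, wake_margin: float = 1.2, alpha: float = 0.05,
        band_names: tuple = BAND_NAMES) -> dict:
    """Bands with a well-defined group peak above sleep AND wake levels.

    ``subject_tc`` is subjects x bands x epochs, wake-normalized (1.0 =
    wake level).  A band qualifies when the group-median time course has
    a peak exceeding the sleep background by ``k`` SD, the median peak
    ratio exceeds the wake level by ``wake_margin``, and a one-sided
    paired test across subjects puts the peak above wake (p < alpha).
    Returns band -> PeakEvent (detected = qualifies on all three counts).
    """
    med = np.median(subject_tc, axis=0)     # bands x epochs
    out = {}
    for bi, band in enumerate(band_names):
        tc = BandTimecourse(values=med, epoch_times=epoch_times,
                            normalization="wake_ratio", band_names=band_names)
        ev = detect_band_peak(tc, band, background_window, k, search_window)
        ei = int(np.argmin(np.abs(epoch_times - ev.latency)))
        subj_vals = subject_tc[:, bi, ei]
        above_wake = med[bi, ei] > wake_margin
        if subj_vals.size >= 3 and np.std(subj_vals) > 0:
            t, p_two = ss.ttest_1samp(np.log(subj_vals), 0.0)
            p_one = p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
        else:
            p_one = 1.0
        out[band] = PeakEvent(band=band, latency=ev.latency, height=ev.height,
                              detected=bool(ev.detected and above_wake
                                            and p_one < alpha))
    return out


def timecourse_ttests(subject_tc: np.ndarray, epoch_times: np.ndarray,
                      sleep_ref: tuple[float, float] = (-45.0, -30.0),
                      wake_ref: float | np.ndarray = 1.0,
                      alpha: float = 0.05, n_perm: int = 1000, seed: int = 0,
                      band_names: tuple = BAND_NAMES) -> dict:
    """Epoch-wise paired t-tests vs the sleep and wake references.

    ``subject_tc`` is subjects x bands x epochs (wake-normalized, so the
    wake reference defaults to 1.0; pass per-subject values otherwise).
    Returns band -> dict with boolean masks ``vs_sleep`` and ``vs_wake``
    over epochs, corrected with the cluster-and-probability procedure
    over contiguous epochs.
    """
    from .stats import timecourse_cluster_correct

    n_subj = subject_tc.shape[0]
    if n_subj < 3:
        raise ValueError("need at least 3 subjects for paired tests")
    sleep_sel = _window_mask(epoch_times, sleep_ref)
    sleep_mean = subject_tc[:, :, sleep_sel].mean(axis=2)     # subj x band
    wake = np.broadcast_to(np.asarray(wake_ref, dtype=float),
                           sleep_mean.shape)
    out = {}
    for bi, band in enumerate(band_names):
        d_sleep = subject_tc[:, bi, :] - sleep_mean[:, bi, None]
        d_wake = subject_tc[:, bi, :] - wake[:, bi, None]
        out[band] = {
            "vs_sleep": timecourse_cluster_correct(d_sleep, alpha=alpha,
                                                   n_perm=n_perm, seed=seed).mask,
            "vs_wake": timecourse_cluster_correct(d_wake, alpha=alpha,
                                                  n_perm=n_perm, seed=seed + 1).mask,
        }
    return out
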