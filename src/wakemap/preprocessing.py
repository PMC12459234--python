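"""Filtering, referencing, epoch hygiene, and the EMG-activation screen.

All filters are zero-phase (forward-backward), so filter delay cannot
bias the latency analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .simulate import Trial


@dataclass
class ScreenResult:
    trial_id: str
    emg_envelope_max: float        # µV, maximum smoothed envelope in the test window
    baseline_mean: float           # µV
    baseline_sd: float             # µV
    rejected: bool


def bandpass(trial: Trial, low: float = 0.5, high: float = 45.0, order: int = 4) -> Trial:
    """Zero-phase band-pass of the EEG channels; EMG channels untouched."""
    if high >= trial.fs / 2:
        raise ValueError(f"high edge {high} Hz >= Nyquist ({trial.fs / 2} Hz)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=trial.fs, output="sos")
    data = trial.data.astype(np.float64, copy=True)
    eeg = np.concatenate([np.arange(trial.layout.n_scalp), trial.layout.mastoid_index])
    data[eeg] = sps.sosfiltfilt(sos, data[eeg], axis=1)
    return replace(trial, data=data.astype(np.float32))


def average_reference(trial: Trial) -> Trial:
    """Subtract the instantaneous mean over scalp channels (mastoid/EMG excluded)."""
    n_scalp = trial.layout.n_scalp
    if n_scalp < 2:
        raise ValueError("average reference needs at least 2 scalp channels")
    data = trial.data.astype(np.float64, copy=True)
    data[:n_scalp] -= data[:n_scalp].mean(axis=0, keepdims=True)
    return replace(trial, data=data.astype(np.float32))


def screen_emg(trial: Trial, band: tuple[float, float] = (100.0, 245.0),
               baseline_window: tuple[float, float] = (-30.0, -20.0),
               test_window: tuple[float, float] = (0.0, 15.0),
               smooth_s: float = 0.2) -> ScreenResult:
    """Reject trials with muscle activation around the alignment event.

    EMG channels are band-passed, the analytic-signal envelope is
    computed and smoothed with a moving average, and the trial is
    rejected when any sample of the mean envelope inside
    ``test_window`` exceeds baseline mean + 1 SD of the
    ``baseline_window`` envelope.  Tuned for zero false negatives at
    the price of some false positives.
    """
    emg = trial.layout.emg_index
    if emg.size == 0:
        raise ValueError("trial has no EMG channels")
    t = trial.times
    if baseline_window[0] < t[0] or baseline_window[1] > t[-1]:
        raise ValueError("baseline window outside the trial")
    sos = sps.butter(4, band, btype="bandpass", fs=trial.fs, output="sos")
    x = sps.sosfiltfilt(sos, trial.data[emg].astype(np.float64), axis=1)
    env = np.abs(sps.hilbert(x, axis=1))
    n_smooth = max(1, int(smooth_s * trial.fs))
    kernel = np.ones(n_smooth) / n_smooth
    env = np.apply_along_axis(lambda e: np.convolve(e, kernel, mode="same"), 1, env)
    env = env.mean(axis=0)
    base = env[(t >= baseline_window[0]) & (t < baseline_window[1])]
    m, s = float(base.mean()), float(base.std(ddof=0))
    test = env[(t >= test_window[0]) & (t < test_window[1])]
    peak = float(test.max())
    rejected = peak > m + s if s > 0 else peak > m
    return ScreenResult(trial_id=trial.trial_id, emg_envelope_max=peak,
                        baseline_mean=m, baseline_sd=s, rejected=bool(rejected))


def interpolate_bad(trial: Trial, bad: set[str] | list[str]) -> Trial:
    """Replace bad scalp channels by the inverse-distance-weighted mean
    of their good neighbors in the layout adjacency."""
    bad = set(bad)
    if not bad:
        return trial
    layout = trial.layout
    scalp = layout.scalp_ids
    if not bad.issubset(scalp):
        raise ValueError("bad channels must be scalp channels")
    if bad == set(scalp):
        raise ValueError("cannot interpolate: all channels bad")
    bad_idx = [scalp.index(c) for c in sorted(bad)]
    good = np.array([i for i in range(len(scalp)) if scalp[i] not in bad])
    data = trial.data.astype(np.float64, copy=True)
    pos = layout.position
    for bi in bad_idx:
        nbrs = np.flatnonzero(layout.adjacency[bi])
        nbrs = np.array([n for n in nbrs if n in good])
        if nbrs.size < 2:
            raise ValueError(f"channel {scalp[bi]!r} has <2 good neighbors")
        wgt = 1.0 / np.linalg.norm(pos[nbrs] - pos[bi], axis=1)
        wgt /= wgt.sum()
        data[bi] = wgt @ trial.data[nbrs].astype(np.float64)
    return replace(trial, data=data.astype(np.float32))


def preprocess(trial: Trial, low: float = 0.5, high: float = 45.0,
               bad: set[str] | None = None, clean_hook=None) -> Trial:
    """Standard hygiene: optional external cleaning hook (pass-through by
    default; real-data users can plug ICA/ASR equivalents here), bad-channel
    interpolation, band-pass, average reference."""
    if clean_hook is not None:
        trial = clean_hook(trial)
    if bad:
        trial = interpolate_bad(trial, bad)
    trial = bandpass(trial, low, high)
    return average_reference(trial)
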