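"""Zero-crossing slow-wave detection and the 75-µV type-I/II split.

Events are negative half-waves: a down-going zero crossing (zc1), a
negative peak, and an up-going zero crossing (zc2), detected per
channel on the mastoid-referenced signal downsampled to 128 Hz and
band-passed 0.5-4 Hz (Chebyshev type II, stop edges 0.1 and 10 Hz,
zero-phase).  Candidates are kept iff the half-wave duration zc2 - zc1
lies in [0.25, 1] s.  The peak-to-peak amplitude pairs the negative
peak with the maximum positive value before the next down-going zero
crossing; waves with p2p >= 75 µV are "large" (type-I-like,
K-complex range), the rest small (type-II-like).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import Trial

SW_FS = 128
DURATION_BOUNDS = (0.25, 1.0)
LARGE_P2P_UV = 75.0
DEFAULT_WINDOWS = ((-45.0, -30.0), (-30.0, -5.0), (-5.0, 0.0), (0.0, 5.0), (5.0, 30.0))


@dataclass
class SlowWaveEvent:
    channel: str
    zc1: float                     # s, down-going zero crossing
    neg_peak_time: float           # s
    zc2: float                     # s, up-going zero crossing
    duration: float                # s
    neg_amp: float                 # µV, signed (< 0)
    p2p_amp: float                 # µV
    slope1: float                  # µV/s, zc1 -> negative peak (< 0)
    slope2: float                  # µV/s, negative peak -> zc2 (> 0)
    n_neg_peaks: int
    is_large: bool


@dataclass
class SwSignal:
    data: np.ndarray               # (n_scalp, n_samples) µV at SW_FS
    times: np.ndarray              # s relative to t0
    channel_ids: list[str]
    fs: int = SW_FS


def _cheby2_sos(fs: int = SW_FS):
    # minimum order reaching 20 dB attenuation at the 0.1 / 10 Hz stop edges
    order, wn = sps.cheb2ord(wp=[0.5, 4.0], ws=[0.1, 10.0], gpass=0.5, gstop=20.0, fs=fs)
    return sps.cheby2(order, 20.0, wn, btype="bandpass", fs=fs, output="sos")


def prepare_sw_signal(trial: Trial) -> SwSignal:
    """Mastoid-average reference, anti-aliased resample to 128 Hz,
    zero-phase Chebyshev-II band-pass."""
    layout = trial.layout
    if len(layout.mastoid_ids) < 2:
        raise ValueError("trial layout has no mastoid channels")
    n_scalp = layout.n_scalp
    ref = trial.data[layout.mastoid_index].astype(np.float64).mean(axis=0)
    x = trial.data[:n_scalp].astype(np.float64) - ref[None, :]
    # 500 -> 128 Hz: factor 32/125
    x = sps.resample_poly(x, up=32, down=125, axis=1)
    x = sps.sosfiltfilt(_cheby2_sos(), x, axis=1)
    n = x.shape[1]
    t0 = trial.t0_index * SW_FS // trial.fs
    times = (np.arange(n) - t0) / SW_FS
    return SwSignal(data=x, times=times, channel_ids=layout.scalp_ids)


def _interp_zc(t: np.ndarray, x: np.ndarray, i: int) -> float:
    """Linear-interpolated zero-crossing time between samples i, i+1."""
    return t[i] + x[i] / (x[i] - x[i + 1]) * (t[i + 1] - t[i])


def detect_sw(sw: SwSignal, channel: str, min_p2p: float = 0.0) -> list[SlowWaveEvent]:
    """Detect slow waves on one channel of a prepared signal."""
    ci = sw.channel_ids.index(channel)
    x = sw.data[ci]
    t = sw.times
    pos = x >= 0
    down = np.flatnonzero(pos[:-1] & ~pos[1:])       # x[i] >= 0 > x[i+1]
    up = np.flatnonzero(~pos[:-1] & pos[1:])         # x[i] < 0 <= x[i+1]
    events: list[SlowWaveEvent] = []
    for d in down:
        nxt = up[up > d]
        if nxt.size == 0:
            break
        u = nxt[0]
        zc1 = _interp_zc(t, x, d)
        zc2 = _interp_zc(t, x, u)
        duration = zc2 - zc1
        if not (DURATION_BOUNDS[0] <= duration <= DURATION_BOUNDS[1]):
            continue
        seg = x[d + 1: u + 1]
        k = int(np.argmin(seg))
        neg_amp = float(seg[k])
        neg_t = float(t[d + 1 + k])
        # positive maximum before the next down-going crossing
        nxt_down = down[down > u]
        end = nxt_down[0] + 1 if nxt_down.size else x.size
        pos_max = float(max(x[u + 1: end].max(initial=0.0), 0.0))
        p2p = pos_max - neg_amp
        if p2p < min_p2p:
            continue
        interior = seg[1:-1]
        minima = np.flatnonzero((interior < seg[:-2]) & (interior < seg[2:])
                                & (interior < 0))
        events.append(SlowWaveEvent(
            channel=channel, zc1=float(zc1), neg_peak_time=neg_t, zc2=float(zc2),
            duration=float(duration), neg_amp=neg_amp, p2p_amp=float(p2p),
            slope1=neg_amp / (neg_t - zc1), slope2=-neg_amp / (zc2 - neg_t),
            n_neg_peaks=max(1, int(minima.size)), is_large=bool(p2p >= LARGE_P2P_UV)))
    return events


def detect_sw_trial(trial: Trial, channels: list[str] | None = None,
                    min_p2p: float = 0.0) -> list[SlowWaveEvent]:
    """Prepare the signal and detect slow waves on each channel."""
    sw = prepare_sw_signal(trial)
    channels = channels or sw.channel_ids
    out: list[SlowWaveEvent] = []
    for ch in channels:
        out.extend(detect_sw(sw, ch, min_p2p=min_p2p))
    return out


_PARAMS = ("neg_amp", "slope1", "slope2", "n_neg_peaks")


def window_aggregate(events: list[SlowWaveEvent],
                     windows=DEFAULT_WINDOWS) -> pd.DataFrame:
    """Per-channel, per-window densities and mean parameters.

    Events are assigned to half-open windows [start, end) by their
    negative-peak time, separately for all waves and for the large
    (p2p >= 75 µV) subset.  Density is waves per minute; parameter
    means of empty windows are NaN.
    """
    rows = []
    channels = sorted({e.channel for e in events}) or []
    for ch in channels:
        ch_events = [e for e in events if e.channel == ch]
        for (w0, w1) in windows:
            in_win = [e for e in ch_events if w0 <= e.neg_peak_time < w1]
            for subset, evs in (("all", in_win),
                                ("large", [e for e in in_win if e.is_large])):
                row = {"channel": ch, "window_start": w0, "window_end": w1,
                       "subset": subset, "n": len(evs),
                       "density": len(evs) / (w1 - w0) * 60.0}
                for p in _PARAMS:
                    row[p] = (float(np.mean([getattr(e, p) for e in evs]))
                              if evs else np.nan)
                rows.append(row)
    return pd.DataFrame(rows)


def aggregate_cohort(cohort, windows=DEFAULT_WINDOWS, min_p2p: float = 0.0,
                     channels: list[str] | None = None) -> pd.DataFrame:
    """Subject-level window statistics: trial aggregates averaged within
    subject (NaN-aware for parameter means of empty windows)."""
    frames = []
    for trial in cohort.trials:
        df = window_aggregate(detect_sw_trial(trial, channels=channels,
                                              min_p2p=min_p2p), windows)
        df["subject_id"] = trial.subject_id
        df["trial_id"] = trial.trial_id
        frames.append(df)
    per_trial = pd.concat(frames, ignore_index=True)
    keys = ["subject_id", "channel", "window_start", "window_end", "subset"]
    return per_trial.groupby(keys, as_index=False).agg(
        {"density": "mean", **{p: "mean" for p in _PARAMS}})


def compare_windows(subject_stats: pd.DataFrame, parameter: str,
                    adjacency: np.ndarray, channel_ids: list[str],
                    subset: str = "all",
                    reference: tuple[float, float] = (-45.0, -30.0),
                    alpha: float = 0.05, n_perm: int = 1000, seed: int = 0) -> dict:
    """Paired t-maps of each window vs the reference window, cluster-corrected
    over the channel adjacency.  Returns window -> (tvals, ClusterTestResult)."""
    from .stats import paired_cluster_test

    df = subject_stats[subject_stats["subset"] == subset]
    subjects = sorted(df["subject_id"].unique())
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")

    def _matrix(w0, w1):
        sel = df[(df["window_start"] == w0) & (df["window_end"] == w1)]
        piv = sel.pivot(index="subject_id", columns="channel", values=parameter)
        return piv.reindex(index=subjects, columns=channel_ids).to_numpy()

    ref = _matrix(*reference)
    windows = sorted({(w0, w1) for w0, w1 in
                      zip(df["window_start"], df["window_end"])})
    out = {}
    for i, (w0, w1) in enumerate(w for w in windows if w != tuple(reference)):
        out[(w0, w1)] = paired_cluster_test(_matrix(w0, w1), ref, adjacency,
                                            alpha=alpha, n_perm=n_perm,
                                            seed=seed + i)
    return out
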