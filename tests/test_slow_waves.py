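import numpy as np
import pytest

from wakemap import TrialConfig, simulate_trial
from wakemap.simulate import N_SAMPLES, T0_INDEX, Trial
from wakemap.slow_waves import (SlowWaveEvent, compare_windows, detect_sw,
                                detect_sw_trial, prepare_sw_signal,
                                window_aggregate)


def _clean_cfg(**kw):
    base = dict(stage="N2", delta_osc_amp=0.0, pink_rms=0.0, spindle_amp=0.0,
                noise_sd=0.0, transient_latency={}, wake_alpha_amp=0.0,
                wake_beta_rms=0.0, wake_pink_rms=0.0)
    base.update(kw)
    return TrialConfig(**base)


def _sine_trial(layout, freq, amp=20.0):
    t = np.arange(N_SAMPLES) / 500.0
    data = np.zeros((len(layout.channel_id), N_SAMPLES), dtype=np.float32)
    data[: layout.n_scalp] = amp * np.sin(2 * np.pi * freq * t)[None, :]
    return Trial(data=data, fs=500, t0_index=T0_INDEX,
                 condition="spontaneous_awakening", stage="N2", subject_id="S",
                 trial_id="t", time_of_night=1.0, layout=layout)


class TestFilterChain:
    def test_resampled_rate_and_passband(self, layout24):
        sw = prepare_sw_signal(_sine_trial(layout24, 2.0))
        assert sw.fs == 128
        assert sw.data.shape[1] == 120 * 128
        assert np.std(sw.data[0]) == pytest.approx(20.0 / np.sqrt(2), rel=0.05)

    @pytest.mark.parametrize("freq", [0.05, 20.0])
    def test_stopbands_attenuate(self, layout24, freq):
        sw = prepare_sw_signal(_sine_trial(layout24, freq))
        assert np.std(sw.data[0]) < 0.1 * 20.0 / np.sqrt(2)


class TestDetection:
    def test_canonical_wave_recovered(self, layout64):
        cfg = _clean_cfg(inserted_waves=[("E5", -20.0, 100.0, 0.7)])
        tr = simulate_trial(layout64, cfg, seed=1)
        events = detect_sw(prepare_sw_signal(tr), "E5")
        big = [e for e in events if e.is_large]
        assert len(big) == 1
        e = big[0]
        assert e.neg_peak_time == pytest.approx(-20.0, abs=0.05)
        assert 0.25 <= e.duration <= 1.0
        assert e.neg_amp < 0 and e.slope1 < 0 < e.slope2
        assert e.p2p_amp >= 75.0

    def test_too_short_deflection_filtered_out(self, layout64):
        cfg = _clean_cfg(inserted_waves=[("E5", -20.0, 100.0, 0.15)])
        tr = simulate_trial(layout64, cfg, seed=1)
        events = detect_sw(prepare_sw_signal(tr), "E5")
        assert not [e for e in events
                    if abs(e.neg_peak_time + 20.0) < 0.5 and e.is_large]

    def test_positive_half_waves_yield_no_events(self, layout24):
        tr = _sine_trial(layout24, 1.0, amp=0.0)
        half = np.zeros(N_SAMPLES, dtype=np.float32)
        for c0 in (10_000, 20_000, 40_000):
            half[c0:c0 + 250] = 50.0 * np.sin(np.pi * np.arange(250) / 250)
        tr.data[: layout24.n_scalp] = half[None, :]
        assert detect_sw(prepare_sw_signal(tr), "E1") == []

    def test_missing_mastoids_rejected(self, layout24):
        tr = _sine_trial(layout24, 1.0)
        tr.layout.mastoid_ids, saved = [], tr.layout.mastoid_ids
        try:
            with pytest.raises(ValueError):
                prepare_sw_signal(tr)
        finally:
            tr.layout.mastoid_ids = saved

    def test_duration_bounds_never_violated(self, layout64):
        tr = simulate_trial(layout64, TrialConfig(transient_latency={}), seed=8)
        for e in detect_sw_trial(tr):
            assert 0.25 <= e.duration <= 1.0


def _event(t, p2p=50.0, channel="E1"):
    return SlowWaveEvent(channel=channel, zc1=t - 0.3, neg_peak_time=t,
                         zc2=t + 0.3, duration=0.6, neg_amp=-0.6 * p2p,
                         p2p_amp=p2p, slope1=-100.0, slope2=100.0,
                         n_neg_peaks=1, is_large=p2p >= 75.0)


class TestWindowAggregate:
    def test_density_arithmetic(self):
        df = window_aggregate([_event(-40.0), _event(-35.0), _event(-32.0)],
                              windows=((-45.0, -30.0),))
        row = df[df["subset"] == "all"].iloc[0]
        assert row["density"] == pytest.approx(12.0)   # 3 waves / 15 s

    def test_empty_window_zero_density_nan_means(self):
        df = window_aggregate([_event(-40.0)], windows=((0.0, 5.0), (-45.0, -30.0)))
        row = df[(df["subset"] == "all") & (df["window_start"] == 0.0)].iloc[0]
        assert row["density"] == 0.0 and np.isnan(row["neg_amp"])

    def test_edge_event_goes_to_half_open_window(self):
        df = window_aggregate([_event(-30.0)],
                              windows=((-45.0, -30.0), (-30.0, -5.0)))
        n_low = df[(df["subset"] == "all")
                   & (df["window_start"] == -45.0)].iloc[0]["n"]
        n_high = df[(df["subset"] == "all")
                    & (df["window_start"] == -30.0)].iloc[0]["n"]
        assert (n_low, n_high) == (0, 1)

    def test_large_small_partition(self):
        events = [_event(-40.0, p2p=100.0), _event(-35.0, p2p=40.0),
                  _event(-33.0, p2p=80.0)]
        df = window_aggregate(events, windows=((-45.0, -30.0),))
        n_all = df[df["subset"] == "all"].iloc[0]["n"]
        n_large = df[df["subset"] == "large"].iloc[0]["n"]
        n_small = sum(1 for e in events if not e.is_large)
        assert n_all == n_large + n_small == 3


class TestCompareWindows:
    def _stats_df(self, effect=0.0, seed=0):
        import pandas as pd

        rng = np.random.default_rng(seed)
        channels = [f"c{i}" for i in range(6)]
        rows = []
        for s in range(8):
            for (w0, w1) in ((-45.0, -30.0), (-5.0, 0.0)):
                for ch in channels:
                    val = rng.normal(10.0, 1.0)
                    if (w0, w1) == (-5.0, 0.0):
                        val += effect
                    rows.append({"subject_id": f"S{s}", "channel": ch,
                                 "window_start": w0, "window_end": w1,
                                 "subset": "large", "density": val,
                                 "neg_amp": val, "slope1": val, "slope2": val,
                                 "n_neg_peaks": 1.0})
        return pd.DataFrame(rows), channels

    def _adjacency(self, n):
        adj = np.zeros((n, n), bool)
        i = np.arange(n - 1)
        adj[i, i + 1] = adj[i + 1, i] = True
        return adj

    def test_injected_pre_onset_effect_detected(self):
        df, channels = self._stats_df(effect=3.0)
        res = compare_windows(df, "density", self._adjacency(6), channels,
                              subset="large", n_perm=200, seed=1)
        assert res[(-5.0, 0.0)].any_significant

    def test_null_windows_stay_quiet(self):
        df, channels = self._stats_df(effect=0.0, seed=3)
        res = compare_windows(df, "density", self._adjacency(6), channels,
                              subset="large", n_perm=200, seed=1)
        assert not res[(-5.0, 0.0)].any_significant
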