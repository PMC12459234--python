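import numpy as np
import pytest

from wakemap.bands import BAND_NAMES, BandDefinition
from wakemap.simulate import WakeReference
from wakemap.spectral import (BandTimecourse, band_power, channel_mean,
                              detect_band_peak, epoch_band_power, log_zscore_tf,
                              normalize_wake, timecourse_ttests)

from conftest import sinusoid_trial

FS = 500


def _tc(values, times=None):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = -60.0 + 0.5 + np.arange(values.shape[1])
    return BandTimecourse(values=values, epoch_times=np.asarray(times),
                          normalization="absolute", band_names=("delta",))


class TestBandPower:
    def test_sinusoid_at_bin_center_gives_half_amplitude_squared(self):
        amp, freq = 8.0, 10.0
        x = amp * np.sin(2 * np.pi * freq * np.arange(10 * FS) / FS)
        pw = epoch_band_power(x[None, :], FS)
        alpha = pw[0, BAND_NAMES.index("alpha")]
        assert np.allclose(alpha, amp**2 / 2, rtol=1e-6)
        for other in ("delta", "theta", "sigma", "beta"):
            assert np.allclose(pw[0, BAND_NAMES.index(other)], 0.0, atol=1e-9)

    def test_zero_signal_zero_power(self):
        pw = epoch_band_power(np.zeros((2, 5 * FS)), FS)
        assert np.all(pw == 0)

    def test_white_noise_power_proportional_to_bandwidth(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000 * FS)
        bands = (BandDefinition("a", 5.0, 14.0), BandDefinition("b", 100.0, 118.0))
        pw = epoch_band_power(x[None, :], FS, bands).mean(axis=-1)
        # 10 vs 19 bins of flat spectrum
        assert pw[0, 1] / pw[0, 0] == pytest.approx(19 / 10, rel=0.05)

    def test_parseval_partition(self):
        """Band powers over a partition of 1-45 Hz sum to the total."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20 * FS)
        parts = (BandDefinition("p1", 1, 10), BandDefinition("p2", 11, 20),
                 BandDefinition("p3", 21, 30), BandDefinition("p4", 31, 45))
        total = (BandDefinition("tot", 1, 45),)
        p_parts = epoch_band_power(x[None], FS, parts).sum(axis=1)
        p_tot = epoch_band_power(x[None], FS, total)[:, 0]
        assert np.allclose(p_parts, p_tot, rtol=1e-2)

    def test_band_outside_passband_warns(self, layout24):
        tr = sinusoid_trial(layout24, 10.0)
        with pytest.warns(UserWarning):
            band_power(tr, (BandDefinition("hf", 50.0, 80.0),))


class TestNormalization:
    def _bpt(self, layout, value=4.0):
        tr = sinusoid_trial(layout, 10.0)
        bpt = band_power(tr)
        bpt.values[:] = value
        return bpt

    def test_wake_ratio_identity_and_scaling(self, layout24):
        bpt = self._bpt(layout24, 4.0)
        ref = WakeReference("S01", np.full((24, 5), 4.0))
        out = normalize_wake(bpt, ref)
        assert np.allclose(out.values, 1.0)
        assert out.normalization == "wake_ratio"
        bpt2 = self._bpt(layout24, 16.0)   # doubling amplitude quadruples power
        assert np.allclose(normalize_wake(bpt2, ref).values, 4.0)

    def test_subject_mismatch_rejected(self, layout24):
        bpt = self._bpt(layout24)
        with pytest.raises(ValueError):
            normalize_wake(bpt, WakeReference("S99", np.ones((24, 5))))

    def test_nonpositive_wake_rejected(self, layout24):
        bpt = self._bpt(layout24)
        with pytest.raises(ValueError):
            normalize_wake(bpt, WakeReference("S01", np.zeros((24, 5))))

    def test_log_zscore_moments(self, layout24):
        tr = sinusoid_trial(layout24, 10.0)
        bpt = band_power(tr)
        rng = np.random.default_rng(0)
        bpt.values[:] = rng.uniform(1.0, 5.0, bpt.values.shape)
        out = log_zscore_tf(bpt)
        assert np.allclose(out.values.mean(axis=-1), 0.0, atol=1e-9)
        assert np.allclose(out.values.std(axis=-1), 1.0, atol=1e-9)

    def test_log_zscore_constant_rejected(self, layout24):
        bpt = self._bpt(layout24, 2.0)
        with pytest.raises(ValueError):
            log_zscore_tf(bpt)


class TestChannelMean:
    def test_single_channel_subset_is_identity(self, layout24):
        tr = sinusoid_trial(layout24, 10.0)
        bpt = band_power(tr)
        out = channel_mean(bpt, subset=np.array([3]))
        assert np.allclose(out.values, bpt.values[3])

    def test_empty_subset_rejected(self, layout24):
        tr = sinusoid_trial(layout24, 10.0)
        with pytest.raises(ValueError):
            channel_mean(band_power(tr), subset=np.array([], dtype=int))


class TestPeakDetection:
    def test_flat_timecourse_undetected(self):
        ev = detect_band_peak(_tc(np.ones((1, 120))), "delta")
        assert not ev.detected

    def test_tie_breaks_to_first_occurrence(self):
        v = np.ones((1, 120))
        v[0, 58] = v[0, 63] = 9.0        # equal maxima at -1.5 s and +3.5 s
        ev = detect_band_peak(_tc(v), "delta")
        assert ev.latency == -1.5

    def test_noiseless_transient_detected_at_its_epoch(self):
        v = np.ones((1, 120))
        v[0, 59] = 20.0                  # epoch centered at -0.5 s
        ev = detect_band_peak(_tc(v), "delta")
        assert ev.detected and ev.latency == -0.5 and ev.height > 2

    def test_background_window_must_precede_onset(self):
        with pytest.raises(ValueError):
            detect_band_peak(_tc(np.ones((1, 120))), "delta",
                             background_window=(-5.0, 5.0))


class TestTimecourseTtests:
    def test_null_group_shows_no_significant_epochs(self):
        rng = np.random.default_rng(0)
        tc = 1.0 + 0.05 * rng.standard_normal((8, 5, 120))
        times = -60.0 + 0.5 + np.arange(120)
        masks = timecourse_ttests(tc, times, n_perm=200, seed=1)
        assert not masks["beta"]["vs_sleep"].any()

    def test_injected_offset_yields_covering_cluster(self):
        rng = np.random.default_rng(0)
        tc = 1.0 + 0.05 * rng.standard_normal((8, 5, 120))
        times = -60.0 + 0.5 + np.arange(120)
        sel = (times > 0) & (times < 10)
        tc[:, 4, sel] += 0.5             # large offset in beta over (0, 10) s
        masks = timecourse_ttests(tc, times, n_perm=200, seed=1)
        got = masks["beta"]["vs_sleep"]
        assert got[sel].mean() > 0.8
        assert got[times < -20].mean() < 0.1

    def test_requires_three_subjects(self):
        with pytest.raises(ValueError):
            timecourse_ttests(np.ones((1, 5, 120)), np.arange(120.0))
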