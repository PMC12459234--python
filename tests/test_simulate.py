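import numpy as np
import pytest

from wakemap import TrialConfig, make_wake_reference, simulate_trial
from wakemap.fixtures import fixture
from wakemap.spectral import band_power, channel_mean, detect_band_peak, epoch_band_power


class TestTrialGeneration:
    def test_deterministic_given_seed(self, layout64):
        cfg = TrialConfig(transient_latency={"delta": -1.0})
        a = simulate_trial(layout64, cfg, seed=9)
        b = simulate_trial(layout64, cfg, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_geometry_and_truth(self, nrem_trial):
        assert nrem_trial.data.shape == (68, 60000)
        assert nrem_trial.t0_index == 30000
        tr = nrem_trial.truth
        assert tr.has_delta_peak and tr.has_beta_peak and tr.delta_before_beta

    def test_latency_out_of_range_rejected(self, layout64):
        with pytest.raises(ValueError):
            simulate_trial(layout64, TrialConfig(
                transient_latency={"delta": -61.0}), seed=0)

    def test_unknown_stage_rejected(self, layout64):
        with pytest.raises(ValueError):
            simulate_trial(layout64, TrialConfig(stage="N9"), seed=0)

    def test_rem_has_no_delta_peak(self, layout64):
        """A REM trial without a delta transient never crosses the 2-SD rule."""
        cfg = TrialConfig(stage="REM", transient_latency={"beta": 8.0})
        tr = simulate_trial(layout64, cfg, seed=11)
        tc = channel_mean(band_power(tr), layout=layout64)
        assert not detect_band_peak(tc, "delta").detected
        assert detect_band_peak(tc, "beta").detected

    def test_spindle_bursts_raise_sigma_power(self, layout64):
        """Spectral fidelity: sigma power during spindle bursts exceeds the
        non-burst sigma level on a noiseless NREM background."""
        cfg = TrialConfig(noise_sd=0.0, pink_rms=0.0, delta_osc_amp=0.0,
                          transient_latency={}, wake_alpha_amp=0.0,
                          wake_beta_rms=0.0, wake_pink_rms=0.0)
        tr = simulate_trial(layout64, cfg, seed=5)
        pw = epoch_band_power(np.asarray(tr.data[:64], np.float64), tr.fs)
        sigma = pw[:, 3, :60].mean(axis=0)          # pre-onset sigma per epoch
        assert sigma.max() > 3.0 * np.median(sigma)

    def test_gradient_encoding_affine_in_ap(self, layout64):
        """Per-channel effective latency recovers the configured AP slope."""
        from scipy.stats import linregress

        cfg = TrialConfig(transient_latency={"beta": 4.0}, ap_gradient_slope=4.0,
                          noise_sd=0.5)
        tr = simulate_trial(layout64, cfg, seed=2)
        pw = epoch_band_power(np.asarray(tr.data[:64], np.float64), tr.fs)
        times = -60.0 + 0.5 + np.arange(120)
        sel = (times > -10) & (times < 20)
        lat = times[sel][np.argmax(pw[:, 4, sel], axis=1)]
        fit = linregress(layout64.ap_coord, lat)
        assert fit.slope == pytest.approx(-4.0, abs=0.8)
        assert fit.rvalue**2 > 0.7


class TestCohorts:
    def test_wake_reference_positive(self, layout24):
        wr = make_wake_reference(layout24, "S01", seed=4)
        assert wr.band_power.shape == (24, 5)
        assert np.all(wr.band_power > 0)

    def test_unknown_fixture_rejected(self):
        with pytest.raises(KeyError):
            fixture("nope")

    def test_tiny_demo_composition(self):
        co = fixture("tiny_demo", seed=1)
        assert len(co) == 2
        assert set(co.wake_refs) == {t.subject_id for t in co}

    def test_ratings_only_on_provoked_and_in_scale(self):
        co = fixture("sleepiness_cohort", seed=1)
        assert all(t.condition == "provoked_awakening" for t in co)
        assert all(t.sleepiness in (1, 2, 3, 4, 5) for t in co)
        spont = fixture("tiny_demo", seed=1)
        assert all(t.sleepiness is None for t in spont)

    def test_nrem74_composition_matches_registry(self, nrem74):
        assert len(nrem74) == 74
        both = [t for t in nrem74
                if t.truth.has_delta_peak and t.truth.has_beta_peak]
        assert len(both) == 69
        assert sum(t.truth.delta_before_beta for t in both) == 63
        stages = [t.stage for t in nrem74]
        assert stages.count("N2") == 55 and stages.count("N3") == 19

    def test_rem37_composition_matches_registry(self, rem37):
        assert len(rem37) == 37
        assert all(not t.truth.has_delta_peak for t in rem37)
        assert all(t.truth.latent_peak_latency["beta"] == 8.0 for t in rem37)
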