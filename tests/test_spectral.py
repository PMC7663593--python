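"""Epoching, artifact zeroing, normalisation, band power and relative gamma."""

import numpy as np
import pandas as pd
import pytest

import rgstress as rg
from rgstress.spectral import BandPowerSeries
from tests.conftest import make_analysis_signal


class TestEpochSignal:
    def test_standard_window_yields_480_epochs(self, clean_session):
        sig = rg.concatenate_blocks(clean_session)
        epochs = rg.epoch_signal(sig)
        assert epochs.data.shape == (480, 8, 500)
        assert epochs.epoch_boundaries["RELAX"] == (300, 450)

    def test_trailing_remainder_dropped_with_warning(self, caplog):
        sig = make_analysis_signal(np.zeros((1, 1250)), 250.0)  # 5 s
        with caplog.at_level("WARNING"):
            epochs = rg.epoch_signal(sig)
        assert epochs.n_epochs == 2
        assert any("remainder" in r.message for r in caplog.records)

    def test_single_epoch_signal_is_identity(self):
        x = np.random.default_rng(0).standard_normal((2, 500))
        epochs = rg.epoch_signal(make_analysis_signal(x, 250.0))
        assert epochs.n_epochs == 1
        np.testing.assert_array_equal(epochs.data[0], x)

    def test_sub_epoch_signal_is_an_error(self):
        with pytest.raises(ValueError):
            rg.epoch_signal(make_analysis_signal(np.zeros((1, 100)), 250.0))


class TestRejectArtifacts:
    def make_epochs(self, n_ep=10, n_ch=4):
        rng = np.random.default_rng(5)
        sig = make_analysis_signal(rng.standard_normal((n_ch, n_ep * 500)) * 10, 250.0)
        return rg.epoch_signal(sig)

    def test_injected_transient_is_localised(self):
        epochs = self.make_epochs()
        epochs.data[7, 3, 100] = 150.0
        out = rg.reject_artifacts(epochs)
        expected = np.zeros_like(out.mask)
        expected[7, 3] = True
        np.testing.assert_array_equal(out.mask, expected)
        assert (out.data[7, 3] == 0).all()

    def test_clean_epochs_untouched(self):
        out = rg.reject_artifacts(self.make_epochs())
        assert not out.mask.any()
        assert out.rejected_fraction == 0.0

    def test_epoch_with_all_channels_hot_is_rejected(self):
        epochs = self.make_epochs()
        epochs.data[2, :, :] = 200.0
        out = rg.reject_artifacts(epochs)
        assert out.rejected[2]
        assert out.rejected_fraction == pytest.approx(1 / 10)

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            rg.reject_artifacts(self.make_epochs(), threshold=0.0)


class TestDetrendZscore:
    def test_trend_removed_and_residual_standardised(self):
        rng = np.random.default_rng(7)
        t = np.arange(500, dtype=float)
        x_in = 0.02 * t + rng.standard_normal(500)
        epochs = rg.detrend_zscore(rg.epoch_signal(make_analysis_signal(x_in, 250.0)))
        x = epochs.data[0, 0]
        assert x.mean() == pytest.approx(0.0, abs=1e-9)
        assert x.var() == pytest.approx(1.0, rel=1e-6)
        # no residual linear dependence on time
        corr = np.corrcoef(x, t)[0, 1]
        assert abs(corr) < 1e-6

    def test_pure_ramp_is_degenerate_and_zeroed(self):
        # an exactly linear epoch has no residual: left at zeros, not blown up
        ramp = np.linspace(0, 1, 500)
        epochs = rg.detrend_zscore(rg.epoch_signal(make_analysis_signal(ramp, 250.0)))
        assert np.abs(epochs.data).max() < 1e-6

    def test_standardised_noise_passes_through(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(500)
        x = (x - x.mean()) / x.std()
        epochs = rg.epoch_signal(make_analysis_signal(x, 250.0))
        out = rg.detrend_zscore(epochs)
        assert out.data[0, 0].std() == pytest.approx(1.0, rel=1e-9)

    def test_masked_channel_stays_exactly_zero(self):
        epochs = rg.epoch_signal(
            make_analysis_signal(np.full((2, 1000), 5.0), 250.0)
        )
        epochs.data[0, 1, 0] = 500.0
        masked = rg.reject_artifacts(epochs)
        out = rg.detrend_zscore(masked)
        assert (out.data[0, 1] == 0).all()


class TestBandPower:
    def test_pure_alpha_sine_lands_in_alpha_band(self):
        t = np.arange(500) / 250.0
        x = np.sin(2 * np.pi * 10 * t)
        epochs = rg.epoch_signal(make_analysis_signal(x, 250.0))
        bp = rg.band_power(epochs)
        total = sum(bp[b.name][0] for b in rg.DEFAULT_BANDS)
        assert bp["alpha"][0] / total >= 0.95

    def test_parseval_total_power_equals_variance(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((3, 2000))
        epochs = rg.epoch_signal(make_analysis_signal(x, 250.0))
        from scipy.signal import periodogram

        f, p = periodogram(epochs.data, fs=250.0, window="boxcar",
                           detrend=False, scaling="spectrum", axis=2)
        total = p.sum(axis=2)
        ms = (epochs.data ** 2).mean(axis=2)
        np.testing.assert_allclose(total, ms, rtol=0.01)

    def test_zero_epoch_has_zero_power(self):
        epochs = rg.epoch_signal(make_analysis_signal(np.zeros((1, 500)), 250.0))
        bp = rg.band_power(epochs)
        assert all(bp[b.name][0] == 0 for b in rg.DEFAULT_BANDS)

    def test_identical_channels_average_to_single_channel(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(500)
        one = rg.band_power(rg.epoch_signal(make_analysis_signal(x, 250.0)))
        two = rg.band_power(
            rg.epoch_signal(make_analysis_signal(np.vstack([x, x]), 250.0))
        )
        for b in rg.DEFAULT_BANDS:
            assert two[b.name][0] == pytest.approx(one[b.name][0])

    def test_band_above_nyquist_rejected(self):
        # at 80 Hz sampling the 25-45 Hz gamma band exceeds the 40 Hz Nyquist
        epochs = rg.epoch_signal(make_analysis_signal(np.zeros((1, 160)), 80.0))
        with pytest.raises(ValueError, match="gamma"):
            rg.band_power(epochs)

    def test_rejected_epoch_yields_missing_values(self):
        epochs = rg.epoch_signal(
            make_analysis_signal(np.random.default_rng(2).standard_normal((2, 1000)),
                                 250.0)
        )
        epochs.data[1, :, :] = 300.0
        bp = rg.band_power(rg.detrend_zscore(rg.reject_artifacts(epochs)))
        assert np.isnan(bp["gamma"][1])
        assert np.isfinite(bp["gamma"][0])


class TestRelativeGamma:
    def series(self, gamma, alpha, theta):
        df = pd.DataFrame({"gamma": gamma, "alpha": alpha, "theta": theta})
        return BandPowerSeries(powers=df)

    def test_direct_substitution(self):
        out = rg.relative_gamma(self.series([2.0], [0.5], [0.5]))
        assert out.values[0] == pytest.approx(2.0)

    def test_ratio_identity(self):
        out = rg.relative_gamma(self.series([1.0], [0.6], [0.4]))
        assert out.values[0] == pytest.approx(1.0)

    def test_zero_denominator_is_missing_not_error(self):
        out = rg.relative_gamma(self.series([1.0], [0.0], [0.0]))
        assert np.isnan(out.values[0])

    def test_missing_band_is_an_error(self):
        with pytest.raises(ValueError, match="theta"):
            rg.relative_gamma(
                BandPowerSeries(powers=pd.DataFrame({"gamma": [1], "alpha": [1]}))
            )

    def test_invariant_under_common_channel_rescaling(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((4, 2000)) * 10
        a = rg.relative_gamma(rg.band_power(rg.epoch_signal(
            make_analysis_signal(x, 250.0))))
        b = rg.relative_gamma(rg.band_power(rg.epoch_signal(
            make_analysis_signal(3.7 * x, 250.0))))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

    def test_direct_responder_rg_higher_under_stress(self, processed_clean):
        rg_series, _ = processed_clean
        b = rg_series.epoch_boundaries
        v = rg_series.values
        task = v[slice(*b["MIST_TASK"])].mean()
        relax = v[slice(*b["RELAX"])].mean()
        assert task > relax

    def test_epoch_accounting_conserves_duration(self, processed_clean):
        # 480 epochs x 2 s = the 16-minute analysis window
        rg_series, _ = processed_clean
        assert len(rg_series.values) == 480

    def test_rejection_rate_stays_below_study_maximum(self, protocol, profile,
                                                      default_config):
        # study-like artifact rates keep zeroed epoch-channels below 9%
        from rgstress.pipeline import process_session

        subj = rg.SubjectSpec("S", "control", artifact_rate=2.0, seed=29)
        sess = rg.generate_session(protocol, subj, profile)
        _, stats = process_session(sess, default_config)
        assert stats["masked_fraction"] < 0.09
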