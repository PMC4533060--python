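import numpy as np
import pandas as pd
import pytest
from scipy.signal import windows

from nacclfp import spectral as sp
from nacclfp.preprocess import EpochSet


def make_epochs(data, fs=512.0, t0=-0.5):
    n, c, t = data.shape
    return EpochSet(
        data=data, times=t0 + np.arange(t) / fs, fs=fs,
        channels=([f"L{i+1}-L{i+2}" for i in range(c)])[:c],
        lock="outcome_onset", metadata=pd.DataFrame({"trial": np.arange(n)}),
    )


def sinusoid_epochs(freq, n_trials=3, n_ch=1, dur=3.0, fs=512.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    sig = amp * np.cos(2 * np.pi * freq * t)
    data = np.tile(sig, (n_trials, n_ch, 1))
    return make_epochs(data, fs=fs)


class TestTFLow:
    def test_frequency_grid(self):
        tfr = sp.tf_low(sinusoid_epochs(10.0))
        assert tfr.freqs[0] == 2.5 and tfr.freqs[-1] == 40.0
        assert np.allclose(np.diff(tfr.freqs), 2.5)
        assert tfr.recipe == "low"

    def test_pure_tone_concentrated_and_stationary(self):
        tfr = sp.tf_low(sinusoid_epochs(10.0, amp=1.0))
        p = tfr.power[0, 0][:, tfr.valid]
        peak_bin = np.argmax(p.mean(axis=1))
        assert tfr.freqs[peak_bin] == 10.0
        # unit-amplitude tone -> power ~= 1 at its bin, stationary in time
        trace = p[peak_bin]
        assert trace.mean() == pytest.approx(1.0, rel=0.05)
        assert trace.std() / trace.mean() < 0.05
        # concentration: off-peak bins (beyond taper main lobe) are tiny
        far = np.abs(tfr.freqs - 10.0) > 5.0
        assert p[far].max() < 0.01 * trace.mean()

    def test_white_noise_flat_spectrum(self, rng):
        data = rng.standard_normal((60, 1, 1536))
        tfr = sp.tf_low(make_epochs(data))
        spec = np.nanmean(tfr.power[:, 0], axis=(0, 2))
        assert spec.max() / spec.min() < 1.6

    def test_zero_in_zero_out(self):
        tfr = sp.tf_low(make_epochs(np.zeros((2, 1, 1024))))
        assert np.nanmax(tfr.power) == 0.0

    def test_edges_marked_invalid(self):
        tfr = sp.tf_low(make_epochs(np.zeros((1, 1, 1024))))
        assert not tfr.valid[0]
        assert not tfr.valid[-1]
        assert tfr.valid.any()
        assert np.isnan(tfr.power[..., ~tfr.valid]).all()

    def test_unresolvable_frequency_rejected(self):
        with pytest.raises(ValueError):
            sp.tf_low(sinusoid_epochs(10.0), freqs=np.array([1.0]))

    def test_parseval_total_power_tracks_variance(self, rng):
        data = rng.standard_normal((20, 1, 2048))
        tfr = sp.tf_low(make_epochs(data), freqs=np.arange(2.5, 256, 2.5))
        total = np.nanmean(np.nansum(tfr.power[..., tfr.valid], axis=2))
        # amplitude-normalized Hanning estimate of white noise: each bin's
        # expected power is var * 4*sum(w^2)/sum(w)^2
        w = windows.hann(int(round(0.4 * 512)), sym=False)
        per_bin = data.var() * 4 * (w**2).sum() / w.sum() ** 2
        expected = len(tfr.freqs) * per_bin
        assert total == pytest.approx(expected, rel=0.10)


class TestTFHigh:
    def test_taper_count_is_seven(self):
        # NW = 0.2 s x 20 Hz = 4 -> 2NW-1 = 7 Slepians
        n_win = int(round(0.2 * 512))
        tapers = windows.dpss(n_win, 4.0, Kmax=7)
        assert tapers.shape[0] == 7

    def test_frequency_grid(self):
        tfr = sp.tf_high(sinusoid_epochs(100.0))
        assert tfr.freqs[0] == 30.0 and tfr.freqs[-1] == 250.0
        assert np.allclose(np.diff(tfr.freqs), 5.0)

    def test_tone_smoothed_over_bandwidth(self):
        tfr = sp.tf_high(sinusoid_epochs(100.0))
        spec = np.nanmean(tfr.power[0, 0][:, tfr.valid], axis=1)
        peak = spec.max()
        half = spec >= 0.5 * peak
        span = tfr.freqs[half]
        assert tfr.freqs[np.argmax(spec)] == pytest.approx(100.0, abs=5.0)
        # half-maximum support reflects the +/-20 Hz multitaper smoothing
        assert span.min() >= 70.0 and span.max() <= 130.0
        assert span.max() - span.min() >= 25.0

    def test_zero_in_zero_out(self):
        tfr = sp.tf_high(make_epochs(np.zeros((2, 1, 512))))
        assert np.nanmax(tfr.power) == 0.0

    def test_recipes_agree_on_midband_tone(self):
        # 35 Hz tone lives in both grids; log-power time courses should agree
        ep = sinusoid_epochs(35.0, dur=3.0)
        lo = sp.tf_low(ep)
        hi = sp.tf_high(ep)
        common = lo.valid & hi.valid
        a = np.log(lo.power[0, 0, lo.freqs == 35.0, common].ravel())
        b = np.log(hi.power[0, 0, hi.freqs == 35.0, common].ravel())
        assert np.corrcoef(a, b)[0, 1] > 0.9 or (a.std() < 0.05 and b.std() < 0.05)


class TestERPAverage:
    def test_identical_trials(self):
        data = np.tile(np.sin(np.linspace(0, 6, 256)), (5, 2, 1))
        erp = sp.erp_average(make_epochs(data))
        assert np.allclose(erp.mean, data[0])
        assert erp.n_trials == 5

    def test_opposite_pairs_cancel(self, rng):
        s = rng.standard_normal((1, 2, 128))
        data = np.concatenate([s, -s])
        erp = sp.erp_average(make_epochs(data))
        assert np.allclose(erp.mean, 0.0)

    def test_empty_mask_rejected(self):
        data = np.zeros((3, 1, 64))
        with pytest.raises(ValueError):
            sp.erp_average(make_epochs(data), mask=np.zeros(3, bool))

    def test_generator_amplitude_ratio(self, small_trials):
        from nacclfp import preprocess as pp
        from nacclfp import synthetic_lfp as sl

        cfg = sl.SyntheticConfig(
            seed=31, erp_gain_amp=8.0, erp_loss_amp=4.0, erp_reversal=False,
            noise_scale=0.5, reference_scale=0.5, line_amplitude=0.0, beta_base_amp=0.0,
        )
        rec = sl.synthesize_recording(small_trials, cfg)
        bip = pp.bipolar_montage(rec)
        ep = pp.epoch(bip, "outcome_onset", (0.0, 0.3), small_trials)
        won = ep.metadata["outcome_cents"].to_numpy() > 0
        gain = sp.erp_average(ep, won)
        loss = sp.erp_average(ep, ~won)
        ratio = np.abs(gain.mean[0]).max() / np.abs(loss.mean[0]).max()
        assert ratio == pytest.approx(2.0, rel=0.2)


class TestBaselinePower:
    def _options_tfr(self, rng, n=12):
        data = rng.standard_normal((n, 2, 1536))
        ep = make_epochs(data, t0=-1.5)
        ep.lock = "options_onset"
        return sp.tf_low(ep)

    def test_stationary_noise_matches_other_windows(self, rng):
        tfr = self._options_tfr(rng, n=40)
        base = sp.baseline_power(tfr)
        other = tfr.power[:, :, :, tfr.valid & (tfr.times >= -0.2)].mean(axis=3)
        ratio = base.mean() / other.mean()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_zero_signal_zero_baseline(self):
        ep = make_epochs(np.zeros((3, 1, 1536)), t0=-1.5)
        base = sp.baseline_power(sp.tf_low(ep))
        assert np.all(base == 0.0)

    def test_uncovered_window_errors(self):
        ep = make_epochs(np.zeros((3, 1, 1024)), t0=0.0)
        with pytest.raises(ValueError):
            sp.baseline_power(sp.tf_low(ep))

    def test_post_outcome_burst_leaves_baseline_unchanged(self, rng):
        quiet = self._options_tfr(rng)
        data = rng.standard_normal((12, 2, 1536))
        data[:, :, 1200:] += 20 * np.sin(2 * np.pi * 20 * np.arange(336) / 512.0)
        ep = make_epochs(data, t0=-1.5)
        loud = sp.tf_low(ep)
        a = sp.baseline_power(quiet).mean()
        b = sp.baseline_power(loud).mean()
        assert b == pytest.approx(a, rel=0.25)


class TestChannelAveraging:
    def test_hemisphere_grouping(self, rng):
        data = rng.standard_normal((4, 6, 1024))
        ep = make_epochs(data)
        ep.channels = ["L1-L2", "L2-L3", "L3-L4", "R1-R2", "R2-R3", "R3-R4"]
        tfr = sp.tf_low(ep)
        pooled = tfr.average_channels()
        assert pooled.channels == ["L", "R"]
        manual = tfr.power[:, :3].mean(axis=1)
        assert np.allclose(pooled.power[:, 0], manual, equal_nan=True)

    def test_averaging_commutes_with_selection(self, rng):
        data = rng.standard_normal((4, 6, 1024))
        ep = make_epochs(data)
        ep.channels = ["L1-L2", "L2-L3", "L3-L4", "R1-R2", "R2-R3", "R3-R4"]
        tfr = sp.tf_low(ep)
        sel = tfr.valid
        a = tfr.average_channels().power[..., sel]
        b = tfr.power[..., sel][:, :3].mean(axis=1)
        assert np.allclose(a[:, 0], b)
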