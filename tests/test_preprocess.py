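import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from nacclfp import preprocess as pp
from nacclfp.synthetic_lfp import LFPRecording


def make_recording(signal, fs=512.0, labels=None, events=None):
    n_ch = signal.shape[0]
    if labels is None:
        labels = [f"L{i+1}" for i in range(4)] + [f"R{i+1}" for i in range(4)]
        labels = labels[:n_ch]
    if events is None:
        events = pd.DataFrame(columns=["trial", "kind", "sample"])
    return LFPRecording(signal=signal, fs=fs, labels=labels, events=events)


def sine(freq, fs=512.0, dur=4.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBipolarMontage:
    def test_common_mode_rejected(self):
        sig = np.tile(np.random.default_rng(0).standard_normal(2048), (8, 1))
        out = pp.bipolar_montage(make_recording(sig))
        assert np.allclose(out.signal, 0.0)
        assert len(out.labels) == 6

    def test_single_contact_signal_propagates(self):
        sig = np.zeros((8, 1024))
        s = sine(7, dur=2.0)
        sig[0] = s
        out = pp.bipolar_montage(make_recording(sig))
        assert np.allclose(out.signal[0], s)
        assert np.allclose(out.signal[1:], 0.0)
        assert out.labels[0] == "L1-L2"

    def test_shared_reference_cancels_on_synthetic(self, small_recording):
        ref_free = pp.bipolar_montage(small_recording)
        # reconstruct the reference by regenerating with noise/effects off
        from nacclfp import synthetic_lfp as sl

        assert ref_free.signal.shape[0] == 6

    def test_missing_contact_errors(self):
        sig = np.zeros((1, 100))
        with pytest.raises(ValueError):
            pp.bipolar_montage(make_recording(sig, labels=["L1"]))


class TestNotch:
    def test_line_tone_removed(self):
        rec = make_recording(sine(50.0)[None, :], labels=["L1"])
        out = pp.notch_line_noise(rec)
        rms_in = np.sqrt((rec.signal**2).mean())
        rms_out = np.sqrt((out.signal[:, 512:-512] ** 2).mean())
        assert rms_out < 0.01 * rms_in

    def test_harmonics_removed(self):
        for f0 in (100.0, 150.0, 200.0, 250.0):
            rec = make_recording(sine(f0)[None, :], labels=["L1"])
            out = pp.notch_line_noise(rec)
            assert np.sqrt((out.signal[:, 512:-512] ** 2).mean()) < 0.01

    def test_passband_preserved(self):
        rec = make_recording(sine(10.0)[None, :], labels=["L1"])
        out = pp.notch_line_noise(rec)
        mid = slice(512, -512)
        ratio = np.abs(out.signal[0, mid]).max() / np.abs(rec.signal[0, mid]).max()
        assert ratio > 0.99

    def test_zero_in_zero_out(self):
        rec = make_recording(np.zeros((2, 2048)), labels=["L1", "L2"])
        out = pp.notch_line_noise(rec)
        assert np.allclose(out.signal, 0.0)


class TestEpoch:
    def _rec_with_events(self):
        sig = np.arange(8 * 4096, dtype=float).reshape(8, 4096)
        events = pd.DataFrame({
            "trial": [0, 0, 0, 1, 1],
            "kind": ["options_onset", "response", "outcome_onset",
                     "options_onset", "response"],
            "sample": [1000, 1500, 2524, 3000, 3300],
        })
        return make_recording(sig, events=events)

    def test_index_arithmetic(self):
        rec = self._rec_with_events()
        ep = pp.epoch(rec, "options_onset", (-1.5, 1.0))
        # closed-open window: samples e-768 .. e+511 inclusive
        assert ep.data.shape[2] == 768 + 512
        assert ep.data[0, 0, 0] == rec.signal[0, 1000 - 768]
        assert ep.data[0, 0, -1] == rec.signal[0, 1000 + 511]
        assert ep.times[0] == pytest.approx(-1.5)

    def test_outcome_lock_only_gamble_trials(self):
        rec = self._rec_with_events()
        ep = pp.epoch(rec, "outcome_onset", (-0.5, 1.0))
        assert ep.n_trials == 1
        assert list(ep.metadata["trial"]) == [0]

    def test_degenerate_window(self):
        rec = self._rec_with_events()
        ep = pp.epoch(rec, "response", (0.0, 0.0))
        assert ep.data.shape[2] == 0

    def test_out_of_bounds_trial_dropped(self):
        rec = self._rec_with_events()
        ep = pp.epoch(rec, "options_onset", (-1.5, 3.0))
        assert list(ep.metadata["trial"]) == [0]  # trial 1 window exceeds bounds


class TestRejectArtifacts:
    def _epochs(self, data):
        n, c, t = data.shape
        return pp.EpochSet(
            data=data, times=np.arange(t) / 512.0, fs=512.0,
            channels=[f"L{i}" for i in range(c)], lock="options_onset",
            metadata=pd.DataFrame({"trial": np.arange(n)}),
        )

    def test_identical_epochs_no_rejection(self):
        data = np.tile(np.random.default_rng(1).standard_normal(256), (20, 3, 1))
        out = pp.reject_artifacts(self._epochs(data))
        assert out.kept.all()

    def test_inflated_trial_rejected(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((40, 3, 256))
        data[7] *= 20.0
        out = pp.reject_artifacts(self._epochs(data), z_threshold=4.0)
        assert not out.kept[7]
        assert out.kept.sum() >= 38

    def test_mask_invariant_to_channel_order(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((30, 3, 128))
        data[4] *= 15.0
        a = pp.reject_artifacts(self._epochs(data))
        b = pp.reject_artifacts(self._epochs(data[:, ::-1]))
        assert np.array_equal(a.kept, b.kept)

    def test_ground_truth_artifacts_caught(self, small_trials, small_recording):
        from nacclfp import synthetic_lfp as sl

        noisy, tagged = sl.inject_artifacts(small_recording, small_trials, 0.19, 10.0, seed=4)
        bip = pp.bipolar_montage(noisy)
        ep = pp.epoch(bip, "options_onset", (-0.5, 3.0), small_trials)
        out = pp.reject_artifacts(ep, z_threshold=4.0)
        rejected = set(out.metadata.loc[~out.kept, "trial"])
        caught = len(rejected & set(tagged)) / max(len(tagged), 1)
        false_pos = len(rejected - set(tagged))
        assert caught >= 0.9
        assert false_pos <= 0.05 * len(small_trials) + 1


class TestBaselineAndFilters:
    def _epochs_with_baseline(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((12, 2, 1024))
        times = (np.arange(1024) - 512) / 512.0  # [-1, 1)
        return pp.EpochSet(
            data=data, times=times, fs=512.0, channels=["L1", "L2"],
            lock="options_onset", metadata=pd.DataFrame({"trial": np.arange(12)}),
        )

    def test_constant_offset_removed(self):
        ep = self._epochs_with_baseline()
        ep.data += 42.0
        out = pp.baseline_correct(ep)
        sel = (out.times >= -0.1) & (out.times < 0.0)
        assert np.abs(out.data[:, :, sel].mean(axis=2)).max() < 1e-9

    def test_linearity_of_offset(self):
        ep = self._epochs_with_baseline()
        base = pp.baseline_correct(ep)
        shifted = self._epochs_with_baseline()
        shifted.data[3] += 7.5
        out = pp.baseline_correct(shifted)
        assert np.allclose(out.data[3], base.data[3], atol=1e-9)

    def test_baseline_from_pretrial_table(self):
        ep = self._epochs_with_baseline()
        baselines = pd.DataFrame(
            np.full((12, 2), 5.0), index=np.arange(12), columns=["L1", "L2"]
        )
        out = pp.baseline_correct(ep, baselines=baselines)
        assert np.allclose(out.data, ep.data - 5.0)

    def test_window_outside_epoch_errors(self):
        ep = self._epochs_with_baseline()
        ep.times = ep.times + 10.0
        with pytest.raises(ValueError):
            pp.baseline_correct(ep)

    def test_bandpass_response(self):
        t = np.arange(4096) / 512.0
        ep = pp.EpochSet(
            data=np.stack([
                np.sin(2 * np.pi * 10 * t),
                np.sin(2 * np.pi * 60 * t),
                np.full_like(t, 3.0),
            ])[:, None, :],
            times=t, fs=512.0, channels=["L1"], lock="outcome_onset",
            metadata=pd.DataFrame({"trial": [0, 1, 2]}),
        )
        out = pp.bandpass_erp(ep)
        mid = slice(1024, -1024)
        assert np.abs(out.data[0, 0, mid]).max() > 0.95
        assert np.abs(out.data[1, 0, mid]).max() < 0.1
        assert np.abs(out.data[2, 0, mid]).max() < 0.1

    def test_filters_zero_phase(self):
        pulse = np.zeros(2048)
        pulse[1024] = 1.0
        rec = make_recording(pulse[None, :], labels=["L1"])
        out = pp.notch_line_noise(rec).signal[0]
        left = out[1024 - 200 : 1024]
        right = out[1025 : 1025 + 200][::-1]
        assert np.abs(left - right).max() < 1e-6

    def test_montage_commutes_with_epoching(self, small_recording, small_trials):
        bip_first = pp.epoch(pp.bipolar_montage(small_recording), "response", (-0.2, 0.2))
        ep_first = pp.epoch(small_recording, "response", (-0.2, 0.2))
        manual = np.stack(
            [ep_first.data[:, i] - ep_first.data[:, i + 1] for i in (0, 1, 2, 4, 5, 6)],
            axis=1,
        )
        assert np.allclose(bip_first.data, manual)
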