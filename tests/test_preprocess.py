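import numpy as np
import pytest

from cfassess.core import Epochs, RawRecording, events_frame
from cfassess.preprocess import (
    bandpass_filter,
    epoch,
    match_trial_counts,
    preprocess_recording,
    reject_artifacts,
    rereference_bipolar,
    resample,
)
from cfassess.synthetic import SimConfig, simulate_recording


def _sine_raw(freq, sfreq=256.0, duration=30.0, events=None):
    t = np.arange(int(duration * sfreq)) / sfreq
    x = np.sin(2 * np.pi * freq * t)
    return RawRecording(
        x[None, :], sfreq, ["C3"], events if events is not None else events_frame([], [])
    )


def _rms(x):
    return np.sqrt(np.mean(x**2))


class TestBandpass:
    def test_passband_10hz_zero_phase(self):
        raw = _sine_raw(10.0)
        out = bandpass_filter(raw).data[0]
        core = slice(int(5 * 256), int(25 * 256))
        x = raw.data[0]
        assert _rms(out[core]) / _rms(x[core]) > 0.95
        # zero phase: peak cross-correlation at zero lag
        xc = np.correlate(out[core], x[core], mode="same")
        assert np.argmax(xc) == len(xc) // 2

    @pytest.mark.parametrize("freq", [0.2, 60.0])
    def test_stopband(self, freq):
        raw = _sine_raw(freq)
        out = bandpass_filter(raw).data[0]
        core = slice(int(5 * 256), int(25 * 256))
        assert _rms(out[core]) / _rms(raw.data[0][core]) < 0.10

    def test_too_short_recording(self):
        raw = _sine_raw(10.0, duration=2.0)
        with pytest.raises(ValueError, match="too short"):
            bandpass_filter(raw)

    def test_length_preserved(self):
        raw = _sine_raw(10.0)
        assert bandpass_filter(raw).n_samples == raw.n_samples


class TestResample:
    def test_length_ratio(self):
        raw = _sine_raw(10.0, sfreq=256.0, duration=10.0)
        out = resample(raw, 100.0)
        assert out.n_samples == 1000
        assert out.sfreq == 100.0

    def test_sinusoid_amplitude_preserved(self):
        raw = _sine_raw(10.0, duration=10.0)
        out = resample(raw, 100.0).data[0]
        t = np.arange(len(out)) / 100.0
        # least-squares sinusoid fit at 10 Hz
        design = np.column_stack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)])
        core = slice(100, 900)
        coef, *_ = np.linalg.lstsq(design[core], out[core], rcond=None)
        assert np.hypot(*coef) == pytest.approx(1.0, abs=0.02)

    def test_event_remapping(self):
        raw = _sine_raw(10.0, duration=10.0, events=events_frame([256], ["left"]))
        out = resample(raw, 100.0)
        assert out.events["onset_sample"].tolist() == [100]

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample(_sine_raw(10.0), 512.0)


class TestEpoch:
    def _raw_with_events(self, onsets, n=12_000, sfreq=100.0):
        data = np.arange(n, dtype=float)[None, :]
        return RawRecording(data, sfreq, ["C3"], events_frame(onsets, ["left"] * len(onsets)))

    def test_counts_and_geometry(self):
        raw = self._raw_with_events([0, 1000, 2000])
        ep = epoch(raw)
        assert ep.data.shape == (3, 1, 600)
        assert ep.times[0] == -2.0
        assert ep.times[-1] == pytest.approx(4.0 - 0.01)

    def test_constant_channel(self):
        raw = RawRecording(
            np.full((1, 2000), 7.0), 100.0, ["C3"], events_frame([100], ["rest"])
        )
        ep = epoch(raw)
        assert np.all(ep.data == 7.0)

    def test_event_near_end_dropped(self):
        raw = self._raw_with_events([0, 11_999])
        with pytest.warns(UserWarning, match="dropping"):
            ep = epoch(raw)
        assert ep.n_trials == 1

    def test_epoch_content_matches_source(self):
        raw = self._raw_with_events([1000])
        ep = epoch(raw)
        assert np.array_equal(ep.data[0, 0], np.arange(1000, 1600, dtype=float))


class TestRejection:
    def _epochs(self, rng, n=40):
        data = rng.normal(0, 10, size=(n, 2, 600))
        conds = np.array((["left", "rest"] * n)[:n], dtype=object)
        return Epochs(data, 100.0, ["C3'", "C4'"], conds, montage="bipolar")

    def test_infinite_threshold_keeps_all(self, rng):
        ep = self._epochs(rng)
        kept, report = reject_artifacts(ep, ptp_threshold=np.inf, var_zmax=np.inf)
        assert kept.n_trials == ep.n_trials
        assert len(report.rejected) == 0

    def test_single_huge_spike_rejected(self, rng):
        ep = self._epochs(rng)
        ep.data[5, 0, 300] = 10_000.0
        kept, report = reject_artifacts(ep)
        assert 5 in report.rejected
        assert kept.n_trials == ep.n_trials - len(report.rejected)

    def test_report_accounting(self, rng):
        ep = self._epochs(rng)
        ep.data[3] *= 50
        _, report = reject_artifacts(ep)
        assert len(report.kept) + len(report.rejected) == ep.n_trials
        assert sum(report.kept_per_condition.values()) == len(report.kept)
        assert report.params["ptp_threshold"] == 150.0

    def test_all_rejected_is_error(self, rng):
        ep = self._epochs(rng, n=4)
        ep.data *= 1e6
        with pytest.raises(RuntimeError):
            reject_artifacts(ep)

    def test_synthetic_artifacts_detected(self):
        # simulator ground truth: >=90% of annotated artifact trials rejected,
        # <=5% of clean trials falsely rejected
        cfg = SimConfig(n_blocks=5, seed=21, artifact_rate=0.1)
        sim = simulate_recording(cfg)
        epochs, report = preprocess_recording(sim.recording, reject=True)
        rejected = set(int(i) for i in report.rejected)
        annotated = set(int(i) for i in sim.artifact_trials)
        assert len(annotated & rejected) >= 0.9 * len(annotated)
        clean = set(range(report.n_total)) - annotated
        assert len(clean & rejected) <= 0.05 * len(clean)


class TestBipolar:
    def _mono(self, data_map, n=600):
        labels = list(data_map)
        data = np.stack([data_map[c] for c in labels])[None, :, :]
        return Epochs(data, 100.0, labels, ["left"], montage="monopolar")

    def test_identity_cancellation(self):
        x = np.random.default_rng(0).normal(size=600)
        ep = self._mono({"FC3": x, "CP3": x, "FC4": x, "CP4": np.zeros(600)})
        out = rereference_bipolar(ep)
        assert out.ch_names == ["C3'", "C4'"]
        assert np.allclose(out.data[0, 0], 0.0)
        assert np.allclose(out.data[0, 1], x)
        assert out.montage == "bipolar"

    def test_label_based_lookup_order_invariant(self):
        rng = np.random.default_rng(1)
        chans = {c: rng.normal(size=600) for c in ["FC3", "CP3", "FC4", "CP4", "Cz"]}
        a = rereference_bipolar(self._mono(chans))
        permuted = {c: chans[c] for c in ["Cz", "CP4", "FC3", "CP3", "FC4"]}
        b = rereference_bipolar(self._mono(permuted))
        assert np.array_equal(a.data, b.data)

    def test_reference_free(self):
        rng = np.random.default_rng(2)
        chans = {c: rng.normal(size=600) for c in ["FC3", "CP3", "FC4", "CP4"]}
        a = rereference_bipolar(self._mono(chans))
        common = rng.normal(size=600)
        shifted = {c: x + common for c, x in chans.items()}
        b = rereference_bipolar(self._mono(shifted))
        # exact up to float addition rounding
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_missing_electrode_named(self):
        ep = self._mono({"FC3": np.zeros(600), "CP3": np.zeros(600), "FC4": np.zeros(600)})
        with pytest.raises(ValueError, match="CP4"):
            rereference_bipolar(ep)


class TestMatchCounts:
    def _epochs(self, counts):
        conds = np.concatenate([[c] * n for c, n in counts.items()]).astype(object)
        data = np.arange(len(conds))[:, None, None] * np.ones((1, 1, 10))
        return Epochs(data, 100.0, ["C3'"], conds, montage="bipolar")

    def test_exact_target_counts(self):
        ep = self._epochs({"left": 40, "right": 40, "rest": 40})
        out = match_trial_counts(ep, {"left": 36, "right": 33, "rest": 34}, seed=0)
        assert out.condition_counts() == {"left": 36, "right": 33, "rest": 34}

    def test_identity_when_targets_equal(self):
        ep = self._epochs({"left": 10, "rest": 10})
        out = match_trial_counts(ep, {"left": 10, "rest": 10}, seed=0)
        assert np.array_equal(out.data, ep.data)

    def test_deterministic(self):
        ep = self._epochs({"left": 40, "rest": 40})
        a = match_trial_counts(ep, {"left": 20, "rest": 30}, seed=5)
        b = match_trial_counts(ep, {"left": 20, "rest": 30}, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_deficit_reported(self):
        ep = self._epochs({"left": 10, "rest": 10})
        with pytest.raises(ValueError, match="deficit 5"):
            match_trial_counts(ep, {"left": 15}, seed=0)


class TestFullChain:
    def test_labels_and_order_preserved(self):
        sim = simulate_recording(SimConfig(n_blocks=1, seed=13))
        epochs, _ = preprocess_recording(sim.recording, reject=False)
        assert epochs.conditions.tolist() == sim.schedule.conditions.tolist()
        assert epochs.data.shape == (36, 2, 600)

    def test_filter_resample_commute_with_epoching(self):
        # filtering/resampling then epoching ~= epoching padded data then
        # filtering, in the central 5 s of the epoch
        sim = simulate_recording(SimConfig(n_blocks=1, seed=17))
        a, _ = preprocess_recording(sim.recording, resample_first=True, reject=False)
        b, _ = preprocess_recording(sim.recording, resample_first=False, reject=False)
        core = slice(50, 550)
        num = np.sqrt(np.mean((a.data[..., core] - b.data[..., core]) ** 2))
        den = np.sqrt(np.mean(b.data[..., core] ** 2))
        # the two orders use different FIR orders (designed at 100 vs 256 Hz),
        # so small band-edge differences remain
        assert num / den < 0.02
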