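import warnings
from dataclasses import replace

import numpy as np
import pytest

from arousalkit.biofeedback import (
    FrameMapping,
    PeakDetectionConfig,
    baseline_correct,
    bipolar_difference,
    extract_heart_rate,
    laterality_index,
    make_frame,
    run_feedback_loop,
    write_frame_log,
)
from arousalkit.features_spectral import BAND_PRESETS, BandPowerSet
from arousalkit.signal_io import MultiChannelSignal
from arousalkit.synthetic import SyntheticEEGConfig, generate_eeg

FS = 128.0


def alpha_bp(alpha):
    return BandPowerSet(alpha=alpha, beta=1.0, delta=0, theta=0, gamma=0,
                        band_edges=BAND_PRESETS["eq23"])


class TestBaselineCorrect:
    def test_planted_drift_removed(self, rng):
        t = np.arange(int(10 * FS)) / FS
        pulses = np.zeros_like(t)
        pulses[::86] = 80.0  # sparse spikes the median must ignore
        x = pulses + 50.0 * t  # 50 uV/s drift
        out = baseline_correct(x, FS)
        slope = np.polyfit(t, out, 1)[0]
        assert abs(slope) < 0.5

    def test_constant_input_zeroed(self):
        out = baseline_correct(np.full(int(2 * FS), 37.0), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_zero_mean_noise_nearly_unchanged(self, rng):
        x = rng.standard_normal(int(4 * FS))
        out = baseline_correct(x, FS)
        # correction only removes the slow median track
        assert np.corrcoef(x, out)[0, 1] > 0.9


class TestBipolarDifference:
    def test_identical_channels_cancel(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(bipolar_difference(x, x), np.zeros(100))

    def test_hand_example(self):
        np.testing.assert_array_equal(bipolar_difference([1, 2], [0, 1]), [1, 1])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bipolar_difference([1, 2, 3], [1, 2])

    def test_opposite_polarity_artifact_doubles(self):
        sig, lab = generate_eeg(SyntheticEEGConfig(
            schedule=(("rest", 10.0),), seed=5, noise_amplitude=0.0,
            band_gains={"delta": 0, "theta": 0, "alpha": 0, "beta": 0, "gamma": 0},
            cardiac_amplitude=50.0, jitter_sd_ms=0.0))
        d = bipolar_difference(sig.channel("FT9"), sig.channel("FT10"))
        assert d.max() == pytest.approx(2 * sig.channel("FT9").max(), rel=1e-6)


class TestHeartRate:
    def test_recovers_planted_72_bpm(self):
        sig, _ = generate_eeg(SyntheticEEGConfig(
            schedule=(("rest", 10.0),), seed=11, cardiac_bpm=72.0, cardiac_snr=5.0))
        hr = extract_heart_rate(sig)
        assert 70 <= hr.bpm <= 74

    def test_spurious_spike_rejected_without_losing_beats(self):
        # strong artifact so the sub-amplitude spikes clear detection and
        # reach the amplitude gate (25% of beat amplitude < 30% cutoff)
        sig, lab = generate_eeg(SyntheticEEGConfig(
            schedule=(("rest", 30.0),), seed=13, cardiac_bpm=60.0, cardiac_snr=8.0,
            spurious_spikes_per_min=6.0, spurious_amplitude_fraction=0.25))
        hr = extract_heart_rate(sig)
        assert 58 <= hr.bpm <= 62
        assert any(reason == "amplitude" for _, reason in hr.rejected_peaks)
        # every true beat inside the guard band is matched by an accepted peak
        accepted_t = hr.accepted_peaks / FS
        inner = [t for t in lab.beat_times if 0.3 < t < 29.7]
        matched = sum(np.min(np.abs(accepted_t - t)) < 0.1 for t in inner)
        assert matched >= 0.95 * len(inner)

    def test_pure_noise_gives_nan(self, rng):
        sig, _ = generate_eeg(SyntheticEEGConfig(
            schedule=(("rest", 10.0),), seed=17, cardiac_amplitude=0.0))
        with pytest.warns(UserWarning):
            hr = extract_heart_rate(sig)
        assert np.isnan(hr.bpm)

    def test_missing_cardiac_channel_raises(self, rng):
        sig = MultiChannelSignal(rng.standard_normal((1280, 2)), fs=FS,
                                 channel_names=["F3", "F4"])
        with pytest.raises(KeyError):
            extract_heart_rate(sig)

    def test_bpm_definition_from_accepted_peaks(self):
        sig, _ = generate_eeg(SyntheticEEGConfig(
            schedule=(("rest", 10.0),), seed=19, cardiac_bpm=80.0))
        hr = extract_heart_rate(sig)
        span = (hr.accepted_peaks[-1] - hr.accepted_peaks[0]) / FS
        assert hr.bpm == pytest.approx(60.0 * (len(hr.accepted_peaks) - 1) / span)

    def test_median_error_under_2bpm_at_snr_3(self):
        errs = []
        rng = np.random.default_rng(99)
        for k in range(20):
            bpm = rng.uniform(55, 140)
            sig, lab = generate_eeg(SyntheticEEGConfig(
                schedule=(("rest", 10.0),), seed=2000 + k,
                cardiac_bpm=bpm, cardiac_snr=3.0))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hr = extract_heart_rate(sig)
            bt = lab.beat_times
            true = 60.0 * (len(bt) - 1) / (bt[-1] - bt[0])
            errs.append(abs(hr.bpm - true))
        assert np.median(errs) <= 2.0


class TestLaterality:
    def test_symmetric_hemispheres_give_zero(self):
        li = laterality_index(alpha_bp(2.0), alpha_bp(2.0), alpha_bp(1.0), alpha_bp(1.0))
        assert li.li == 0.0

    def test_right_three_times_left(self):
        li = laterality_index(alpha_bp(1.0), alpha_bp(3.0), alpha_bp(0.0), alpha_bp(0.0))
        assert li.li == pytest.approx(0.5)

    def test_antisymmetric_under_hemisphere_swap(self, rng):
        a, b, c, d = rng.uniform(0.1, 5.0, 4)
        fwd = laterality_index(alpha_bp(a), alpha_bp(b), alpha_bp(c), alpha_bp(d))
        rev = laterality_index(alpha_bp(b), alpha_bp(a), alpha_bp(d), alpha_bp(c))
        assert fwd.li == pytest.approx(-rev.li)
        assert -1.0 <= fwd.li <= 1.0

    def test_monotone_in_planted_asymmetry(self):
        lis = []
        for ratio in (0.5, 1.0, 2.0, 4.0):
            sig, _ = generate_eeg(SyntheticEEGConfig(
                schedule=(("rest", 5.0),), seed=23, asymmetry=ratio))
            from arousalkit.features_spectral import window_band_powers
            from arousalkit.signal_io import segment
            win = segment(sig, 5.0)[0]
            bp = window_band_powers(win, ["F3", "F4", "AF3", "AF4"])
            lis.append(laterality_index(bp["F3"], bp["F4"], bp["AF3"], bp["AF4"]).li)
        assert lis == sorted(lis)

    def test_zero_power_sentinel(self):
        with pytest.warns(UserWarning):
            li = laterality_index(alpha_bp(0.0), alpha_bp(0.0), alpha_bp(0.0), alpha_bp(0.0))
        assert np.isnan(li.li)


class TestFrames:
    @pytest.mark.parametrize("bpm,level", [(59.0, 0), (65.0, 1), (85.0, 2),
                                           (119.9, 3), (120.0, 4)])
    def test_heart_level_binning(self, bpm, level):
        assert make_frame(bpm, 0.0).heart_level == level

    def test_boundary_steps_by_one(self):
        below = make_frame(79.999, 0.0).heart_level
        above = make_frame(80.001, 0.0).heart_level
        assert above - below == 1

    def test_unordered_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            FrameMapping(bpm_breakpoints=(80.0, 60.0))

    def test_invalid_inputs_flagged(self):
        fr = make_frame(float("nan"), 0.1)
        assert not fr.valid


class TestFeedbackLoop:
    def test_frame_count_and_latency(self):
        sig, _ = generate_eeg(SyntheticEEGConfig(schedule=(("rest", 30.0),), seed=29))
        frames = run_feedback_loop(sig)
        assert len(frames) == 6
        assert [f.timestamp for f in frames] == [5.0, 10.0, 15.0, 20.0, 25.0, 30.0]

    def test_constant_hr_constant_levels(self):
        sig, _ = generate_eeg(SyntheticEEGConfig(
            schedule=(("rest", 30.0),), seed=31, cardiac_bpm=90.0, jitter_sd_ms=5.0))
        frames = run_feedback_loop(sig)
        assert len({f.heart_level for f in frames}) == 1

    def test_ramped_hr_levels_nondecreasing(self):
        sig, _ = generate_eeg(SyntheticEEGConfig(
            schedule=(("rest", 60.0),), seed=37, cardiac_bpm=(60.0, 120.0),
            jitter_sd_ms=5.0, cardiac_snr=5.0))
        levels = [f.heart_level for f in run_feedback_loop(sig)]
        assert levels == sorted(levels)

    def test_frame_log_deterministic_bytes(self, tmp_path):
        sig, _ = generate_eeg(SyntheticEEGConfig(schedule=(("rest", 15.0),), seed=41))
        p1, p2 = tmp_path / "a.ndjson", tmp_path / "b.ndjson"
        write_frame_log(run_feedback_loop(sig), p1)
        write_frame_log(run_feedback_loop(sig), p2)
        assert p1.read_bytes() == p2.read_bytes()
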