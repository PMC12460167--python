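"""Stimulus synthesis: calibration, grids, batteries and mixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from iccode import stimuli as st
from iccode.errors import CalibrationError, StimulusError


class TestCalibration:
    def test_rms_004_is_94_db(self):
        x = np.sin(2 * np.pi * 1000 * np.arange(2048) / st.AUDIO_RATE)
        stim = st.calibrate_level(x, 94.0)
        assert stim.rms() == pytest.approx(0.04, rel=1e-12)
        assert stim.measured_level() == pytest.approx(94.0, abs=1e-9)

    def test_minus_20_db_is_tenth_rms(self):
        x = np.random.default_rng(0).standard_normal(1000)
        stim = st.calibrate_level(x, 94.0 - 20.0)
        assert stim.rms() == pytest.approx(0.004, rel=1e-12)

    def test_rms_008_measures_100_02_db(self):
        x = np.random.default_rng(0).standard_normal(4096)
        x *= 0.08 / np.sqrt(np.mean(x**2))
        level = st.SoundStimulus(x).measured_level()
        assert level == pytest.approx(94.0 + 20 * np.log10(2.0), abs=1e-9)
        assert level == pytest.approx(100.0206, abs=1e-3)

    def test_all_zero_waveform_rejected(self):
        with pytest.raises(CalibrationError):
            st.calibrate_level(np.zeros(100), 60.0)

    @settings(max_examples=30, deadline=None)
    @given(hst.floats(min_value=-20.0, max_value=110.0))
    def test_round_trip_within_hundredth_db(self, target):
        x = np.random.default_rng(7).standard_normal(500)
        stim = st.calibrate_level(x, target)
        assert stim.measured_level() == pytest.approx(target, abs=0.01)


class TestGrids:
    @pytest.mark.parametrize(
        "f_lo,f_hi,step,expected",
        [
            (256.0, 16384.0, 0.2, 31),  # frequency-response-area battery
            (294.0, 16384.0, 0.2, 31),  # CF battery (printed endpoint appended)
            (2.0, 512.0, 1.0, 9),  # AM modulation frequencies
            (500.0, 8000.0, 0.5, 9),  # AM centre frequencies
            (500.0, 11313.71, 0.5, 10),  # forward-masking probes
        ],
    )
    def test_octave_grid_counts(self, f_lo, f_hi, step, expected):
        assert st.octave_grid(f_lo, f_hi, step).size == expected

    def test_ripple_carrier_count_near_61(self):
        n = st.octave_grid(4700.0, 10800.0, 0.02).size
        assert abs(n - 61) <= 1

    @pytest.mark.parametrize(
        "lo,hi,step,expected",
        [(4.0, 103.0, 9.0, 12), (4.0, 85.0, 9.0, 10), (21.0, 96.0, 2.0, 38),
         (5.0, 75.0, 5.0, 15)],
    )
    def test_level_grid_counts(self, lo, hi, step, expected):
        assert st.level_grid(lo, hi, step).size == expected


class TestToneBattery:
    def test_envelope_flat_between_ramps(self):
        env = st.cosine_ramps(int(0.05 * st.AUDIO_RATE), 0.01, st.AUDIO_RATE)
        n_ramp = int(round(0.01 * st.AUDIO_RATE))
        assert np.all(env[n_ramp:-n_ramp] == 1.0)
        assert env[0] == 0.0

    def test_ramp_longer_than_half_duration_rejected(self):
        grid = st.StimulusGrid(np.array([1000.0]), np.array([60.0]),
                               duration=0.05, ramp=0.03)
        with pytest.raises(StimulusError):
            st.synth_tone_battery(grid, seed=0)

    def test_annotations_within_one_sample_of_envelope(self):
        grid = st.StimulusGrid(np.array([1000.0, 2000.0]), np.array([60.0]),
                               duration=0.02, ramp=0.002, gap=0.01)
        stim = st.synth_tone_battery(grid, seed=3)
        for ann in stim.annotations:
            i0 = int(round(ann.onset * stim.rate))
            i1 = int(round((ann.onset + ann.duration) * stim.rate))
            # silence strictly outside the annotated span, energy inside
            assert np.all(stim.samples[max(i0 - 5, 0) : max(i0 - 1, 0)] == 0.0)
            assert np.any(stim.samples[i0 : i0 + 50] != 0.0)
            assert np.all(stim.samples[i1 + 1 : i1 + 5] == 0.0)

    def test_each_cell_calibrated_to_its_level(self):
        grid = st.StimulusGrid(np.array([1000.0]), np.array([50.0, 70.0]),
                               duration=0.05, ramp=0.005, gap=0.01)
        stim = st.synth_tone_battery(grid, seed=1)
        for ann in stim.annotations:
            i0 = int(round(ann.onset * stim.rate))
            n = int(round(ann.duration * stim.rate))
            seg = stim.samples[i0 : i0 + n]
            level = st.DEFAULT_CONVENTION.level_of_rms(np.sqrt(np.mean(seg**2)))
            assert level == pytest.approx(ann.params["level"], abs=0.01)


class TestMovingRipple:
    def test_same_seed_bit_identical(self):
        a = st.synth_moving_ripple(4700.0, 10800.0, duration=0.3, seed=9)
        b = st.synth_moving_ripple(4700.0, 10800.0, duration=0.3, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_zero_depth_is_plain_carrier_sum(self):
        stim = st.synth_moving_ripple(1000.0, 2000.0, carrier_step=0.5,
                                      depth=0.0, duration=0.1, seed=1)
        carriers = st.octave_grid(1000.0, 2000.0, 0.5)
        rng = np.random.default_rng(1)
        phases = rng.uniform(0, 2 * np.pi, carriers.size)
        t = np.arange(stim.samples.size) / stim.rate
        expected = sum(np.sin(2 * np.pi * f * t + p) for f, p in zip(carriers, phases))
        assert np.allclose(stim.samples, expected)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(StimulusError):
            st.synth_moving_ripple(4000.0, 13000.0, rate=24000.0)


class TestHPRSequence:
    def test_paper_sequence_duration_and_burst_count(self):
        stim = st.synth_hpr_sequence(21.0, 96.0, 1.0, hpr_center=39.0, seed=4)
        assert len(stim.annotations) == 323
        assert stim.duration == pytest.approx(16.15, abs=1.0 / stim.rate)

    def test_level_histogram_matches_draw_rule(self):
        stim = st.synth_hpr_sequence(21.0, 96.0, 1.0, hpr_center=75.0, seed=2)
        levels = np.array([a.params["level"] for a in stim.annotations])
        vals, counts = np.unique(levels, return_counts=True)
        in_hpr = (vals >= 69.0) & (vals <= 81.0)
        assert np.all(counts[in_hpr] == 20)
        assert np.all(counts[~in_hpr] == 1)

    def test_uniform_limit_every_level_equal(self):
        stim = st.synth_hpr_sequence(21.0, 96.0, 2.0, hpr_center=39.0, hpr_range=12.0,
                                     hpr_draws=3, other_draws=3, seed=0)
        levels = [a.params["level"] for a in stim.annotations]
        _, counts = np.unique(levels, return_counts=True)
        assert np.all(counts == 3)

    def test_hpr_outside_range_rejected(self):
        with pytest.raises(StimulusError):
            st.synth_hpr_sequence(21.0, 96.0, 1.0, hpr_center=15.0)

    def test_no_inter_burst_silence(self):
        stim = st.synth_hpr_sequence(40.0, 50.0, 5.0, hpr_center=45.0, hpr_range=0.0,
                                     hpr_draws=2, other_draws=1, seed=1)
        # bursts are contiguous noise: no run of zeros anywhere
        assert np.count_nonzero(stim.samples == 0.0) == 0


class TestAMNoise:
    def test_zero_depth_equals_unmodulated(self):
        a = st.synth_am_noise(2000.0, mod_freq=8.0, depth=0.0, duration=0.2, seed=5)
        b = st.synth_am_noise(2000.0, mod_freq=None, duration=0.2, seed=5)
        assert np.allclose(a.samples, b.samples)

    def test_modulation_above_nyquist_rejected(self):
        with pytest.raises(StimulusError):
            st.synth_am_noise(2000.0, mod_freq=13000.0, rate=24000.0)

    def test_raised_sine_envelope_narrows_energy(self):
        plain = st.synth_am_noise(2000.0, mod_freq=8.0, envelope="sinusoid",
                                  duration=0.5, seed=3)
        raised = st.synth_am_noise(2000.0, mod_freq=8.0, envelope="raised-sine-32",
                                   duration=0.5, seed=3)
        # same calibrated level, but the raised-sine envelope is mostly near zero
        frac_quiet_plain = np.mean(np.abs(plain.samples) < 0.1 * plain.samples.std())
        frac_quiet_raised = np.mean(np.abs(raised.samples) < 0.1 * raised.samples.std())
        assert frac_quiet_raised > frac_quiet_plain


class TestForwardMasking:
    def test_unmasked_condition_contains_probe_only(self):
        stim = st.synth_forward_masking(2000.0, [60.0], masker_level=None)
        labels = [a.label for a in stim.annotations]
        assert labels == ["probe"]

    def test_probe_onset_identical_with_and_without_masker(self):
        masked = st.synth_forward_masking(2000.0, [60.0], masker_level=70.0)
        unmasked = st.synth_forward_masking(2000.0, [60.0], masker_level=None)
        p1 = [a for a in masked.annotations if a.label == "probe"][0]
        p2 = unmasked.annotations[0]
        assert p1.onset == p2.onset == pytest.approx(0.2 + 0.01, abs=1.0 / masked.rate)

    def test_one_trial_per_probe_level(self):
        levels = st.level_grid(5.0, 75.0, 5.0)
        stim = st.synth_forward_masking(1000.0, levels, masker_level=50.0)
        probes = [a for a in stim.annotations if a.label == "probe"]
        assert len(probes) == 15


class TestContextEnhancement:
    def test_without_conditioner_single_test_event(self):
        stim = st.synth_context_enhancement(1000.0, with_conditioner=False, seed=1)
        assert [a.label for a in stim.annotations] == ["test"]

    def test_notch_removes_components(self):
        comps = st.octave_grid(200.0, 16000.0, 0.1)
        width = 1.0
        removed = np.abs(np.log2(comps / 1000.0)) <= width / 2
        assert removed.sum() >= 9  # ~1 octave at 0.1-octave spacing

    def test_notch_center_outside_band_rejected(self):
        with pytest.raises(StimulusError):
            st.synth_context_enhancement(100.0)

    def test_notch_widths_grid(self):
        assert st.level_grid(0.0, 2.0, 0.5).size == 5


class TestSpeechProcessing:
    def test_speed_two_halves_duration(self):
        x = st.SoundStimulus(np.random.default_rng(0).standard_normal(24414))
        y = st.process_speech(x, speed_factor=2)
        assert y.samples.size == pytest.approx(x.samples.size / 2, abs=2)

    def test_identity_when_no_processing(self):
        x = st.SoundStimulus(np.random.default_rng(1).standard_normal(5000))
        y = st.process_speech(x, speed_factor=1)
        assert np.array_equal(y.samples, x.samples)

    def test_2khz_tone_gains_17_db(self):
        t = np.arange(24414) / st.AUDIO_RATE
        x = st.calibrate_level(np.sin(2 * np.pi * 2000 * t), 60.0)
        y = st.process_speech(x, multiband_gains=st.HEARING_AID_GAINS)
        gain = y.measured_level() - x.measured_level()
        assert gain == pytest.approx(17.0, abs=0.3)

    def test_unsupported_speed_rejected(self):
        with pytest.raises(StimulusError):
            st.process_speech(st.SoundStimulus(np.ones(100)), speed_factor=4)


class TestMixing:
    def test_snr_zero_equal_rms(self):
        rng = np.random.default_rng(2)
        speech = st.calibrate_level(rng.standard_normal(10000), 65.0)
        noise = st.SoundStimulus(rng.standard_normal(10000))
        mixed = st.mix_at_snr(speech, noise, 0.0)
        added = mixed.samples - speech.samples
        assert np.sqrt(np.mean(added**2)) == pytest.approx(speech.rms(), rel=1e-9)

    def test_snr_20_noise_is_tenth(self):
        rng = np.random.default_rng(3)
        speech = st.calibrate_level(rng.standard_normal(10000), 65.0)
        noise = st.SoundStimulus(rng.standard_normal(10000))
        mixed = st.mix_at_snr(speech, noise, 20.0)
        added = mixed.samples - speech.samples
        assert np.sqrt(np.mean(added**2)) == pytest.approx(0.1 * speech.rms(), rel=1e-9)

    def test_uncorrelated_mixture_rms_sqrt2(self):
        rng = np.random.default_rng(4)
        a = st.SoundStimulus(rng.standard_normal(200000))
        a = st.calibrate_level(a, st.DEFAULT_CONVENTION.level_of_rms(1.0))
        b = st.SoundStimulus(rng.standard_normal(200000))
        mixed = st.mix_at_snr(a, b, 0.0)
        assert mixed.rms() == pytest.approx(np.sqrt(2.0), rel=0.01)

    def test_silent_noise_rejected(self):
        speech = st.SoundStimulus(np.ones(100))
        with pytest.raises(StimulusError):
            st.mix_at_snr(speech, st.SoundStimulus(np.zeros(100)), 0.0)


def test_intensity_offsets_match_anchor_table():
    assert st.intensity_offset_db(500.0) == pytest.approx(15.0)
    assert st.intensity_offset_db(2000.0) == pytest.approx(0.0)
    assert st.intensity_offset_db(8000.0) == pytest.approx(20.0)
    # interpolated on the log-frequency axis between 500 Hz and 1 kHz
    assert 0.0 < st.intensity_offset_db(707.0) < 15.0
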