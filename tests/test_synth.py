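"""Synthetic PPG generator: determinism, ground truth, noise realism, I/O."""

import numpy as np
import pytest
from scipy.signal import periodogram

from ppgdistort.errors import ParameterError
from ppgdistort.synth import (
    BeatTemplate,
    NoiseSpec,
    generate_beat,
    generate_cohort,
    generate_record,
    load_record,
    save_record,
)


class TestBeatTemplate:
    def test_two_gaussian_mixture_shape(self):
        tpl = BeatTemplate()
        t = np.linspace(0.0, 0.8, 8000)
        y = tpl.evaluate(t)
        # systolic peak near its center, positive everywhere
        assert abs(t[np.argmax(y)] - tpl.systolic_center) < 0.01
        assert np.all(y >= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            BeatTemplate(systolic_width=0.0)
        with pytest.raises(ParameterError):
            BeatTemplate(diastolic_amplitude_ratio=-0.1)


class TestGenerateBeat:
    def test_truth_fiducials_ordered(self):
        beat, truth = generate_beat(BeatTemplate(), fs=320.0, period=0.8)
        assert len(beat) == int(round(0.8 * 320))
        assert truth.onset_time < truth.systolic_peak_time
        assert truth.has_diastolic_wave
        assert truth.systolic_peak_time < truth.notch_time < truth.diastolic_peak_time

    def test_default_template_truth_values(self):
        _, truth = generate_beat(BeatTemplate(), fs=320.0, period=0.8)
        # dense evaluation of the default mixture: RI well inside (0, 100),
        # onset-to-notch time a plausible ejection time
        assert 20.0 < truth.ri_percent < 60.0
        assert 0.2 < truth.delta_t < 0.35

    def test_overlapping_diastolic_wave_has_no_notch(self):
        tpl = BeatTemplate(
            diastolic_amplitude_ratio=0.05, diastolic_center=0.38, diastolic_width=0.16
        )
        _, truth = generate_beat(tpl, fs=320.0, period=0.8)
        assert not truth.has_diastolic_wave
        assert truth.ri_percent is None


class TestGenerateRecord:
    def test_deterministic_given_seed(self):
        a = generate_record(seed=123)
        b = generate_record(seed=123)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert len(a.truth) == len(b.truth)

    def test_different_seeds_differ(self):
        a = generate_record(seed=123)
        b = generate_record(seed=124)
        assert not np.array_equal(a.samples, b.samples)

    def test_raw_polarity_and_dc_offset(self):
        rec = generate_record(seed=5, dc_offset=10.0)
        assert rec.polarity == "raw-inverted"
        # beats point downward from a positive baseline
        assert 8.0 < np.mean(rec.samples) < 10.5
        assert np.max(rec.samples) <= 10.5

    def test_truth_beat_count_and_heart_rate(self):
        rec = generate_record(seed=5, duration=40.0, hr_mean=75.0, hr_sd=2.0)
        # ~50 beats in 40 s at 75 bpm; only complete beats carry truth
        assert 40 <= len(rec.truth) <= 55
        assert rec.true_heart_rate() == pytest.approx(75.0, abs=3 * 2.0)

    def test_mains_harmonic_level(self):
        rec = generate_record(seed=5)
        upright = -(rec.samples - np.mean(rec.samples))
        f, pxx = periodogram(upright, fs=rec.fs)
        cardiac = pxx[(f > 0.5) & (f < 5.0)].max()
        mains = pxx[np.argmin(np.abs(f - 50.0))]
        level_db = 10 * np.log10(mains / cardiac)
        # nominal -60 dB relative to the systolic spectral peak
        assert -75.0 < level_db < -45.0

    def test_silent_noise_is_clean(self):
        rec = generate_record(seed=5, noise=NoiseSpec.silent())
        # spectral content above 40 Hz should be essentially absent
        upright = -(rec.samples - np.mean(rec.samples))
        f, pxx = periodogram(upright, fs=rec.fs)
        # superposition of smooth Gaussians leaves only numerical leakage
        assert pxx[f > 40.0].max() < 1e-6 * pxx.max()

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            generate_record(seed=1, hr_mean=500.0)
        with pytest.raises(ParameterError):
            generate_record(seed=1, duration=0.0)
        with pytest.raises(ParameterError):
            generate_record(seed=1, fs=50.0)  # 50 Hz mains at Nyquist


class TestGenerateCohort:
    def test_class_split_and_truth(self, cohort20):
        assert len(cohort20) == 20
        class1 = [r for r in cohort20 if r.morphology_class == 1]
        class2 = [r for r in cohort20 if r.morphology_class == 2]
        assert len(class1) == 10 and len(class2) == 10
        # pronounced diastolic wave: every truth beat has a notch
        for rec in class1:
            assert all(b.has_diastolic_wave for b in rec.truth)
        # weak/absent wave: overlapping mixture has no interior minimum
        for rec in class2:
            assert not any(b.has_diastolic_wave for b in rec.truth)

    def test_deterministic(self):
        a = generate_cohort(n_records=3, seed=9)
        b = generate_cohort(n_records=3, seed=9)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_between_record_heart_rate_spread(self, cohort20):
        hrs = [r.true_heart_rate() for r in cohort20]
        assert np.std(hrs) > 2.0  # between-record variation present
        assert all(45.0 < hr < 115.0 for hr in hrs)

    def test_validation(self):
        with pytest.raises(ParameterError):
            generate_cohort(n_records=0, seed=1)
        with pytest.raises(ParameterError):
            generate_cohort(n_records=2, class1_fraction=1.5, seed=1)


class TestRecordIO:
    def test_roundtrip(self, tmp_path):
        rec = generate_record(seed=77, record_id="roundtrip", duration=5.0)
        path = save_record(rec, tmp_path)
        back = load_record(path)
        np.testing.assert_allclose(back.samples, rec.samples, rtol=0, atol=1e-12)
        assert back.fs == rec.fs
        assert back.polarity == rec.polarity
        assert back.record_id == rec.record_id
        assert len(back.truth) == len(rec.truth)
        assert back.truth[0].onset_time == pytest.approx(rec.truth[0].onset_time)
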