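"""Morphology indices: beat detection, fiducials, S_SQI, RI, ETc, HR."""

import numpy as np
import pytest

from ppgdistort.errors import NoBeatError, ParameterError, UndefinedIndexError
from ppgdistort.morphology import (
    BeatFiducials,
    analyze_signal,
    classify_dawber,
    detect_beats,
    detect_fiducials,
    ejection_time_compensated,
    heart_rate,
    reflection_index,
    skewness_sqi,
)
from ppgdistort.preprocess import invert_and_remove_dc


def _fid(a_s=1.0, prominence=None, a_d=None, notch_t=None, dia_t=None):
    return BeatFiducials(
        onset_index=0,
        onset_time=0.0,
        onset_amplitude=0.0,
        systolic_peak_index=48,
        systolic_peak_time=0.15,
        systolic_amplitude=a_s,
        notch_time=notch_t,
        notch_prominence=prominence,
        diastolic_peak_time=dia_t,
        diastolic_amplitude=a_d,
    )


class TestSkewnessSQI:
    def test_matches_brute_force_moment(self, rng):
        for n in (3, 10, 37, 100, 1000):
            x = rng.normal(size=n) + rng.exponential(size=n)
            mu = sum(x) / n
            sigma = (sum((v - mu) ** 2 for v in x) / n) ** 0.5
            brute = sum(((v - mu) / sigma) ** 3 for v in x) / n
            assert skewness_sqi(x) == pytest.approx(brute, abs=1e-12)

    def test_small_example(self):
        # [0, 0, 1]: mu = 1/3, population sigma = sqrt(2)/3,
        # skewness = 1/sqrt(2)
        assert skewness_sqi(np.array([0.0, 0.0, 1.0])) == pytest.approx(
            1.0 / np.sqrt(2.0), abs=1e-12
        )

    def test_symmetric_signal_is_zero(self):
        t = np.linspace(0, 1, 1000, endpoint=False)
        assert skewness_sqi(np.sin(2 * np.pi * 3 * t)) == pytest.approx(0.0, abs=1e-10)

    def test_errors(self):
        with pytest.raises(ParameterError):
            skewness_sqi(np.array([1.0, 2.0]))
        with pytest.raises(UndefinedIndexError):
            skewness_sqi(np.full(10, 2.0))


class TestHeartRate:
    def test_paper_interval_example(self):
        # 0.690-s beat-to-beat intervals: 87 bpm, fundamental 1.45 Hz
        peaks = np.arange(10) * 0.690
        hr = heart_rate(peaks)
        assert round(hr) == 87
        assert round(hr / 60.0, 2) == 1.45

    def test_one_second_intervals(self):
        assert heart_rate(np.arange(5) * 1.0) == pytest.approx(60.0)

    def test_median_robust_to_one_missed_beat(self):
        peaks = np.concatenate([np.arange(10) * 0.8, [0.8 * 11]])  # one gap
        assert heart_rate(peaks) == pytest.approx(75.0)

    def test_needs_two_beats(self):
        with pytest.raises(UndefinedIndexError):
            heart_rate(np.array([1.0]))


class TestClassification:
    def test_prominence_thresholds(self):
        pronounced = _fid(prominence=0.15, a_d=0.4, notch_t=0.30, dia_t=0.40)
        weak = _fid(prominence=0.05, a_d=0.2, notch_t=0.30, dia_t=0.40)
        absent = _fid()
        assert classify_dawber(pronounced) == (1, True)
        assert classify_dawber(weak) == (2, True)
        assert classify_dawber(absent) == (3, False)

    def test_eligibility_monotone(self):
        # removing the diastolic wave never makes a beat eligible
        full = _fid(prominence=0.15, a_d=0.4, notch_t=0.30, dia_t=0.40)
        assert classify_dawber(full)[1]
        for strip in ("notch_prominence", "diastolic_amplitude"):
            partial = _fid(prominence=0.15, a_d=0.4, notch_t=0.30, dia_t=0.40)
            setattr(partial, strip, None)
            assert not classify_dawber(partial)[1]


class TestDetection:
    def test_beats_match_truth_on_clean_record(self, clean_record):
        ac = invert_and_remove_dc(clean_record)
        peaks, onsets = detect_beats(ac.samples, ac.fs)
        assert peaks.shape == onsets.shape
        assert np.all(onsets < peaks)
        truth_times = np.array([b.systolic_peak_time for b in clean_record.truth])
        # every truth peak inside the record has a detection within 15 ms
        for t in truth_times:
            assert np.min(np.abs(peaks / ac.fs - t)) < 0.015

    def test_detect_fiducials_on_synthetic_beat(self, clean_record):
        ac = invert_and_remove_dc(clean_record)
        peaks, onsets = detect_beats(ac.samples, ac.fs)
        fid = detect_fiducials(ac.samples, ac.fs, onsets[2], peaks[2], onsets[3])
        assert fid.eligible and fid.dawber_class == 1
        # match the truth entry by systolic-peak time (truth omits the
        # first and last beats, so positional indices need not line up)
        t_peak = peaks[2] / ac.fs
        truth = min(clean_record.truth,
                    key=lambda b: abs(b.systolic_peak_time - t_peak))
        assert fid.notch_time == pytest.approx(truth.notch_time, abs=0.02)

    def test_malformed_segment_rejected(self):
        with pytest.raises(ParameterError):
            detect_fiducials(np.zeros(100), 320.0, 50, 40, 90)

    def test_too_short_signal(self):
        with pytest.raises(ParameterError):
            detect_beats(np.zeros(100), 320.0)

    def test_flat_signal_has_no_beats(self):
        with pytest.raises(NoBeatError):
            detect_beats(np.zeros(2000), 320.0)


class TestRecordIndices:
    def test_reflection_index_bounds(self, clean_record):
        ac = invert_and_remove_dc(clean_record)
        indices, fids, _ = analyze_signal(ac.samples, ac.fs)
        assert indices.eligible
        assert 0.0 <= indices.ri_percent <= 100.0
        assert indices.etc_ms > 0
        assert indices.n_beats_used <= indices.n_beats_total

    def test_no_eligible_beats_gives_undefined(self):
        with pytest.raises(UndefinedIndexError):
            reflection_index([_fid()])
        with pytest.raises(UndefinedIndexError):
            ejection_time_compensated([_fid()], 60.0)
        with pytest.raises(ParameterError):
            ejection_time_compensated([_fid(prominence=0.2, a_d=0.4,
                                            notch_t=0.3, dia_t=0.4)], 0.0)

    def test_class2_record_has_no_ri(self, cohort20):
        rec = next(r for r in cohort20 if r.morphology_class == 2)
        ac = invert_and_remove_dc(rec)
        indices, _, _ = analyze_signal(ac.samples, ac.fs)
        assert not indices.eligible
        assert indices.ri_percent is None and indices.etc_ms is None
        assert np.isfinite(indices.s_sqi)  # skewness always defined
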