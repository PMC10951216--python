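"""Synthetic fingertip-PPG generator with exact ground-truth morphology.

Each beat is modelled as the sum of two Gaussian waves: a direct (systolic)
ejection wave and a reflected (diastolic) wave.  The trough between them is
the dicrotic notch, which marks aortic valve closure.  This is the simplest
model that exposes the quantities morphological pulse-wave analysis cares
about — the systolic amplitude A_s, the diastolic amplitude A_d (so the true
reflection index is 100*A_d/A_s), and the onset-to-notch time used by the
ejection-time index — with every fiducial computable to machine precision
from the analytic mixture rather than from the detector under test.

Records emulate 40-s fingertip recordings sampled at 320 Hz with raw
(inverted) polarity, a positive DC offset, slow baseline drift, broadband
sensor noise near -90 dB relative to the systolic spectral peak, and mains
interference lines at 30 and 50 Hz.  A cohort generator produces the two
morphology subgroups seen in practice: pronounced diastolic wave
(A_d/A_s >= 0.3) and barely visible or absent diastolic wave (<= 0.1, with
strongly overlapping waves so that no dicrotic notch exists).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "BeatTemplate",
    "NoiseSpec",
    "BeatTruth",
    "PPGRecord",
    "generate_beat",
    "generate_record",
    "generate_cohort",
    "save_record",
    "load_record",
]

#: oversampling factor for the dense grid on which truth fiducials are found
_DENSE = 10


@dataclass(frozen=True)
class BeatTemplate:
    """Two-Gaussian beat shape: systolic wave + optional diastolic wave.

    Times are seconds from beat onset; amplitudes are relative units with the
    systolic amplitude fixed to 1.0 before any record-level scaling.
    ``diastolic_amplitude_ratio`` is the true A_d/A_s of the mixture's
    component waves (the realized peak ratio differs slightly because the
    Gaussians overlap; truth fiducials are measured on the realized mixture).
    """

    systolic_center: float = 0.15
    systolic_width: float = 0.05
    diastolic_amplitude_ratio: float = 0.4
    diastolic_center: float = 0.45
    diastolic_width: float = 0.09
    systolic_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.systolic_width <= 0 or self.diastolic_width <= 0:
            raise ParameterError("Gaussian widths must be positive")
        if self.systolic_amplitude <= 0:
            raise ParameterError("systolic amplitude must be positive")
        if not 0.0 <= self.diastolic_amplitude_ratio <= 1.0:
            raise ParameterError("diastolic_amplitude_ratio must be in [0, 1]")
        if self.diastolic_center <= self.systolic_center:
            raise ParameterError("diastolic wave must follow the systolic wave")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the analytic two-Gaussian mixture at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        a = self.systolic_amplitude
        y = a * np.exp(-0.5 * ((t - self.systolic_center) / self.systolic_width) ** 2)
        if self.diastolic_amplitude_ratio > 0:
            y = y + a * self.diastolic_amplitude_ratio * np.exp(
                -0.5 * ((t - self.diastolic_center) / self.diastolic_width) ** 2
            )
        return y


@dataclass(frozen=True)
class NoiseSpec:
    """Additive-noise model for a raw PPG record.

    ``broadband_level_db`` sets the white-noise floor of the record's power
    spectral density relative to the systolic spectral peak (the tallest
    cardiac-harmonic line of the clean signal's periodogram).  Discrete
    interference harmonics (mains pickup) are placed at ``harmonic_freqs``
    with spectral lines ``harmonic_level_db`` below the same peak.  A slow
    sinusoidal baseline drift emulates respiration/vasomotion wander.
    """

    broadband_level_db: float = -90.0
    harmonic_freqs: tuple[float, ...] = (30.0, 50.0)
    harmonic_level_db: float = -60.0
    drift_freq: float = 0.25
    drift_amplitude: float = 0.05

    def __post_init__(self) -> None:
        if self.broadband_level_db >= 0 and np.isfinite(self.broadband_level_db):
            raise ParameterError("broadband_level_db must be negative (dB below peak)")
        if any(f <= 0 for f in self.harmonic_freqs):
            raise ParameterError("harmonic frequencies must be positive")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        """Noise disabled entirely (noise-free, drift-free records)."""
        return cls(
            broadband_level_db=-np.inf,
            harmonic_freqs=(),
            drift_amplitude=0.0,
        )


@dataclass
class BeatTruth:
    """Ground-truth fiducials of one generated beat (absolute times, s).

    Notch/diastolic fields are ``None`` when the analytic mixture has no
    interior minimum after the systolic peak (no dicrotic notch).  Amplitudes
    are measured above the onset amplitude, matching the detector convention.
    """

    onset_time: float
    systolic_peak_time: float
    systolic_amplitude: float
    notch_time: Optional[float] = None
    diastolic_peak_time: Optional[float] = None
    diastolic_amplitude: Optional[float] = None

    @property
    def has_diastolic_wave(self) -> bool:
        return self.notch_time is not None and self.diastolic_peak_time is not None

    @property
    def ri_percent(self) -> Optional[float]:
        """True reflection index 100*A_d/A_s, if the diastolic wave exists."""
        if self.diastolic_amplitude is None:
            return None
        return 100.0 * self.diastolic_amplitude / self.systolic_amplitude

    @property
    def delta_t(self) -> Optional[float]:
        """True onset-to-notch time in seconds, if the notch exists."""
        if self.notch_time is None:
            return None
        return self.notch_time - self.onset_time


@dataclass
class PPGRecord:
    """A uniformly sampled PPG signal plus optional ground truth.

    ``polarity`` is ``"raw-inverted"`` for generator output (beats point
    downward, positive DC offset, as a transmissive/backscatter sensor
    records them) or ``"ac-positive"`` after pre-processing.
    """

    samples: np.ndarray
    fs: float = 320.0
    polarity: str = "raw-inverted"
    record_id: str = "rec"
    morphology_class: Optional[int] = None  # 1 = pronounced diastolic wave, 2 = weak/absent
    truth: Optional[list[BeatTruth]] = None
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def true_heart_rate(self) -> Optional[float]:
        """Median instantaneous heart rate (bpm) from truth peak times."""
        if not self.truth or len(self.truth) < 2:
            return None
        peaks = np.array([b.systolic_peak_time for b in self.truth])
        return 60.0 / float(np.median(np.diff(peaks)))


def _dense_fiducials(template: BeatTemplate, period: float) -> BeatTruth:
    """Locate truth fiducials by dense evaluation of the analytic mixture.

    A dicrotic notch exists iff the mixture has an interior local minimum
    after the systolic peak; with heavily overlapped waves (class-2 beats)
    the reflected wave is only a shoulder and the notch fields stay None.
    """
    n = max(int(round(period * _DENSE * 320)), 64)
    t = np.linspace(0.0, period, n, endpoint=False)
    y = template.evaluate(t)

    i_sys = int(np.argmax(y))
    # threshold-departure foot: last pre-peak point within 2% of the beat
    # amplitude above the pre-peak minimum (the detector's convention)
    pre = y[: i_sys + 1]
    m = float(pre.min())
    tol = 0.02 * (float(y[i_sys]) - m)
    i_onset = int(np.nonzero(pre <= m + tol)[0][-1])
    onset_t = float(t[i_onset])
    onset_amp = float(y[i_onset])
    a_s = float(y[i_sys]) - onset_amp

    truth = BeatTruth(
        onset_time=onset_t,
        systolic_peak_time=float(t[i_sys]),
        systolic_amplitude=a_s,
    )
    if template.diastolic_amplitude_ratio <= 0:
        return truth

    # interior local minimum after the systolic peak, then the next maximum
    tail = y[i_sys:]
    d = np.diff(tail)
    rising = np.nonzero((d[:-1] <= 0) & (d[1:] > 0))[0]
    if rising.size == 0:
        return truth
    i_notch = i_sys + int(rising[0]) + 1
    after = y[i_notch:]
    d2 = np.diff(after)
    falling = np.nonzero((d2[:-1] >= 0) & (d2[1:] < 0))[0]
    if falling.size == 0:
        return truth
    i_dia = i_notch + int(falling[0]) + 1
    a_d = float(y[i_dia]) - onset_amp
    # a usable dicrotic notch must separate the waves by at least 1% of A_s
    # (same presence convention as the fiducial detector)
    if (y[i_dia] - y[i_notch]) < 0.01 * a_s or a_d <= 0:
        return truth
    truth.notch_time = float(t[i_notch])
    truth.diastolic_peak_time = float(t[i_dia])
    truth.diastolic_amplitude = a_d
    return truth


def generate_beat(
    template: BeatTemplate, fs: float, period: float
) -> tuple[np.ndarray, BeatTruth]:
    """Sample one beat at ``fs`` and return it with its analytic truth.

    Truth fiducials come from a dense (10x oversampled) evaluation of the
    two-Gaussian mixture, independent of any peak detector.
    """
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if period <= template.systolic_center:
        raise ParameterError("period must exceed the systolic center time")
    n = int(round(period * fs))
    if n < 2:
        raise ParameterError("period too short for the sampling rate")
    t = np.arange(n) / fs
    return template.evaluate(t), _dense_fiducials(template, period)


def _noise_sigma_from_db(clean_ac: np.ndarray, fs: float, level_db: float) -> float:
    """White-noise sigma whose one-sided PSD sits ``level_db`` below the
    tallest spectral line of the clean signal's periodogram."""
    from scipy.signal import periodogram

    f, pxx = periodogram(clean_ac - clean_ac.mean(), fs=fs)
    p_peak = float(pxx.max())
    target_density = 10.0 ** (level_db / 10.0) * p_peak
    # one-sided white-noise density is 2*sigma^2/fs
    return float(np.sqrt(target_density * fs / 2.0))


def _harmonic_amplitude_from_db(
    clean_ac: np.ndarray, fs: float, level_db: float
) -> float:
    """Sinusoid amplitude whose periodogram line sits ``level_db`` below the
    clean signal's tallest line (line density ~ a^2 * N / (2 fs))."""
    from scipy.signal import periodogram

    f, pxx = periodogram(clean_ac - clean_ac.mean(), fs=fs)
    p_peak = float(pxx.max())
    target = 10.0 ** (level_db / 10.0) * p_peak
    n = len(clean_ac)
    return float(np.sqrt(2.0 * fs * target / n))


def generate_record(
    *,
    duration: float = 40.0,
    hr_mean: float = 75.0,
    hr_sd: float = 2.0,
    template: BeatTemplate | None = None,
    noise: NoiseSpec | None = None,
    fs: float = 320.0,
    dc_offset: float = 10.0,
    seed: int,
    record_id: str = "rec",
    morphology_class: Optional[int] = None,
) -> PPGRecord:
    """Generate one raw-polarity PPG record with ground-truth annotations.

    Beat start times follow per-beat period jitter drawn from a normal
    heart-rate distribution (``hr_mean`` +/- ``hr_sd`` bpm, clipped to
    30-180 bpm); the clean signal is the superposition of every beat's
    full-support mixture, so it is continuous across beat boundaries.  It
    is then inverted, offset by a positive DC level, and polluted per
    ``noise``.  The same seed always reproduces the identical sample array.
    """
    if not 30.0 <= hr_mean <= 180.0:
        raise ParameterError("hr_mean must lie in [30, 180] bpm")
    if hr_sd < 0:
        raise ParameterError("hr_sd must be non-negative")
    if fs <= 0 or duration <= 0:
        raise ParameterError("fs and duration must be positive")
    template = template or BeatTemplate()
    noise = noise or NoiseSpec()
    for f_h in noise.harmonic_freqs:
        if f_h >= fs / 2:
            raise ParameterError(f"harmonic {f_h} Hz at or above Nyquist ({fs / 2} Hz)")
    if duration < 60.0 / hr_mean:
        raise ParameterError("duration too short for a single beat")

    rng = np.random.default_rng(seed)
    n_total = int(round(fs * duration))
    t = np.arange(n_total) / fs

    starts: list[float] = []
    periods: list[float] = []
    t0 = 0.0
    while t0 < duration:
        hr = float(np.clip(rng.normal(hr_mean, hr_sd), 30.0, 180.0)) if hr_sd > 0 else hr_mean
        starts.append(t0)
        periods.append(60.0 / hr)
        t0 += periods[-1]

    # true superposition: every beat's mixture has full support, so the
    # assembled signal is continuous everywhere (no boundary steps)
    clean = np.zeros(n_total)
    for start in starts:
        clean += template.evaluate(t - start)

    truths = _record_truth(template, starts, periods, fs, duration)
    contaminated = clean.copy()
    if noise.drift_amplitude > 0:
        contaminated += noise.drift_amplitude * np.sin(
            2.0 * np.pi * noise.drift_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if np.isfinite(noise.broadband_level_db):
        sigma = _noise_sigma_from_db(clean, fs, noise.broadband_level_db)
        contaminated += rng.normal(0.0, sigma, n_total)
        amp = _harmonic_amplitude_from_db(clean, fs, noise.harmonic_level_db)
        for f_h in noise.harmonic_freqs:
            contaminated += amp * np.sin(2.0 * np.pi * f_h * t + rng.uniform(0, 2 * np.pi))

    raw = dc_offset - contaminated  # raw-inverted polarity: beats point down
    return PPGRecord(
        samples=raw,
        fs=fs,
        polarity="raw-inverted",
        record_id=record_id,
        morphology_class=morphology_class,
        truth=truths,
        meta={
            "seed": seed,
            "hr_mean": hr_mean,
            "hr_sd": hr_sd,
            "dc_offset": dc_offset,
            "template": asdict(template),
            "noise": {**asdict(noise), "harmonic_freqs": list(noise.harmonic_freqs)},
        },
    )


def _record_truth(
    template: BeatTemplate,
    starts: list[float],
    periods: list[float],
    fs: float,
    duration: float,
) -> list[BeatTruth]:
    """Ground-truth fiducials of every fully visible beat of a record.

    The analytic superposition is evaluated on a dense grid (``_DENSE`` x
    the sampling rate) and the fiducials are located by the same
    operational rules the detector uses — threshold-departure foot in the
    last 35% of the inter-peak interval, most prominent interior minimum
    for the notch, 1%-of-A_s presence rule — so that truth is what an
    ideal continuous-time measurement of the same definitions would
    return.  The first and last beats lack a neighbouring beat on one side
    and carry no truth.
    """
    from scipy.signal import find_peaks

    from .morphology import (
        FOOT_TOLERANCE_FRACTION,
        NOTCH_PRESENCE_FRACTION,
        NOTCH_SEARCH_FRACTION,
        ONSET_SEARCH_FRACTION,
    )

    dense_fs = _DENSE * fs
    nd = int(round(duration * dense_fs))
    td = np.arange(nd) / dense_fs
    yd = np.zeros(nd)
    for start in starts:
        yd += template.evaluate(td - start)

    n_beats = len(starts)
    peak_idx: list[Optional[int]] = []
    for start in starts:
        center = start + template.systolic_center
        lo = max(int((center - 0.1) * dense_fs), 0)
        hi = min(int((center + 0.1) * dense_fs) + 1, nd)
        peak_idx.append(lo + int(np.argmax(yd[lo:hi])) if hi - lo >= 3 else None)

    onset_idx: list[Optional[int]] = [None] * n_beats
    for k in range(1, n_beats):
        p, prev = peak_idx[k], peak_idx[k - 1]
        if p is None or prev is None or p <= prev:
            continue
        lo = max(prev, p - int(round(ONSET_SEARCH_FRACTION * (p - prev))))
        window = yd[lo:p]
        if window.size == 0:
            continue
        m = float(window.min())
        tol = FOOT_TOLERANCE_FRACTION * (float(yd[p]) - m)
        below = np.nonzero(window <= m + tol)[0]
        if below.size:
            onset_idx[k] = lo + int(below[-1])

    truths: list[BeatTruth] = []
    for k in range(1, n_beats - 1):
        i_on, i_sys, i_next = onset_idx[k], peak_idx[k], onset_idx[k + 1]
        if i_on is None or i_sys is None or i_next is None:
            continue
        if starts[k] + periods[k] > duration:
            continue
        onset_amp = float(yd[i_on])
        a_s = float(yd[i_sys]) - onset_amp
        if a_s <= 0:
            continue
        truth = BeatTruth(
            onset_time=i_on / dense_fs,
            systolic_peak_time=i_sys / dense_fs,
            systolic_amplitude=a_s,
        )
        period_d = i_next - i_on
        search_end = min(i_on + int(round(NOTCH_SEARCH_FRACTION * period_d)), i_next)
        seg = yd[i_sys:search_end]
        if seg.size >= 3:
            minima, props = find_peaks(-seg, prominence=0.0)
            if minima.size:
                i_notch = i_sys + int(minima[np.argmax(props["prominences"])])
                after = yd[i_notch:i_next]
                maxima, _ = find_peaks(after)
                if maxima.size:
                    i_dia = i_notch + int(maxima[0])
                    a_d = float(yd[i_dia]) - onset_amp
                    rise = float(yd[i_dia] - yd[i_notch])
                    if rise >= NOTCH_PRESENCE_FRACTION * a_s and a_d > 0:
                        truth.notch_time = i_notch / dense_fs
                        truth.diastolic_peak_time = i_dia / dense_fs
                        truth.diastolic_amplitude = min(a_d, a_s)
        truths.append(truth)
    return truths


# class-2 beats use a wide, heavily overlapped reflected wave so that the
# mixture has no interior minimum — a "barely noticeable or absent" wave
_CLASS2_TEMPLATE_KW = dict(diastolic_center=0.38, diastolic_width=0.16)


def _jittered_template(rng: np.random.Generator, morphology_class: int) -> BeatTemplate:
    if morphology_class == 1:
        return BeatTemplate(
            systolic_center=rng.uniform(0.13, 0.17),
            systolic_width=rng.uniform(0.045, 0.055),
            diastolic_amplitude_ratio=rng.uniform(0.3, 0.55),
            diastolic_center=rng.uniform(0.42, 0.48),
            diastolic_width=rng.uniform(0.08, 0.10),
        )
    return BeatTemplate(
        systolic_center=rng.uniform(0.13, 0.17),
        systolic_width=rng.uniform(0.045, 0.055),
        diastolic_amplitude_ratio=rng.uniform(0.02, 0.10),
        **_CLASS2_TEMPLATE_KW,
    )


def generate_cohort(
    n_records: int = 20,
    class1_fraction: float = 0.5,
    *,
    seed: int,
    duration: float = 40.0,
    fs: float = 320.0,
    hr_mean: float = 75.0,
    hr_sd: float = 2.0,
    hr_between_sd: float = 8.0,
    noise: NoiseSpec | None = None,
) -> list[PPGRecord]:
    """Generate a cohort split into pronounced- and weak-diastolic subgroups.

    The first ``round(n_records * class1_fraction)`` records are class 1
    (diastolic amplitude ratio >= 0.3), the rest class 2 (<= 0.1 with
    overlapping waves).  Per-record templates and mean heart rates are
    jittered with the seeded generator; identical arguments reproduce a
    byte-identical cohort.
    """
    if n_records <= 0:
        raise ParameterError("n_records must be positive")
    if not 0.0 <= class1_fraction <= 1.0:
        raise ParameterError("class1_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_class1 = int(round(n_records * class1_fraction))
    records = []
    for i in range(n_records):
        cls = 1 if i < n_class1 else 2
        template = _jittered_template(rng, cls)
        rec_hr = float(np.clip(rng.normal(hr_mean, hr_between_sd), 50.0, 110.0))
        rec_seed = int(rng.integers(0, 2**31 - 1))
        records.append(
            generate_record(
                duration=duration,
                hr_mean=rec_hr,
                hr_sd=hr_sd,
                template=template,
                noise=noise,
                fs=fs,
                seed=rec_seed,
                record_id=f"rec{i:02d}",
                morphology_class=cls,
            )
        )
    return records


def save_record(record: PPGRecord, directory: str | Path) -> Path:
    """Write a record as ``<id>.csv`` (time_s, value) plus a JSON sidecar
    with fs, polarity, seed/meta and truth annotations.  Returns the CSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{record.record_id}.csv"
    pd.DataFrame({"time_s": record.time, "value": record.samples}).to_csv(
        csv_path, index=False
    )
    sidecar = {
        "record_id": record.record_id,
        "fs": record.fs,
        "polarity": record.polarity,
        "morphology_class": record.morphology_class,
        "meta": record.meta,
        "truth": [asdict(b) for b in record.truth] if record.truth else None,
    }
    (directory / f"{record.record_id}.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def load_record(csv_path: str | Path) -> PPGRecord:
    """Read a record written by :func:`save_record` (sidecar optional)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        truth = (
            [BeatTruth(**b) for b in side["truth"]] if side.get("truth") else None
        )
        return PPGRecord(
            samples=df["value"].to_numpy(),
            fs=float(side["fs"]),
            polarity=side["polarity"],
            record_id=side["record_id"],
            morphology_class=side.get("morphology_class"),
            truth=truth,
            meta=side.get("meta", {}),
        )
    dt = float(np.median(np.diff(df["time_s"].to_numpy())))
    return PPGRecord(
        samples=df["value"].to_numpy(), fs=1.0 / dt, record_id=csv_path.stem
    )
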