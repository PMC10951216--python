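"""Beat segmentation, fiducial points and morphological pulse-wave indices.

Per beat the detector locates the onset (pulse foot: the local minimum
preceding the systolic upstroke), the systolic peak, the dicrotic notch
(local minimum between the systolic and diastolic waves, marking aortic
valve closure) and the diastolic peak.  Beats are graded on the
Dawber-style four-class scale by the prominence of the diastolic wave:
classes 1-2 have a usable notch and are eligible for the reflection index
and the ejection-time index; classes 3-4 are not.

Record-level indices:

* ``S_SQI`` — skewness signal quality index, the third standardized moment
  of the sample distribution (population-sigma convention); higher skewness
  reflects more detailed pulse morphology.
* ``RI``   — reflection index, 100 * A_d / A_s averaged over eligible beats
  (peripheral arteriolar-tone marker).
* ``ETc``  — ejection time compensated, dT / sqrt(HR/60) in ms, where dT is
  onset-to-notch time (surrogate for left-ventricular ejection time).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .errors import NoBeatError, ParameterError, UndefinedIndexError

__all__ = [
    "BeatFiducials",
    "IndexSet",
    "detect_beats",
    "detect_fiducials",
    "classify_dawber",
    "skewness_sqi",
    "reflection_index",
    "ejection_time_compensated",
    "heart_rate",
    "analyze_signal",
]

#: minimum separation of systolic peaks (s); 0.4 s caps HR at 150 bpm and,
#: crucially, exceeds the largest systolic-to-diastolic spacing a beat can
#: show (~0.35 s), so a pronounced diastolic wave can never be double-counted
#: as a beat — find_peaks keeps the taller (systolic) peak within the window
MIN_PEAK_SEPARATION_S = 0.4
#: adaptive prominence threshold as a fraction of the local amplitude range
PROMINENCE_FRACTION = 0.4
#: a diastolic wave exists if it rises above the notch by >= 1% of A_s ...
NOTCH_PRESENCE_FRACTION = 0.01
#: ... and is "pronounced" (Dawber class 1) above 10% of A_s
CLASS1_PROMINENCE_FRACTION = 0.10
#: the notch is searched between the systolic peak and this fraction of the
#: beat period
NOTCH_SEARCH_FRACTION = 0.8
#: the onset (pulse foot) is searched within this trailing fraction of
#: the inter-peak interval — late diastole only, so that causal high-pass
#: sag between beats cannot drag the foot into the previous beat
ONSET_SEARCH_FRACTION = 0.35
#: the foot is the last pre-peak sample within this fraction of the beat
#: amplitude above the window minimum (threshold-departure foot; robust to
#: shallow undershoot dips and flat diastolic valleys)
FOOT_TOLERANCE_FRACTION = 0.02
#: record-level RI/ETc are reported only when at least this fraction of the
#: detected beats carries a usable diastolic wave; a handful of eligible
#: beats in an otherwise notch-free record is detection noise (drift or
#: sensor wiggles masquerading as a diastolic wave), not morphology
MIN_ELIGIBLE_FRACTION = 0.25


@dataclass
class BeatFiducials:
    """Fiducial points of one beat (times in s, amplitudes above onset)."""

    onset_index: int
    onset_time: float
    onset_amplitude: float
    systolic_peak_index: int
    systolic_peak_time: float
    systolic_amplitude: float  # A_s, above onset amplitude
    notch_time: Optional[float] = None
    notch_prominence: Optional[float] = None  # diastolic rise above the notch
    diastolic_peak_time: Optional[float] = None
    diastolic_amplitude: Optional[float] = None  # A_d, above onset amplitude
    dawber_class: int = 4
    eligible: bool = False

    @property
    def delta_t(self) -> Optional[float]:
        """Onset-to-notch time (s), the dT of the ejection-time index."""
        if self.notch_time is None:
            return None
        return self.notch_time - self.onset_time


@dataclass
class IndexSet:
    """Record-level morphology indices."""

    s_sqi: float
    hr_bpm: float
    ri_percent: Optional[float]
    etc_ms: Optional[float]
    n_beats_total: int
    n_beats_used: int

    @property
    def eligible(self) -> bool:
        """True when RI/ETc could be computed (a usable diastolic wave)."""
        return self.ri_percent is not None


def detect_beats(
    x: np.ndarray, fs: float, range_window_s: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Locate systolic peaks and the beat onsets preceding them.

    Peaks are local maxima separated by at least 0.33 s whose prominence
    exceeds 0.4x the local (rolling 2-s) amplitude range — an adaptive
    threshold that tolerates baseline drift and amplitude variation.  Each
    onset (pulse foot) is located in the last 35% of the interval since the
    previous peak (or the record start) as the last sample still within 2%
    of the beat amplitude above the window minimum; restricting the search
    to late diastole and using a threshold departure rather than a bare
    argmin keeps the foot at the systolic upstroke even when causal
    filtering makes the signal sag between beats or the diastolic valley
    is flat.

    Returns ``(peak_indices, onset_indices)`` (equal length).
    """
    import pandas as pd

    x = np.asarray(x, dtype=float)
    if x.size < int(2 * fs):
        raise ParameterError("need at least 2 s of signal to detect beats")
    distance = max(int(round(MIN_PEAK_SEPARATION_S * fs)), 1)
    peaks, props = find_peaks(x, distance=distance, prominence=0.0)
    if peaks.size == 0:
        raise NoBeatError("no local maxima found")
    win = max(int(round(range_window_s * fs)), 2)
    s = pd.Series(x)
    local_range = (
        s.rolling(win, center=True, min_periods=1).max()
        - s.rolling(win, center=True, min_periods=1).min()
    ).to_numpy()
    keep = props["prominences"] >= PROMINENCE_FRACTION * local_range[peaks]
    peaks = peaks[keep]
    if peaks.size == 0:
        raise NoBeatError("no sufficiently prominent systolic peaks")
    onsets = np.empty_like(peaks)
    prev = 0
    for k, p in enumerate(peaks):
        lo = max(prev, p - int(round(ONSET_SEARCH_FRACTION * (p - prev))))
        if p <= lo:
            onsets[k] = prev
        else:
            window = x[lo:p]
            m = window.min()
            tol = FOOT_TOLERANCE_FRACTION * (x[p] - m)
            below = np.nonzero(window <= m + tol)[0]
            onsets[k] = lo + int(below[-1])
        prev = p
    return peaks, onsets


def detect_fiducials(
    x: np.ndarray,
    fs: float,
    onset_index: int,
    peak_index: int,
    next_onset_index: int,
) -> BeatFiducials:
    """Fiducial points of the beat spanning ``[onset_index, next_onset_index)``.

    The dicrotic notch is the most prominent local minimum between the
    systolic peak and 80% of the beat period; the diastolic peak is the
    first local maximum after it.  If no local minimum exists, a
    second-derivative fallback records the inflection-type notch position
    (the diastolic wave itself is then absent).  All diastolic fields stay
    ``None`` unless the minimum-maximum pair rises by at least 1% of A_s.
    """
    x = np.asarray(x, dtype=float)
    if not onset_index <= peak_index < next_onset_index <= len(x):
        raise ParameterError("malformed beat segment boundaries")
    onset_amp = float(x[onset_index])
    a_s = float(x[peak_index]) - onset_amp
    if a_s <= 0:
        raise ParameterError("segment contains no systolic peak above its onset")
    fid = BeatFiducials(
        onset_index=int(onset_index),
        onset_time=onset_index / fs,
        onset_amplitude=onset_amp,
        systolic_peak_index=int(peak_index),
        systolic_peak_time=peak_index / fs,
        systolic_amplitude=a_s,
    )
    period = next_onset_index - onset_index
    search_end = min(onset_index + int(round(NOTCH_SEARCH_FRACTION * period)), next_onset_index)
    seg = x[peak_index:search_end]
    if seg.size < 3:
        return _finalize_class(fid)

    minima, min_props = find_peaks(-seg, prominence=0.0)
    if minima.size == 0:
        # inflection fallback: maximum of the second derivative marks where
        # the reflected wave shoulders the decay (no true trough)
        d2 = np.gradient(np.gradient(seg))
        if d2.size >= 3:
            interior = d2[1:-1]
            fid.notch_time = (peak_index + 1 + int(np.argmax(interior))) / fs
        return _finalize_class(fid)

    i_notch_rel = int(minima[np.argmax(min_props["prominences"])])
    i_notch = peak_index + i_notch_rel
    after = x[i_notch:next_onset_index]
    maxima, _ = find_peaks(after)
    fid.notch_time = i_notch / fs
    if maxima.size == 0:
        return _finalize_class(fid)
    i_dia = i_notch + int(maxima[0])
    prominence = float(x[i_dia] - x[i_notch])
    a_d = float(x[i_dia]) - onset_amp
    if prominence < NOTCH_PRESENCE_FRACTION * a_s or a_d <= 0:
        return _finalize_class(fid)
    fid.notch_prominence = prominence
    fid.diastolic_peak_time = i_dia / fs
    fid.diastolic_amplitude = min(a_d, a_s)
    return _finalize_class(fid)


def _finalize_class(fid: BeatFiducials) -> BeatFiducials:
    cls, eligible = classify_dawber(fid)
    fid.dawber_class = cls
    fid.eligible = eligible
    return fid


def classify_dawber(fid: BeatFiducials) -> tuple[int, bool]:
    """Grade a beat by diastolic-wave prominence and flag RI/ETc eligibility.

    Class 1: distinct notch and diastolic peak (prominence > 10% of A_s);
    class 2: visible notch, weak diastolic peak (1-10%]; classes 3-4: no
    usable notch.  Eligible iff class 1-2 with both A_d and dT measurable.
    """
    if fid.notch_prominence is None or fid.diastolic_amplitude is None:
        return 3, False
    rel = fid.notch_prominence / fid.systolic_amplitude
    cls = 1 if rel > CLASS1_PROMINENCE_FRACTION else 2
    eligible = fid.delta_t is not None and fid.diastolic_amplitude > 0
    return cls, eligible


def skewness_sqi(x: np.ndarray) -> float:
    """Skewness signal quality index: mean of cubed standardized samples.

    Uses the population (divisor-N) standard deviation, matching the 1/N
    averaging of the definition.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ParameterError("need at least 3 samples")
    mu = x.mean()
    sigma = x.std()  # population convention (ddof=0)
    if sigma == 0:
        raise UndefinedIndexError("skewness undefined for zero-variance signal")
    return float(np.mean(((x - mu) / sigma) ** 3))


def reflection_index(fiducials: list[BeatFiducials]) -> float:
    """Record-level RI (%): mean over eligible beats of 100 * A_d / A_s."""
    vals = [
        100.0 * f.diastolic_amplitude / f.systolic_amplitude
        for f in fiducials
        if f.eligible
    ]
    if not vals:
        raise UndefinedIndexError("no eligible beats for the reflection index")
    return float(np.mean(vals))


def ejection_time_compensated(fiducials: list[BeatFiducials], hr_bpm: float) -> float:
    """Record-level ETc (ms): mean over eligible beats of dT/sqrt(HR/60)."""
    if hr_bpm <= 0:
        raise ParameterError("heart rate must be positive")
    vals = [1000.0 * f.delta_t / np.sqrt(hr_bpm / 60.0) for f in fiducials if f.eligible]
    if not vals:
        raise UndefinedIndexError("no eligible beats for the ejection-time index")
    return float(np.mean(vals))


def heart_rate(peak_times: np.ndarray) -> float:
    """Heart rate in bpm from systolic peak times (median inter-beat interval)."""
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        raise UndefinedIndexError("need at least 2 beats for a heart rate")
    return 60.0 / float(np.median(np.diff(peak_times)))


def analyze_signal(
    x: np.ndarray, fs: float
) -> tuple[IndexSet, list[BeatFiducials], np.ndarray]:
    """Full morphological analysis of one (pre-processed) signal.

    Detects beats, extracts per-beat fiducials, and computes the record
    indices.  RI/ETc are ``None`` when fewer than MIN_ELIGIBLE_FRACTION of
    the beats carry a usable diastolic wave — indices averaged over a small
    minority of beats reflect detection noise, not waveform morphology.
    The skewness index is always reported.

    Returns ``(indices, per-beat fiducials, systolic peak indices)``.
    """
    peaks, onsets = detect_beats(x, fs)
    boundaries = list(onsets[1:]) + [len(x)]
    fids = []
    for onset, peak, nxt in zip(onsets, peaks, boundaries):
        # the last beat has no following onset; skip it if truncated
        if nxt - onset < int(0.25 * fs):
            continue
        try:
            fids.append(detect_fiducials(x, fs, onset, peak, nxt))
        except ParameterError:
            continue
    hr = heart_rate(peaks / fs)
    s = skewness_sqi(x)
    used = sum(f.eligible for f in fids)
    if fids and used / len(fids) >= MIN_ELIGIBLE_FRACTION:
        try:
            ri = reflection_index(fids)
            etc = ejection_time_compensated(fids, hr)
        except UndefinedIndexError:
            ri, etc = None, None
    else:
        ri, etc = None, None
    return (
        IndexSet(
            s_sqi=s,
            hr_bpm=hr,
            ri_percent=ri,
            etc_ms=etc,
            n_beats_total=len(fids),
            n_beats_used=used,
        ),
        fids,
        peaks,
    )
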