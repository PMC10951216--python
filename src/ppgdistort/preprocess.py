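"""Pre-processing chain for raw PPG records.

The chain is: invert the raw signal, estimate and subtract the DC component
(1-s moving average), then in parallel (a) band-pass filter and (b) smooth
with a short 10-sample moving average to obtain the *reference* signal that
all distortion metrics are compared against, and finally normalize each
branch to the systolic-wave amplitude so that pulse waves from different
filters are comparable on a common 0-1 scale.

Both moving averages are centered (symmetric window, shrunken at the edges)
so the reference branch introduces no phase shift of its own — essential,
since every delay metric is measured against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoBeatError, ParameterError
from .synth import PPGRecord

__all__ = [
    "ProcessedSignal",
    "moving_average",
    "estimate_dc",
    "invert_and_remove_dc",
    "smooth_reference",
    "normalize_to_systolic",
]


@dataclass
class ProcessedSignal:
    """A signal at a known stage of the chain, with its provenance."""

    samples: np.ndarray
    fs: float
    stage: str  # "ac" | "reference" | "filtered" | "normalized"
    provenance: list[str] = field(default_factory=list)
    record_id: str = "rec"

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrunken windows at the edges."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("empty signal")
    if window < 1:
        raise ParameterError("window must span at least one sample")
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def estimate_dc(x: np.ndarray, fs: float, window_s: float = 1.0) -> np.ndarray:
    """Slowly varying DC component via a moving average of ``window_s`` s.

    At fs = 320 Hz and a 1-s window this is the canonical N = 320 average.
    """
    window = int(round(window_s * fs))
    if window < 1:
        raise ParameterError("DC window spans less than one sample")
    return moving_average(x, window)


def invert_and_remove_dc(
    record: PPGRecord, dc_window_s: float = 1.0
) -> ProcessedSignal:
    """Invert a raw-polarity record and subtract its moving-average DC.

    The output's pulse peaks point upward and its mean over any interior
    1-s window is near zero.
    """
    if record.polarity != "raw-inverted":
        raise ParameterError(
            f"expected a raw-inverted record, got polarity {record.polarity!r}"
        )
    upright = -np.asarray(record.samples, dtype=float)
    ac = upright - estimate_dc(upright, record.fs, dc_window_s)
    return ProcessedSignal(
        samples=ac,
        fs=record.fs,
        stage="ac",
        provenance=[f"invert", f"dc_subtract(window_s={dc_window_s})"],
        record_id=record.record_id,
    )


def smooth_reference(
    ac: ProcessedSignal, window_samples: int = 10
) -> ProcessedSignal:
    """Short moving-average smoothing that defines the reference branch.

    The 10-sample default closely follows the contour of the pulse wave
    while suppressing high-frequency sensor noise; being centered, it
    moves the systolic peak by at most one sample.
    """
    out = moving_average(ac.samples, window_samples)
    return ProcessedSignal(
        samples=out,
        fs=ac.fs,
        stage="reference",
        provenance=ac.provenance + [f"smooth(window_samples={window_samples})"],
        record_id=ac.record_id,
    )


def normalize_to_systolic(
    sig: ProcessedSignal,
    onset_indices: np.ndarray,
    peak_indices: np.ndarray,
) -> ProcessedSignal:
    """Rescale a signal to the systolic-wave amplitude (nominal 0-1 range).

    The per-record baseline is the median of the beat-onset amplitudes; the
    scale is the mean systolic-peak amplitude above that baseline.  Using
    one scale per record (not per beat) preserves the beat-to-beat amplitude
    structure that the reflection index depends on.  Affine-invariant:
    ``normalize(k*x + b)`` equals ``normalize(x)`` for k > 0.
    """
    peak_indices = np.asarray(peak_indices, dtype=int)
    onset_indices = np.asarray(onset_indices, dtype=int)
    if peak_indices.size == 0:
        raise NoBeatError("cannot normalize: no systolic peaks provided")
    x = np.asarray(sig.samples, dtype=float)
    baseline = float(np.median(x[onset_indices])) if onset_indices.size else 0.0
    scale = float(np.mean(x[peak_indices])) - baseline
    if scale <= 0:
        raise NoBeatError("systolic amplitude above baseline is not positive")
    return ProcessedSignal(
        samples=(x - baseline) / scale,
        fs=sig.fs,
        stage="normalized",
        provenance=sig.provenance + ["normalize_to_systolic"],
        record_id=sig.record_id,
    )
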