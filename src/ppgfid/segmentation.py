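"""Signal-quality gating and single-beat extraction.

A record is admitted on its skewness signal-quality index (Ssqi): the
third standardized moment of the samples.  A clean pulse — sharp systolic
upstroke, long diastolic tail — is right-skewed, so a positive Ssqi
separates usable beats from motion-corrupted ones; the default inclusion
threshold is 0.41.  Pulse onsets are the local minima delimiting beats,
and the analysed segment is the slice between the first two onsets
(Min1, Min2), inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import DegenerateBeatError, NoBeatError, ParameterError

__all__ = [
    "BeatSegment",
    "skewness_sqi",
    "select_segment",
    "detect_onsets",
    "extract_beat",
]

SQI_THRESHOLD_DEFAULT = 0.41


@dataclass
class BeatSegment:
    """One beat of filtered pulse, bounded by onset indices (inclusive)."""

    subject_id: str
    min1: int
    min2: int
    samples: np.ndarray
    fs: float
    truncated: bool = False

    @property
    def wavelength(self) -> int:
        """Total segment length T in samples."""
        return self.min2 - self.min1 + 1


def skewness_sqi(samples: np.ndarray, bias_corrected: bool = False) -> float:
    """Skewness signal-quality index: the third standardized moment.

    The default is the biased (divisor-n) moment estimator
    ``mean(((x - mean) / std)**3)`` with the population standard deviation;
    ``bias_corrected=True`` applies the usual small-sample adjustment.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ParameterError(f"need at least 3 samples for a skewness, got {x.size}")
    mu = x.mean()
    sd = x.std()  # population (divisor n)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateBeatError("zero-variance input has no defined skewness")
    g1 = float(np.mean(((x - mu) / sd) ** 3))
    if bias_corrected:
        n = x.size
        g1 *= np.sqrt(n * (n - 1)) / (n - 2)
    return g1


def select_segment(
    candidates: Sequence[tuple[str, np.ndarray]],
    threshold: float = SQI_THRESHOLD_DEFAULT,
) -> str | None:
    """Pick the candidate segment with the highest Ssqi at or above threshold.

    Returns the chosen segment id, or ``None`` when no candidate reaches
    the threshold (the subject is then excluded).  Ties are broken toward
    the earliest candidate.
    """
    if len(candidates) == 0:
        raise ParameterError("no candidate segments supplied")
    best_id, best_val = None, -np.inf
    for seg_id, samples in candidates:
        val = skewness_sqi(samples)
        if val >= threshold and val > best_val:
            best_id, best_val = seg_id, val
    return best_id


def detect_onsets(
    filtered_ppg: np.ndarray,
    fs: float = 1000.0,
    prominence_frac: float = 0.05,
    min_spacing_s: float = 0.3,
) -> np.ndarray:
    """Locate pulse onsets: prominent local minima of the filtered pulse.

    A minimum qualifies when its prominence is at least ``prominence_frac``
    of the record's peak-to-peak range and it is at least ``min_spacing_s``
    seconds from the previous onset (a 200 bpm ceiling by default).
    """
    x = np.asarray(filtered_ppg, dtype=float)
    if x.size < 3:
        raise NoBeatError("record too short to contain a beat")
    rng = np.ptp(x)
    if rng == 0:
        raise NoBeatError("flat record contains no beats")
    onsets, _ = find_peaks(
        -x,
        prominence=prominence_frac * rng,
        distance=max(1, int(round(min_spacing_s * fs))),
    )
    if onsets.size < 2:
        raise NoBeatError(f"found {onsets.size} onset(s); need at least 2 to bound a beat")
    return onsets


def extract_beat(
    filtered_ppg: np.ndarray,
    min1: int,
    min2: int,
    subject_id: str = "",
    fs: float = 1000.0,
    max_export_len: int = 1200,
) -> BeatSegment:
    """Slice the inclusive beat segment [min1, min2] out of a record.

    Indices are 0-based internally; they are converted to 1-based only at
    the CSV boundary.  Segments longer than ``max_export_len`` are kept in
    full but flagged ``truncated`` so writers know zero-padded export will
    clip them.
    """
    x = np.asarray(filtered_ppg, dtype=float)
    if not (0 <= min1 < min2 < x.size):
        raise ParameterError(
            f"invalid beat bounds min1={min1}, min2={min2} for record of {x.size} samples"
        )
    samples = x[min1 : min2 + 1].copy()
    return BeatSegment(
        subject_id=subject_id,
        min1=int(min1),
        min2=int(min2),
        samples=samples,
        fs=fs,
        truncated=samples.size > max_export_len,
    )
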