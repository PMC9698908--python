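"""Pulse-wave delineation: peak/valley detection and per-beat indices.

A PPG heartbeat cycle is one systolic peak bounded by two valleys.  Peaks
are local maxima passed through a prominence gate and a refractory-distance
rule; valleys are the minima between consecutive retained peaks.  From the
(valley, peak, valley) triplet of each complete beat, five morphological
indices are measured:

==== ==========================================================
BVA  blood volume amplitude: onset valley to peak, mV
ST   systolic upstroke time: onset valley to peak, ms
DT   diastolic time: peak to next valley, ms
PPI  peak-to-peak interval to the next beat, ms
VVI  valley-to-valley interval (onset to next onset), ms
==== ==========================================================

By these definitions ST + DT = VVI exactly for every beat.  Timing is at
sample resolution (times are sample index / fs); no sub-sample interpolation
is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthcohort import PPGRecord

DEFAULT_MIN_DISTANCE_S = 0.33  # refractory spacing, ~180 bpm ceiling
DEFAULT_MIN_PROMINENCE_FRAC = 0.3

BEAT_COLUMNS = ["beat_idx", "onset_s", "peak_s", "end_s", "bva_mV", "st_ms", "dt_ms", "ppi_ms", "vvi_ms"]


class DelineationError(ValueError):
    """Raised when landmarks do not form an alternating valley/peak structure."""


@dataclass(frozen=True)
class LandmarkSet:
    """Retained peak and valley sample positions (strictly increasing)."""

    peak_indices: np.ndarray
    valley_indices: np.ndarray


def bandpass_filter(record: PPGRecord, low_hz: float = 0.1, high_hz: float = 50.0, order: int = 4) -> PPGRecord:
    """Zero-phase Butterworth band-pass; length preserved."""
    if not 0 < low_hz < high_hz < record.fs / 2:
        raise ValueError("band must satisfy 0 < low_hz < high_hz < fs/2")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=record.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, record.samples)
    return PPGRecord(samples=filtered, fs=record.fs, subject_id=record.subject_id, stage=record.stage)


def detect_peaks(
    record: PPGRecord,
    min_distance_s: float = DEFAULT_MIN_DISTANCE_S,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
) -> np.ndarray:
    """Locate systolic peaks.

    Candidate maxima are pre-thinned to the refractory spacing
    ``min_distance_s`` (this stabilizes the prominence statistics against
    ripple maxima riding on the pulse slopes); candidates with prominence
    below ``min_prominence_frac`` times the median candidate prominence are
    then rejected, and a final greedy pass re-enforces the spacing, keeping
    the higher-prominence candidate (earlier on ties) whenever two survivors
    lie closer than ``min_distance_s``.  Set ``min_prominence_frac=0`` to
    disable the gate on clean signals.
    """
    x = np.asarray(record.samples, dtype=float)
    if x.size == 0:
        raise ValueError("record is empty")
    min_dist = max(int(round(min_distance_s * record.fs)), 1)
    candidates, _ = sps.find_peaks(x, distance=min_dist)
    if candidates.size == 0:
        return np.array([], dtype=int)
    prominences = sps.peak_prominences(x, candidates)[0]
    if min_prominence_frac > 0:
        threshold = min_prominence_frac * float(np.median(prominences))
        keep = prominences >= threshold
        candidates, prominences = candidates[keep], prominences[keep]

    # greedy refractory selection: best prominence first, earlier wins ties
    order = np.lexsort((candidates, -prominences))
    accepted: list[int] = []
    for idx in candidates[order]:
        if all(abs(idx - a) >= min_dist for a in accepted):
            accepted.append(int(idx))
    return np.array(sorted(accepted), dtype=int)


def detect_valleys(record: PPGRecord, peaks: np.ndarray) -> np.ndarray:
    """Valleys = argmin strictly between consecutive peaks (earliest on ties),
    plus the onset valley before the first peak (argmin of the leading span).
    """
    x = np.asarray(record.samples, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        return np.array([], dtype=int)
    valleys = []
    if peaks[0] > 0:
        valleys.append(int(np.argmin(x[: peaks[0]])))
    for left, right in zip(peaks[:-1], peaks[1:]):
        seg = x[left + 1 : right]
        if seg.size:
            valleys.append(int(left + 1 + np.argmin(seg)))
    return np.array(valleys, dtype=int)


def _check_alternating(peaks: np.ndarray, valleys: np.ndarray) -> None:
    merged = sorted([(v, "v") for v in valleys] + [(p, "p") for p in peaks])
    kinds = "".join(k for _, k in merged)
    if "pp" in kinds or "vv" in kinds:
        raise DelineationError(f"landmarks do not alternate: pattern {kinds!r}")


def delineate_beats(record: PPGRecord, landmarks: LandmarkSet) -> pd.DataFrame:
    """Measure the five indices for every complete (valley, peak, valley) beat.

    Beat i spans valley_i → peak_i → valley_{i+1}; the trailing beat without a
    closing valley is dropped.  ``ppi_ms`` of the final measured beat is NaN
    when no following peak exists.
    """
    peaks = np.asarray(landmarks.peak_indices, dtype=int)
    valleys = np.asarray(landmarks.valley_indices, dtype=int)
    if valleys.size < 2:
        raise DelineationError("need at least two valleys to delineate a beat")
    _check_alternating(peaks, valleys)
    x = np.asarray(record.samples, dtype=float)
    fs = record.fs

    n_beats = min(peaks.size, valleys.size - 1)
    rows = []
    for i in range(n_beats):
        v0, p, v1 = valleys[i], peaks[i], valleys[i + 1]
        if not v0 < p < v1:
            raise DelineationError(f"beat {i}: landmarks not ordered ({v0}, {p}, {v1})")
        ppi = (peaks[i + 1] - p) / fs * 1000.0 if i + 1 < peaks.size else np.nan
        rows.append(
            {
                "beat_idx": i,
                "onset_s": v0 / fs,
                "peak_s": p / fs,
                "end_s": v1 / fs,
                "bva_mV": x[p] - x[v0],
                "st_ms": (p - v0) / fs * 1000.0,
                "dt_ms": (v1 - p) / fs * 1000.0,
                "ppi_ms": ppi,
                "vvi_ms": (v1 - v0) / fs * 1000.0,
            }
        )
    return pd.DataFrame(rows, columns=BEAT_COLUMNS)


def delineate_record(
    record: PPGRecord,
    bandpass: tuple[float, float] | None = None,
    min_distance_s: float = DEFAULT_MIN_DISTANCE_S,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
) -> pd.DataFrame:
    """Full delineation of one record: optional band-pass, peaks, valleys, beats.

    ``bandpass`` of None skips filtering (appropriate for clean synthetic
    signals); pass e.g. ``(0.1, 50.0)`` for raw device-like input.
    """
    if bandpass is not None:
        record = bandpass_filter(record, *bandpass)
    peaks = detect_peaks(record, min_distance_s, min_prominence_frac)
    if peaks.size < 2:
        return pd.DataFrame(columns=BEAT_COLUMNS)
    valleys = detect_valleys(record, peaks)
    return delineate_beats(record, LandmarkSet(peak_indices=peaks, valley_indices=valleys))
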