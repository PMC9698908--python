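"""Segment features, differential features and leakage-free normalization.

Each 3-minute recording is split into six non-overlapping 30-second
segments.  A segment is summarized by the mean and standard deviation of
each of the five beat indices (BVA, ST, DT, PPI, VVI) — ten "waveform"
features.  Because resting pulse morphology differs strongly between
subjects, each activated-stage segment is additionally expressed as a
differential vector: its features minus the subject's baseline reference
(the per-feature mean over the subject's baseline segments).  Waveform and
differential blocks concatenate into a 20-feature combined vector.

Normalization is z-scoring whose column means/SDs are estimated from
training rows only and then applied to both training and test rows, so no
statistic ever leaks from held-out data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

INDEX_NAMES = ("bva", "st", "dt", "ppi", "vvi")
WAVEFORM_FEATURES = [f"{idx}_{stat}" for idx in INDEX_NAMES for stat in ("mean", "std")]
DIFFERENTIAL_FEATURES = [f"d_{name}" for name in WAVEFORM_FEATURES]
COMBINED_FEATURES = WAVEFORM_FEATURES + DIFFERENTIAL_FEATURES

FEATURE_SETS = {
    "waveform10": WAVEFORM_FEATURES,
    "differential10": DIFFERENTIAL_FEATURES,
    "combined20": COMBINED_FEATURES,
}

EMOTION_STAGES = ("neutral", "anger", "happiness", "sadness")

#: Task → (stages used, stage → class label).  Binary baseline-vs-state tasks
#: label the baseline 0 and the activated stage 1.  The multi-state tasks use
#: only the four recall stages: 2C groups negative = {anger, sadness} vs
#: positive = {neutral, happiness}; 3C splits neutral out of the positive
#: class; 4C keeps all four stages distinct.
TASKS: dict[str, dict[str, int]] = {
    "baseline_vs_neutral": {"baseline": 0, "neutral": 1},
    "baseline_vs_anger": {"baseline": 0, "anger": 1},
    "baseline_vs_happiness": {"baseline": 0, "happiness": 1},
    "baseline_vs_sadness": {"baseline": 0, "sadness": 1},
    "2C": {"anger": 0, "sadness": 0, "neutral": 1, "happiness": 1},
    "3C": {"anger": 0, "sadness": 0, "neutral": 1, "happiness": 2},
    "4C": {"anger": 0, "sadness": 1, "neutral": 2, "happiness": 3},
}

MIN_BEATS_PER_SEGMENT = 3
DEFAULT_WINDOW_S = 30.0


class InvalidSegmentError(ValueError):
    """Segment holds too few beats to yield stable statistics."""


def segment_record(
    beats: pd.DataFrame, duration_s: float, window_s: float = DEFAULT_WINDOW_S
) -> list[pd.DataFrame]:
    """Partition delineated beats into consecutive half-open time windows.

    Beat membership is decided by the onset-valley time: window k is
    [k*window_s, (k+1)*window_s).  A trailing partial window is dropped with
    a warning.  Returns one (possibly empty) DataFrame per window.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    n_windows = duration_s / window_s
    if abs(n_windows - round(n_windows)) > 1e-9:
        warnings.warn("duration is not a multiple of window_s; trailing partial window dropped")
    n_windows = int(np.floor(n_windows + 1e-9))
    groups = []
    onset = beats["onset_s"].to_numpy()
    for k in range(n_windows):
        mask = (onset >= k * window_s) & (onset < (k + 1) * window_s)
        groups.append(beats.loc[mask])
    return groups


def segment_features(beat_group: pd.DataFrame) -> dict[str, float]:
    """Mean and population SD (divisor n) of each index over one segment.

    The final beat's PPI may be undefined (NaN); it is excluded pairwise.
    Raises :class:`InvalidSegmentError` below 3 beats.
    """
    if len(beat_group) < MIN_BEATS_PER_SEGMENT:
        raise InvalidSegmentError(f"segment has {len(beat_group)} beats (< {MIN_BEATS_PER_SEGMENT})")
    out: dict[str, float] = {}
    for idx in INDEX_NAMES:
        col = "bva_mV" if idx == "bva" else f"{idx}_ms"
        values = beat_group[col].to_numpy(dtype=float)
        values = values[~np.isnan(values)]
        out[f"{idx}_mean"] = float(np.mean(values))
        out[f"{idx}_std"] = float(np.std(values))  # population SD
    return out


def baseline_reference(baseline_vectors: pd.DataFrame) -> pd.Series:
    """Per-feature mean across a subject's valid baseline segments."""
    if len(baseline_vectors) == 0:
        raise ValueError("subject has no valid baseline segments")
    return baseline_vectors[WAVEFORM_FEATURES].mean(axis=0)


def differential_features(state_vector: pd.Series, reference: pd.Series) -> pd.Series:
    """Elementwise state − baseline-reference, renamed with a ``d_`` prefix."""
    missing = [k for k in WAVEFORM_FEATURES if k not in state_vector.index or k not in reference.index]
    if missing:
        raise KeyError(f"feature names missing: {missing}")
    delta = state_vector[WAVEFORM_FEATURES] - reference[WAVEFORM_FEATURES]
    delta.index = DIFFERENTIAL_FEATURES
    return delta


def extract_cohort_features(
    cohort,
    bandpass: tuple[float, float] | None = (0.1, 8.0),
    min_prominence_frac: float = 0.05,
    window_s: float = DEFAULT_WINDOW_S,
) -> pd.DataFrame:
    """Delineate every record of a cohort and build the full feature table.

    One row per valid segment with keys (subject_id, stage, segment_idx
    1-based), the 10 waveform features and the 10 differential features
    (baseline rows carry their own delta to the subject's baseline
    reference).  Subjects without a valid baseline segment are dropped with
    a warning.

    The default band-pass upper edge (8 Hz) keeps the pulse harmonics while
    suppressing broadband noise ahead of the local-maxima delineator, and
    after that smoothing a mild prominence gate (0.05 of the median) is
    enough to reject ripple maxima without censoring genuinely small beats —
    a missed beat merges two cycles and corrupts the interval SD features
    far more than any ripple peak could.  Pass ``bandpass=None`` and gate 0
    for clean synthetic signals.
    """
    from .delineation import delineate_record

    rows = []
    for (sid, stage), record in cohort.records.items():
        beats = delineate_record(record, bandpass=bandpass, min_prominence_frac=min_prominence_frac)
        groups = segment_record(beats, record.duration, window_s)
        for k, group in enumerate(groups):
            try:
                feats = segment_features(group)
            except InvalidSegmentError:
                warnings.warn(f"dropping invalid segment {sid}/{stage}/{k + 1}")
                continue
            rows.append({"subject_id": sid, "stage": stage, "segment_idx": k + 1, **feats})
    table = pd.DataFrame(rows)

    # differential block: per subject, subtract the baseline reference
    pieces = []
    for sid, sub in table.groupby("subject_id", sort=False):
        base = sub[sub["stage"] == "baseline"]
        if len(base) == 0:
            warnings.warn(f"subject {sid} has no valid baseline segment; excluded")
            continue
        ref = baseline_reference(base)
        diff = sub[WAVEFORM_FEATURES].sub(ref, axis=1)
        diff.columns = DIFFERENTIAL_FEATURES
        pieces.append(pd.concat([sub, diff], axis=1))
    return pd.concat(pieces, ignore_index=True) if pieces else table


def assemble_matrix(features: pd.DataFrame, feature_set: str, task: str) -> pd.DataFrame:
    """Restrict the cohort feature table to one task and one feature set.

    Returns a matrix with key columns (subject_id, stage, segment_idx), the
    requested feature columns in fixed order, an integer ``label`` column
    and a ``fold`` column equal to the segment index.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature_set {feature_set!r}")
    stage_labels = TASKS[task]
    cols = FEATURE_SETS[feature_set]
    sel = features[features["stage"].isin(stage_labels)].copy()
    sel["label"] = sel["stage"].map(stage_labels).astype(int)
    sel["fold"] = sel["segment_idx"].astype(int)
    out = sel[["subject_id", "stage", "segment_idx", *cols, "label", "fold"]].reset_index(drop=True)
    if out[cols].isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return out


@dataclass
class NormalizationModel:
    """Per-column z-score statistics estimated from training rows only."""

    mean: pd.Series
    std: pd.Series

    def apply(self, rows: pd.DataFrame) -> pd.DataFrame:
        return zscore_apply(self, rows)


def zscore_fit(train_rows: pd.DataFrame, columns: list[str] | None = None) -> NormalizationModel:
    """Estimate column means and population SDs from training rows."""
    if len(train_rows) < 2:
        raise ValueError("need at least 2 training rows to fit normalization")
    cols = list(columns) if columns is not None else list(train_rows.columns)
    sub = train_rows[cols].astype(float)
    return NormalizationModel(mean=sub.mean(axis=0), std=sub.std(axis=0, ddof=0))


def zscore_apply(model: NormalizationModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Transform rows with the fitted statistics; constant columns map to 0."""
    cols = list(model.mean.index)
    out = rows.copy()
    std = model.std.copy()
    constant = std == 0
    if constant.any():
        warnings.warn(f"constant training columns set to zero: {list(std.index[constant])}")
        std[constant] = 1.0
    transformed = (rows[cols].astype(float) - model.mean) / std
    transformed.loc[:, constant[constant].index] = 0.0
    out[cols] = transformed
    return out
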