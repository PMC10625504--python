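"""Trial preprocessing: missing-sample repair, lift-event detection,
windowing with time normalization, and object velocity.

Each trial is cut to the lifting process.  Lift onset is the first sample
whose object height exceeds the pre-movement baseline level by a fixed
threshold; lift end (t_e) is the first sample from which the height stays
within a settle tolerance of its final (placed) value.  Two windowing modes
feed the classifier:

* ``first_T`` — the first T samples after onset, with the time grid
  normalized as (t_j - t_1)/(t_T - t_1), to probe early prediction
  (T = 30 samples is 300 ms at 100 Hz);
* ``full`` — onset..t_e, normalized to [0, 1], so trials of different
  durations become comparable.

No operation here reads the weight-class label: preprocessing is
label-blind by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .synthkin import ANGLE_CHANNELS, Trial

__all__ = [
    "PreprocessParams",
    "Segment",
    "LiftDetectionError",
    "TrialTooShortError",
    "UnusableTrialError",
    "interpolate_missing",
    "detect_lift_onset",
    "detect_lift_end",
    "object_velocity",
    "window_first_T",
    "window_full",
    "make_segment",
    "VELOCITY_CHANNELS",
]

VELOCITY_CHANNELS = ("vx", "vy", "vz")


class LiftDetectionError(RuntimeError):
    """No lift onset / no placement detected in the object-height series."""


class TrialTooShortError(RuntimeError):
    """The requested window extends past the end of the trial."""


class UnusableTrialError(RuntimeError):
    """Too few observed samples to repair the series."""


@dataclass(frozen=True)
class PreprocessParams:
    """Detection thresholds.

    The onset threshold and settle tolerance default to 10 mm — five times
    the typical optical-capture position noise — so a single-sample
    crossing rule is robust against false triggers.
    """

    baseline_window: int = 10
    onset_threshold_m: float = 0.010
    settle_tolerance_m: float = 0.010
    settle_window: int = 10


@dataclass
class Segment:
    """A trial windowed to (part of) the lifting process, on a normalized grid."""

    person_id: int
    weight_class: int
    start_position: str
    object_size: str
    mode: Literal["first_T", "full"]
    normalized_times: np.ndarray       # in [0, 1], first 0, last 1
    channels: np.ndarray               # (len(grid), N), gap-free
    channel_names: tuple[str, ...]
    T: int | None = None               # first_T mode only
    t_e_index: int | None = None       # full mode only

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]


def interpolate_missing(series: np.ndarray) -> np.ndarray:
    """Fill NaN gaps: linear between nearest observed neighbours, nearest
    value at the edges.  Observed samples pass through unchanged."""
    series = np.asarray(series, dtype=float)
    valid = ~np.isnan(series)
    n_valid = int(valid.sum())
    if n_valid == len(series):
        return series.copy()
    if n_valid < 2:
        raise UnusableTrialError(
            f"only {n_valid} observed samples; need at least 2 to interpolate"
        )
    idx = np.arange(len(series))
    # np.interp is linear between observed points and clamps at the edges
    return np.interp(idx, idx[valid], series[valid])


def detect_lift_onset(
    object_z: np.ndarray,
    baseline_window: int = 10,
    threshold: float = 0.010,
) -> int:
    """First sample where object height exceeds baseline mean + threshold."""
    z = np.asarray(object_z, dtype=float)
    if len(z) <= baseline_window:
        raise ValueError("series shorter than the baseline window")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    level = float(np.mean(z[:baseline_window])) + threshold
    above = z > level
    if not above.any():
        raise LiftDetectionError("no lift detected: height never exceeds baseline level")
    return int(np.argmax(above))


def detect_lift_end(
    object_z: np.ndarray,
    onset: int,
    settle_tolerance: float = 0.010,
    settle_window: int = 10,
) -> int:
    """First index e > onset from which ``settle_window`` consecutive samples
    stay within ``settle_tolerance`` of the final height.

    The final height is taken as the mean of the last ``settle_window``
    samples (robust against single-sample noise in the last frame).
    """
    z = np.asarray(object_z, dtype=float)
    n = len(z)
    if not 0 <= onset < n:
        raise ValueError("onset outside the series")
    final = float(np.mean(z[-settle_window:]))
    ok = np.abs(z - final) <= settle_tolerance
    w = settle_window
    # rolling all-true over windows of length w
    csum = np.concatenate([[0], np.cumsum(ok)])
    full = csum[w:] - csum[:-w] == w        # full[e] == all(ok[e:e+w])
    candidates = np.nonzero(full[onset + 1:])[0]
    if len(candidates) == 0:
        raise LiftDetectionError("no placement detected: height never settles")
    return int(onset + 1 + candidates[0])


def object_velocity(object_position: np.ndarray, sample_rate: float) -> np.ndarray:
    """3-channel velocity (m/s) by central differences (one-sided at edges)."""
    pos = np.asarray(object_position, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("object_position must be (n, 3)")
    if pos.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(pos, axis=0) * sample_rate


def _normalize_times(t_ms: np.ndarray) -> np.ndarray:
    span = t_ms[-1] - t_ms[0]
    if span <= 0:
        raise ValueError("window has zero time span")
    return (t_ms - t_ms[0]) / span


def window_first_T(
    trial: Trial,
    onset: int,
    T: int,
    channels: np.ndarray | None = None,
    channel_names: Sequence[str] | None = None,
) -> Segment:
    """The first T samples from lift onset, grid normalized to [0, 1].

    ``channels`` defaults to the trial's angle block; pass a (n, N) array
    (e.g. object velocity) with matching ``channel_names`` otherwise.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    if channels is None:
        channels = trial.angles
        channel_names = ANGLE_CHANNELS
    if onset + T > trial.n_samples:
        raise TrialTooShortError(
            f"trial has {trial.n_samples} samples; window needs onset({onset})+T({T})"
        )
    sl = slice(onset, onset + T)
    return Segment(
        person_id=trial.person_id,
        weight_class=trial.weight_class,
        start_position=trial.start_position,
        object_size=trial.object_size,
        mode="first_T",
        normalized_times=_normalize_times(trial.timestamps_ms[sl]),
        channels=np.asarray(channels, dtype=float)[sl],
        channel_names=tuple(channel_names),
        T=T,
    )


def window_full(
    trial: Trial,
    onset: int,
    end: int,
    channels: np.ndarray | None = None,
    channel_names: Sequence[str] | None = None,
) -> Segment:
    """The whole lifting process onset..end (inclusive), normalized to [0, 1]."""
    if channels is None:
        channels = trial.angles
        channel_names = ANGLE_CHANNELS
    if end <= onset:
        raise ValueError("invalid window: end must exceed onset")
    if end >= trial.n_samples:
        raise TrialTooShortError("window end past the trial")
    sl = slice(onset, end + 1)
    return Segment(
        person_id=trial.person_id,
        weight_class=trial.weight_class,
        start_position=trial.start_position,
        object_size=trial.object_size,
        mode="full",
        normalized_times=_normalize_times(trial.timestamps_ms[sl]),
        channels=np.asarray(channels, dtype=float)[sl],
        channel_names=tuple(channel_names),
        t_e_index=end,
    )


def repaired_channels(trial: Trial) -> tuple[np.ndarray, np.ndarray]:
    """Gap-free copies of the angle block and object position."""
    angles = np.column_stack(
        [interpolate_missing(trial.angles[:, i]) for i in range(trial.angles.shape[1])]
    )
    pos = np.column_stack(
        [interpolate_missing(trial.object_position[:, i]) for i in range(3)]
    )
    return angles, pos


def make_segment(
    trial: Trial,
    feature_set: Literal["angles", "object_velocity"],
    mode: Literal["first_T", "full"],
    T: int | None = None,
    params: PreprocessParams | None = None,
    sample_rate: float = 100.0,
) -> Segment:
    """Full preprocessing of one trial for one feature set and window.

    Repairs missing samples, detects the lift events on object height, and
    windows either the 7 angle channels or the 3 object-velocity channels.

    Raises LiftDetectionError / TrialTooShortError for trials to exclude.
    """
    params = params or PreprocessParams()
    angles, pos = repaired_channels(trial)
    onset = detect_lift_onset(
        pos[:, 2], baseline_window=params.baseline_window,
        threshold=params.onset_threshold_m,
    )
    if feature_set == "angles":
        block, names = angles, ANGLE_CHANNELS
    elif feature_set == "object_velocity":
        block, names = object_velocity(pos, sample_rate), VELOCITY_CHANNELS
    else:
        raise ValueError(f"unknown feature set {feature_set!r}")
    if mode == "first_T":
        if T is None:
            raise ValueError("first_T mode requires T")
        return window_first_T(trial, onset, T, channels=block, channel_names=names)
    if mode == "full":
        end = detect_lift_end(
            pos[:, 2], onset,
            settle_tolerance=params.settle_tolerance_m,
            settle_window=params.settle_window,
        )
        return window_full(trial, onset, end, channels=block, channel_names=names)
    raise ValueError(f"unknown mode {mode!r}")
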