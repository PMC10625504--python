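"""Half-period cosine feature compression.

Each windowed channel alpha_i(t), t in [0, 1], is compressed into n
coefficients of the half-period cosine basis,

    alpha_i(t)  ~=  sum_{k=0}^{n-1} a_k^{(i)} cos(pi k t),

by least-squares projection onto {cos(pi k t_j)} at the segment's own
normalized grid.  The half-period basis suits non-periodic movement traces
(no periodicity is imposed at t = 1), smooths measurement noise, and turns
a ~163-sample multichannel trial into n*N numbers.  n defaults to 8; the
classification results are insensitive to similar choices.

The least-squares projection is the normative definition.  Speed comes
from caching the design-matrix pseudoinverse per (grid length, n) — all
grids arising from uniformly sampled trials are uniform on [0, 1], so the
cache is exact, not an approximation.

Features for M segments are assembled column-wise into X in R^{(nN) x M}
with labels y in {-1, +1}^M (-1 light, +1 heavy) and aligned person ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import Segment

__all__ = [
    "CosineFeatures",
    "FeatureMatrix",
    "UnderdeterminedFitError",
    "cosine_design",
    "cosine_coefficients",
    "reconstruct",
    "segment_features",
    "build_feature_matrix",
]

DEFAULT_N_COEFFS = 8


class UnderdeterminedFitError(ValueError):
    """Fewer samples than coefficients requested."""


@dataclass
class CosineFeatures:
    """Coefficients a_k^{(i)}: one length-n vector per channel."""

    a: np.ndarray                       # (N channels, n)
    n: int
    channel_names: tuple[str, ...]


@dataclass
class FeatureMatrix:
    """X in R^{(nN) x M}, columns are trials; y in {-1,+1}^M."""

    X: np.ndarray
    y: np.ndarray
    person_ids: np.ndarray
    channel_names: tuple[str, ...]
    n: int
    meta: pd.DataFrame                  # per-column condition metadata

    @property
    def n_trials(self) -> int:
        return self.X.shape[1]

    @property
    def n_features(self) -> int:
        return self.X.shape[0]


def cosine_design(t: np.ndarray, n: int) -> np.ndarray:
    """Design matrix [cos(pi k t_j)]_{j,k}, shape (len(t), n)."""
    t = np.asarray(t, dtype=float)
    return np.cos(np.pi * np.outer(t, np.arange(n)))


@lru_cache(maxsize=256)
def _uniform_pinv(length: int, n: int) -> np.ndarray:
    """Pseudoinverse of the design on the uniform grid linspace(0, 1, length)."""
    A = cosine_design(np.linspace(0.0, 1.0, length), n)
    return np.linalg.pinv(A)


def _is_uniform(t: np.ndarray) -> bool:
    return bool(
        np.allclose(t, np.linspace(0.0, 1.0, len(t)), rtol=0.0, atol=1e-12)
    )


def cosine_coefficients(
    channel: np.ndarray, t: np.ndarray | None = None, n: int = DEFAULT_N_COEFFS
) -> np.ndarray:
    """Least-squares coefficients a_0..a_{n-1} of one channel on its grid.

    ``t`` defaults to the uniform grid on [0, 1].  The returned vector
    minimizes sum_j (channel_j - sum_k a_k cos(pi k t_j))^2.
    """
    values = np.asarray(channel, dtype=float)
    if values.ndim != 1:
        raise ValueError("channel must be a 1-D series")
    if t is None:
        t = np.linspace(0.0, 1.0, len(values))
    t = np.asarray(t, dtype=float)
    if len(t) != len(values):
        raise ValueError("grid and series lengths differ")
    if len(values) < n:
        raise UnderdeterminedFitError(
            f"{len(values)} samples cannot determine {n} coefficients"
        )
    if _is_uniform(t):
        return _uniform_pinv(len(t), n) @ values
    A = cosine_design(t, n)
    coeffs, _, rank, _ = np.linalg.lstsq(A, values, rcond=None)
    if rank < n:
        raise np.linalg.LinAlgError(
            f"rank-deficient cosine design (rank {rank} < n={n}); "
            "degenerate time grid"
        )
    return coeffs


def reconstruct(a: np.ndarray, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate sum_k a_k cos(pi k t) at t (scalar or array) in [0, 1]."""
    a = np.asarray(a, dtype=float)
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = cosine_design(t_arr, len(a)) @ a
    return float(out[0]) if scalar else out


def segment_features(segment: Segment, n: int = DEFAULT_N_COEFFS) -> CosineFeatures:
    """Fit all channels of one segment on its shared grid."""
    t = segment.normalized_times
    if len(t) < n:
        raise UnderdeterminedFitError(
            f"{len(t)} samples cannot determine {n} coefficients"
        )
    if _is_uniform(t):
        a = (_uniform_pinv(len(t), n) @ segment.channels).T
    else:
        a = np.stack(
            [cosine_coefficients(segment.channels[:, i], t, n)
             for i in range(segment.n_channels)]
        )
    return CosineFeatures(a=a, n=n, channel_names=segment.channel_names)


def build_feature_matrix(
    segments: Sequence[Segment], n: int = DEFAULT_N_COEFFS
) -> FeatureMatrix:
    """Stack per-segment coefficients into X (nN x M) with aligned labels.

    Column j holds segment j's channels in fixed channel order, coefficient
    order k = 0..n-1 within each channel.  All segments must share the
    channel set and windowing mode.
    """
    if len(segments) == 0:
        raise ValueError("no segments")
    names = segments[0].channel_names
    mode = segments[0].mode
    for s in segments:
        if s.channel_names != names or s.mode != mode:
            raise ValueError("segments have heterogeneous channel sets or modes")
    N = len(names)
    M = len(segments)
    X = np.empty((n * N, M))
    for j, seg in enumerate(segments):
        X[:, j] = segment_features(seg, n).a.reshape(-1)
    y = np.array([s.weight_class for s in segments], dtype=int)
    person_ids = np.array([s.person_id for s in segments], dtype=int)
    meta = pd.DataFrame(
        {
            "person_id": person_ids,
            "weight_class": y,
            "start_position": [s.start_position for s in segments],
            "object_size": [s.object_size for s in segments],
            "mode": mode,
            "T": [s.T for s in segments],
        }
    )
    return FeatureMatrix(
        X=X, y=y, person_ids=person_ids, channel_names=names, n=n, meta=meta
    )
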