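"""Cross-validation orchestration and the window-length sweep.

Two CV strategies probe two different questions:

* ``all_trials`` — repeated random 80/20 splits of all trials, so the same
  person contributes to both train and test.  Measures within-sample
  discriminability; optimistic when trajectory shapes cluster by person.
* ``person_wise`` — the trials of 2 randomly chosen participants form the
  test set and all other participants the training set, so test persons
  are wholly unseen.  Measures transfer to new people.

Each CV is repeated (default 10 times) and the per-repetition test
classification rates, their mean and SD are reported.  The sweep crosses
window lengths T (plus the time-normalized full series) with the two
feature sets (7 joint angles vs 3 object-velocity components) and both CV
strategies, yielding the rate-vs-T table; trials too short for a given T
are excluded from that cell and counted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import classify
from .classify import SVMConfig, ThresholdResult
from .features import (
    DEFAULT_N_COEFFS,
    FeatureMatrix,
    build_feature_matrix,
    reconstruct,
    segment_features,
)
from .preprocess import (
    LiftDetectionError,
    PreprocessParams,
    Segment,
    TrialTooShortError,
    make_segment,
)
from .synthkin import ConfigError, Trial

__all__ = [
    "CVSpec",
    "CVResult",
    "SplitError",
    "split_all_trials",
    "split_person_wise",
    "run_cv",
    "build_segments",
    "feature_table",
    "peak_vertical_velocity",
    "threshold_baseline_cv",
    "sweep",
    "DEFAULT_T_GRID",
]

logger = logging.getLogger(__name__)

#: Default window-length grid (samples at 100 Hz): 300–1600 ms.
DEFAULT_T_GRID: tuple[int | str, ...] = (30, 50, 70, 100, 130, 160, "full")

FEATURE_SETS = ("angles", "object_velocity")
STRATEGIES = ("all_trials", "person_wise")


class SplitError(RuntimeError):
    """A usable train/test split could not be constructed."""


@dataclass(frozen=True)
class CVSpec:
    strategy: Literal["all_trials", "person_wise"] = "all_trials"
    test_fraction: float = 0.2
    n_test_persons: int = 2
    repetitions: int = 10
    seed: int = 0
    exhaustive_pairs: bool = False     # person_wise: iterate all person pairs

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigError(f"unknown CV strategy {self.strategy!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.repetitions < 1 or self.n_test_persons < 1:
            raise ConfigError("repetitions and n_test_persons must be positive")


@dataclass
class CVResult:
    rates: np.ndarray                  # per-repetition test classification rates
    spec: CVSpec
    feature_set: str = ""
    window: str = ""
    n_excluded: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.rates))

    @property
    def sd(self) -> float:
        return float(np.std(self.rates, ddof=1)) if len(self.rates) > 1 else 0.0


def split_all_trials(
    M: int,
    test_fraction: float,
    rng: np.random.Generator,
    strata: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random disjoint, exhaustive train/test split of M trials.

    When ``strata`` are given (here: the person x weight-class design
    cells) the test fraction is drawn uniformly within each stratum, so
    both subsets keep the design's balance.  Without stratification, a
    split of balanced chance-level data biases the measured rate below
    50%: the test set is exactly the complement of the training set, so a
    classifier leaning toward the training majority — globally or inside
    a person's cluster — is anti-correlated with the test composition.
    Every index still lands in the test set with probability
    ``test_fraction``.
    """
    if M < 5:
        raise SplitError("too few trials to split")
    n_test = int(round(test_fraction * M))
    if n_test < 1 or n_test >= M:
        raise SplitError("test fraction leaves an empty split")
    if strata is None:
        perm = rng.permutation(M)
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    strata = np.asarray(strata)
    test_parts = []
    for stratum in np.unique(strata):
        idx = np.nonzero(strata == stratum)[0]
        k = int(round(test_fraction * len(idx)))
        test_parts.append(rng.choice(idx, size=k, replace=False))
    test = np.sort(np.concatenate(test_parts))
    if len(test) == 0 or len(test) == M:
        # strata too small for the fraction: fall back to a plain split
        perm = rng.permutation(M)
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    train = np.setdiff1d(np.arange(M), test)
    return train, test


def split_person_wise(
    person_ids: np.ndarray, n_test_persons: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """All trials of a uniformly drawn set of persons form the test set."""
    person_ids = np.asarray(person_ids)
    persons = np.unique(person_ids)
    if len(persons) < n_test_persons + 1:
        raise SplitError(
            f"{len(persons)} persons cannot supply {n_test_persons} test persons "
            "and a non-empty training set"
        )
    test_persons = rng.choice(persons, size=n_test_persons, replace=False)
    mask = np.isin(person_ids, test_persons)
    return np.nonzero(~mask)[0], np.nonzero(mask)[0]


def _person_pair_splits(
    person_ids: np.ndarray, spec: CVSpec, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pre-draw the person-wise splits: distinct person sets across
    repetitions (all of them in exhaustive mode)."""
    persons = np.unique(person_ids)
    if len(persons) < spec.n_test_persons + 1:
        raise SplitError("too few persons for person-wise CV")
    combos = list(itertools.combinations(persons, spec.n_test_persons))
    if spec.exhaustive_pairs:
        chosen = combos
    else:
        if spec.repetitions > len(combos):
            raise SplitError(
                f"{spec.repetitions} repetitions exceed the {len(combos)} "
                "distinct person sets; use exhaustive_pairs or fewer repetitions"
            )
        idx = rng.choice(len(combos), size=spec.repetitions, replace=False)
        chosen = [combos[i] for i in idx]
    splits = []
    for combo in chosen:
        mask = np.isin(person_ids, combo)
        splits.append((np.nonzero(~mask)[0], np.nonzero(mask)[0]))
    return splits


def _design_strata(features: FeatureMatrix) -> np.ndarray:
    """Integer codes of the (person, start position, weight class) cells."""
    keys = list(
        zip(
            features.person_ids.tolist(),
            features.meta["start_position"].tolist(),
            features.y.tolist(),
        )
    )
    return pd.factorize(pd.Series(keys))[0]


def run_cv(
    features: FeatureMatrix,
    spec: CVSpec,
    hyper: SVMConfig | None = None,
) -> CVResult:
    """The repeated split -> standardize-on-train -> SVM -> score protocol.

    Fully determined by spec.seed.  A repetition whose training split
    contains a single class is resplit with the next derived seed (logged);
    person-wise repetitions use distinct person sets.
    """
    hyper = hyper or SVMConfig()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    M = features.n_trials
    if spec.strategy == "person_wise":
        planned = _person_pair_splits(features.person_ids, spec, rng)
        n_reps = len(planned)
    else:
        planned = None
        n_reps = spec.repetitions
    rates = np.empty(n_reps)
    for rep in range(n_reps):
        for attempt in range(100):
            if planned is not None:
                train_idx, test_idx = planned[rep]
            else:
                train_idx, test_idx = split_all_trials(
                    M, spec.test_fraction, rng, strata=_design_strata(features)
                )
            if len(np.unique(features.y[train_idx])) == 2:
                break
            logger.warning("single-class training split; resplitting (rep %d)", rep)
            if planned is not None:
                raise SplitError("person-wise training split is single-class")
        else:
            raise SplitError("could not draw a two-class training split")
        params = classify.zscore_fit(features.X[:, train_idx])
        X_tr = classify.zscore_apply(params, features.X[:, train_idx])
        X_te = classify.zscore_apply(params, features.X[:, test_idx])
        model = classify.train_svm(X_tr, features.y[train_idx], hyper,
                                   seed=spec.seed + rep)
        pred = classify.predict(model, X_te)
        rates[rep] = float(np.mean(pred == features.y[test_idx]))
    return CVResult(rates=rates, spec=spec)


# ---------------------------------------------------------------------------
# Dataset -> feature-table plumbing
# ---------------------------------------------------------------------------

def build_segments(
    trials: Sequence[Trial],
    feature_set: str,
    window: int | str,
    params: PreprocessParams | None = None,
    n: int = DEFAULT_N_COEFFS,
) -> tuple[list[Segment], int]:
    """Preprocess every trial for one (feature set, window) cell.

    Returns the usable segments and the number of excluded trials (too
    short for the window, or failed lift detection).
    """
    mode = "full" if window == "full" else "first_T"
    T = None if window == "full" else int(window)
    segments: list[Segment] = []
    excluded = 0
    for trial in trials:
        try:
            segments.append(
                make_segment(trial, feature_set, mode, T=T, params=params)
            )
        except (LiftDetectionError, TrialTooShortError) as exc:
            logger.info("excluding trial (person %d #%d): %s",
                        trial.person_id, trial.trial_index, exc)
            excluded += 1
    return segments, excluded


def feature_table(
    trials: Sequence[Trial],
    feature_set: str,
    window: int | str,
    params: PreprocessParams | None = None,
    n: int = DEFAULT_N_COEFFS,
) -> tuple[FeatureMatrix, int]:
    segments, excluded = build_segments(trials, feature_set, window, params, n)
    if not segments:
        raise ConfigError(f"no usable trials for window {window!r}")
    return build_feature_matrix(segments, n=n), excluded


def peak_vertical_velocity(
    trial: Trial,
    params: PreprocessParams | None = None,
    n: int = DEFAULT_N_COEFFS,
) -> float:
    """Per-trial maximum vertical object velocity (m/s).

    Taken from the n-coefficient cosine reconstruction of v_z on the full
    lifting window — the same smoothing the classifier sees — so the
    maximum is not dominated by differentiated sensor noise.
    """
    seg = make_segment(trial, "object_velocity", "full", params=params)
    a = segment_features(seg, n).a[2]          # v_z channel
    return float(np.max(reconstruct(a, seg.normalized_times)))


def threshold_baseline_cv(
    trials: Sequence[Trial],
    spec: CVSpec,
    params: PreprocessParams | None = None,
    n: int = DEFAULT_N_COEFFS,
) -> tuple[CVResult, list[ThresholdResult]]:
    """Repeated-split evaluation of the universal-threshold baseline."""
    usable = []
    v, y = [], []
    for trial in trials:
        try:
            v.append(peak_vertical_velocity(trial, params, n))
            y.append(trial.weight_class)
            usable.append(trial)
        except (LiftDetectionError, TrialTooShortError):
            continue
    v = np.asarray(v)
    y = np.asarray(y, dtype=int)
    person_ids = np.array([t.person_id for t in usable])
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.strategy == "person_wise":
        splits = _person_pair_splits(person_ids, spec, rng)
    else:
        splits = [split_all_trials(len(v), spec.test_fraction, rng)
                  for _ in range(spec.repetitions)]
    results = [classify.threshold_baseline(v, y, tr, te) for tr, te in splits]
    rates = np.array([r.test_accuracy for r in results])
    return CVResult(rates=rates, spec=spec, feature_set="peak_vz",
                    window="full"), results


def sweep(
    trials: Sequence[Trial],
    T_grid: Sequence[int | str] = DEFAULT_T_GRID,
    feature_sets: Sequence[str] = FEATURE_SETS,
    strategies: Sequence[str] = STRATEGIES,
    repetitions: int = 10,
    n: int = DEFAULT_N_COEFFS,
    hyper: SVMConfig | None = None,
    params: PreprocessParams | None = None,
    seed: int = 0,
    min_usable_fraction: float = 0.9,
) -> pd.DataFrame:
    """Rate-vs-window experiment: one CV per (window, feature set, strategy).

    Returns a tidy frame with one row per repetition per cell (columns:
    window, feature_set, strategy, repetition, rate, mean, sd,
    n_excluded).  Splits are shared across feature sets at equal seeds, so
    feature-set comparisons are paired.  A window usable for fewer than
    ``min_usable_fraction`` of trials is a configuration error.
    """
    if len(T_grid) == 0:
        raise ConfigError("empty T grid")
    rows = []
    for window in T_grid:
        for fs in feature_sets:
            fm, excluded = feature_table(trials, fs, window, params, n)
            if fm.n_trials < min_usable_fraction * len(trials):
                raise ConfigError(
                    f"window {window!r} usable for only {fm.n_trials}/{len(trials)} trials"
                )
            for strategy in strategies:
                spec = CVSpec(strategy=strategy, repetitions=repetitions, seed=seed)
                res = run_cv(fm, spec, hyper)
                for rep, rate in enumerate(res.rates):
                    rows.append(
                        {
                            "window": str(window),
                            "feature_set": fs,
                            "strategy": strategy,
                            "repetition": rep,
                            "rate": rate,
                            "mean": res.mean,
                            "sd": res.sd,
                            "n_excluded": excluded,
                        }
                    )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """One row per (window, feature_set, strategy) with mean and SD."""
    return (
        results.groupby(["window", "feature_set", "strategy"], sort=False)["rate"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"std": "sd", "count": "repetitions"})
    )
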