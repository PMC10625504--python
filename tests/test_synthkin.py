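"""Generator contracts: determinism, design balance, null mode, and the
programmed weight and start-position effects."""

import numpy as np
import pytest
from scipy import stats

from kinloadclass import synthkin
from kinloadclass.evaluate import build_segments, peak_vertical_velocity
from kinloadclass.features import segment_features
from kinloadclass.synthkin import Condition, ConfigError, GeneratorConfig


def _clean_config(**kw):
    kw.setdefault("noise_sd_angle_deg", 0.0)
    kw.setdefault("noise_sd_pos_m", 0.0)
    kw.setdefault("missing_rate", 0.0)
    return GeneratorConfig(**kw)


class TestPersonParams:
    def test_deterministic_in_seed_and_id(self):
        cfg = GeneratorConfig(seed=1)
        a = synthkin.sample_person_params(cfg, 0)
        b = synthkin.sample_person_params(cfg, 0)
        assert np.array_equal(a.baseline_coeffs, b.baseline_coeffs)
        assert a.amplitude_scale == b.amplitude_scale
        assert a.duration_bias_ms == b.duration_bias_ms

    def test_different_persons_differ(self):
        cfg = GeneratorConfig(seed=1)
        a = synthkin.sample_person_params(cfg, 0)
        b = synthkin.sample_person_params(cfg, 1)
        assert not np.array_equal(a.baseline_coeffs, b.baseline_coeffs)

    def test_zero_person_sd_shares_baseline(self):
        cfg = GeneratorConfig(seed=1, person_sd=0.0)
        coeffs = [synthkin.sample_person_params(cfg, p).baseline_coeffs
                  for p in range(cfg.n_persons)]
        for c in coeffs[1:]:
            assert np.array_equal(c, coeffs[0])

    def test_out_of_range_person(self):
        with pytest.raises(IndexError):
            synthkin.sample_person_params(GeneratorConfig(), 12)

    def test_person_clustering_dominates_trial_variance(self):
        """Between-person variance of the leading fitted coefficient exceeds
        the within-person trial variance (trajectory shapes cluster by
        person), by brute-force variance decomposition over the dataset."""
        trials = synthkin.generate_dataset(GeneratorConfig(seed=2, person_sd=2.0))
        segments, _ = build_segments(trials, "angles", "full")
        a0 = np.array([segment_features(s).a[0, 0] for s in segments])
        pid = np.array([s.person_id for s in segments])
        person_means = np.array([a0[pid == p].mean() for p in np.unique(pid)])
        within = np.mean([a0[pid == p].var(ddof=1) for p in np.unique(pid)])
        between = person_means.var(ddof=1)
        assert between > within


class TestGenerateTrial:
    def test_null_mode_labels_only_differ(self):
        cfg = _clean_config(seed=3, weight_effect=0.0)
        person = synthkin.sample_person_params(cfg, 0)
        light = synthkin.generate_trial(
            person, Condition("near_table", -1, "small"), cfg, 5)
        heavy = synthkin.generate_trial(
            person, Condition("near_table", +1, "small"), cfg, 5)
        assert np.array_equal(light.angles, heavy.angles)
        assert np.array_equal(light.object_position, heavy.object_position)
        assert light.weight_class != heavy.weight_class

    def test_light_lifted_faster(self):
        """Mean per-trial max vertical velocity is strictly larger for light
        trials of one person (Monte-Carlo over 100 + 100 trials)."""
        cfg = GeneratorConfig(seed=4)
        person = synthkin.sample_person_params(cfg, 0)
        v = {wc: [] for wc in (-1, +1)}
        for wc in (-1, +1):
            for k in range(100):
                t = synthkin.generate_trial(
                    person, Condition("near_table", wc, "small"), cfg,
                    trial_seed=1000 + 2 * k + (wc + 1) // 2)
                v[wc].append(peak_vertical_velocity(t))
        assert np.mean(v[-1]) > np.mean(v[+1])

    def test_light_peak_is_earlier(self):
        cfg = _clean_config(seed=4)
        person = synthkin.sample_person_params(cfg, 0)
        peaks = {}
        for wc in (-1, +1):
            t = synthkin.generate_trial(
                person, Condition("near_table", wc, "small"), cfg, 5)
            vz = np.gradient(t.object_position[:, 2]) * cfg.sample_rate
            peaks[wc] = np.argmax(vz)
        assert peaks[-1] < peaks[+1]

    def test_far_start_has_larger_displacement(self):
        cfg = _clean_config(seed=4)
        person = synthkin.sample_person_params(cfg, 0)
        disp = {}
        for dist in ("near", "far"):
            t = synthkin.generate_trial(
                person, Condition(f"{dist}_table", -1, "small"), cfg, 5)
            start = t.object_position[0, :2]
            end = t.object_position[-1, :2]
            disp[dist] = np.linalg.norm(start - end)
        assert disp["far"] > disp["near"]

    def test_elevated_start_is_15cm_higher(self):
        cfg = _clean_config(seed=4)
        person = synthkin.sample_person_params(cfg, 0)
        z0 = {}
        for height in ("table", "elevated"):
            t = synthkin.generate_trial(
                person, Condition(f"near_{height}", -1, "small"), cfg, 5)
            z0[height] = t.object_position[0, 2]
        assert z0["elevated"] - z0["table"] == pytest.approx(0.15, abs=1e-9)

    def test_z_constant_outside_lift(self):
        cfg = _clean_config(seed=4)
        person = synthkin.sample_person_params(cfg, 0)
        t = synthkin.generate_trial(
            person, Condition("far_elevated", +1, "large"), cfg, 5)
        z = t.object_position[:, 2]
        assert np.all(np.abs(z[: t.lift_onset_true] - z[0]) <= 0.010 + 1e-12)
        assert np.all(np.abs(z[t.lift_end_true:] - z[-1]) <= 0.010 + 1e-12)

    def test_uniform_timestamps_and_channel_count(self):
        cfg = GeneratorConfig(seed=4)
        person = synthkin.sample_person_params(cfg, 0)
        t = synthkin.generate_trial(
            person, Condition("near_table", -1, "small"), cfg, 5)
        assert t.angles.shape[1] == 7
        steps = np.diff(t.timestamps_ms)
        assert np.allclose(steps, 10.0)
        lo, hi = cfg.duration_range_ms
        movement = (t.lift_end_true - t.lift_onset_true) * cfg.dt_ms
        assert movement < hi

    def test_invalid_condition_rejected(self):
        with pytest.raises(ConfigError):
            Condition("sideways", -1, "small")
        with pytest.raises(ConfigError):
            Condition("near_table", 0, "small")


class TestGenerateDataset:
    def test_minimal_design_counts(self, small_config):
        trials = synthkin.generate_dataset(small_config)
        assert len(trials) == 32
        for p in range(4):
            mine = [t for t in trials if t.person_id == p]
            assert len(mine) == 8
            cells = {(t.start_position, t.weight_class) for t in mine}
            assert len(cells) == 8  # every condition exactly once

    def test_design_balance_cells(self, study_trials, study_config):
        counts = {}
        for t in study_trials:
            counts[(t.person_id, t.start_position, t.weight_class)] = (
                counts.get((t.person_id, t.start_position, t.weight_class), 0) + 1
            )
        assert set(counts.values()) == {study_config.reps_per_condition}

    def test_bit_reproducible(self, small_config):
        a = synthkin.generate_dataset(small_config)
        b = synthkin.generate_dataset(small_config)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.angles, tb.angles, equal_nan=True)
            assert np.array_equal(ta.object_position, tb.object_position,
                                  equal_nan=True)
            assert ta.lift_onset_true == tb.lift_onset_true

    def test_inconsistent_design_raises(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(blocks_per_person=1, trials_per_block=10,
                            reps_per_condition=2)

    def test_effect_monotone_in_weight_effect(self):
        """The light-heavy gap in mean peak vertical velocity is
        non-decreasing in weight_effect (3 grid values, 240 trials each)."""
        gaps = []
        for we in (0.5, 1.0, 2.0):
            cfg = GeneratorConfig(
                seed=6, weight_effect=we, n_persons=3,
                blocks_per_person=1, trials_per_block=80,
            )
            trials = synthkin.generate_dataset(cfg)
            v = np.array([peak_vertical_velocity(t) for t in trials])
            y = np.array([t.weight_class for t in trials])
            gaps.append(v[y == -1].mean() - v[y == +1].mean())
        assert gaps[0] <= gaps[1] <= gaps[2]
        assert gaps[0] > 0

    def test_null_mode_is_statistically_null(self):
        """With weight_effect=0 a rank test on peak vertical velocity
        rejects at about its nominal alpha=0.01 rate across seeds."""
        rejections = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cfg = GeneratorConfig(
                seed=100 + seed, weight_effect=0.0, n_persons=4,
                blocks_per_person=1, trials_per_block=16,
                reps_per_condition=2,
            )
            trials = synthkin.generate_dataset(cfg)
            v = np.array([peak_vertical_velocity(t) for t in trials])
            y = np.array([t.weight_class for t in trials])
            p = stats.mannwhitneyu(v[y == -1], v[y == +1]).pvalue
            rejections += p < 0.01
        assert rejections <= 3  # binomial(25, 0.01) above 3 is ~1e-5
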