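"""Synthetic pick-up-and-replacement kinematics.

Generates per-trial multichannel kinematic time series with the statistical
structure that the downstream weight-class prediction pipeline assumes:

* a balanced within-person design (start positions x weight classes,
  repeated a fixed number of times, arranged in blocks),
* person-level clustering of trajectory shapes (each person has a canonical
  per-channel cosine-coefficient profile plus an anthropometric amplitude
  scale),
* a weight-class effect expressed as a higher and earlier peak vertical
  object velocity for light objects, a slightly shorter movement, and small
  shifts of the angle-trajectory coefficients,
* additive Gaussian measurement noise and uniformly random missing samples.

Seven upper-limb joint-angle channels (degrees) and the 3-D position of the
object's mid-point (metres, z vertical) are produced at 100 Hz.  Object
transport follows minimum-jerk segments (lift, carry, set-down); the
set-down is planned slightly below the table surface and truncated at
contact so the placement event is a crisp, detectable crossing rather than
an asymptotically flat approach.

All randomness derives from one master seed via `numpy.random.SeedSequence`
spawn keys, so datasets are bit-reproducible and extensible: adding persons
or trials never reshuffles earlier ones.  Setting ``weight_effect=0``
yields a null mode in which the light/heavy generative distributions are
identical (labels carry no kinematic information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ANGLE_CHANNELS",
    "START_POSITIONS",
    "OBJECT_SIZES",
    "WEIGHT_LIGHT",
    "WEIGHT_HEAVY",
    "ConfigError",
    "GeneratorConfig",
    "PersonParams",
    "Condition",
    "Trial",
    "sample_person_params",
    "generate_trial",
    "generate_dataset",
]

#: Fixed channel order used everywhere downstream (serialization, feature
#: stacking).  Plug-in-Gait-style right-arm angle set.
ANGLE_CHANNELS = (
    "shoulder_flex",   # shoulder flexion/extension
    "shoulder_abd",    # shoulder abduction/adduction
    "shoulder_rot",    # shoulder internal/external rotation
    "elbow_flex",      # elbow flexion/extension
    "wrist_flex",      # wrist flexion/extension
    "wrist_dev",       # wrist ulnar/radial deviation
    "wrist_rot",       # hand rotation about the forearm axis
)
N_ANGLES = len(ANGLE_CHANNELS)

START_POSITIONS = ("near_table", "near_elevated", "far_table", "far_elevated")
OBJECT_SIZES = ("small", "large")
WEIGHT_LIGHT = -1
WEIGHT_HEAVY = +1
WEIGHT_CLASSES = (WEIGHT_LIGHT, WEIGHT_HEAVY)

N_COEFF_ORDERS = 7  # cosine orders 0..6 parameterizing each angle channel


class ConfigError(ValueError):
    """Raised for inconsistent or non-physical generator configuration."""


# ---------------------------------------------------------------------------
# Geometry of the task space (metres).  The end position is fixed on the
# table in front of the participant; start positions vary in distance and in
# height (3 cm vs 18 cm above the table -> a 15 cm elevation difference).
# ---------------------------------------------------------------------------
START_XY = {"near": (0.38, 0.22), "far": (0.52, 0.38)}
START_Z = {"table": 0.03, "elevated": 0.18}
END_XY = (0.30, 0.00)
END_Z = 0.03

#: Height above the start level at which the lift becomes measurable and at
#: which the placement is considered complete — the resolution at which the
#: generator defines its ground-truth onset/end events.
EVENT_RESOLUTION_M = 0.010

#: Nominal extra lift height above max(start, end) level during transport.
LIFT_HEIGHT_M = 0.13

#: Planned set-down undershoot (m): the descent is aimed slightly below the
#: table so contact occurs with a small nonzero velocity, as in real
#: placements; z is truncated at the table level at contact.
SETDOWN_UNDERSHOOT_M = 0.012

# ---------------------------------------------------------------------------
# Movement timing (ms)
# ---------------------------------------------------------------------------
BASE_MOVEMENT_MS = 1800.0
FAR_EXTRA_MS = 130.0
WEIGHT_EXTRA_MS = 40.0       # per unit weight_effect, heavy slower
TRIAL_JITTER_MS = 180.0      # uniform +- jitter of movement duration
PRE_MOVEMENT_MS = (300.0, 500.0)   # recorded baseline before the lift
TAIL_MS = (200.0, 350.0)           # recorded tail after placement
PERSON_DURATION_SD_MS = 120.0

#: Movement-phase fractions: minimum-jerk lift, constant-height carry,
#: minimum-jerk set-down.  The lift fraction carries the weight effect
#: (light objects are lifted faster -> shorter lift phase, earlier and
#: higher velocity peak).
LIFT_FRACTION = 0.33
DESCENT_FRACTION = 0.30
LIFT_FRACTION_WEIGHT_GAIN = 0.12   # per unit weight_effect
LIFT_HEIGHT_WEIGHT_LOSS = 0.06     # heavy lifted slightly lower
LIFT_FRACTION_JITTER = 0.06
LIFT_HEIGHT_JITTER = 0.05

# ---------------------------------------------------------------------------
# Angle-trajectory model: alpha_i(t) = rest_i + sum_k C[i,k] cos(pi k s(t))
# with s the normalized movement time, and C the per-trial coefficient
# matrix (person baseline + condition shifts + motor variability).
# All values in degrees.
# ---------------------------------------------------------------------------
ANGLE_REST = np.array([25.0, 12.0, -15.0, 90.0, 15.0, 12.0, 15.0])

# canonical movement-shape coefficients, channels x orders 0..6
BASE_COEFFS = np.array([
    [18.0, -12.0,  4.0,  2.5, -1.5,  0.8, -0.4],   # shoulder_flex
    [ 8.0,  -5.0,  2.0,  1.2, -0.8,  0.4, -0.2],   # shoulder_abd
    [ 6.0,   4.0, -2.5,  1.5,  0.8, -0.5,  0.3],   # shoulder_rot
    [-15.0, 10.0, -5.0,  2.0,  1.2, -0.6,  0.3],   # elbow_flex
    [ 5.0,  -4.0,  2.5, -1.5,  0.8, -0.4,  0.2],   # wrist_flex
    [-4.0,   3.0, -1.5,  1.0, -0.5,  0.3, -0.15],  # wrist_dev
    [ 7.0,  -5.0,  3.0, -1.5,  0.9, -0.5,  0.25],  # wrist_rot
])

#: SD of the person-level deviation from BASE_COEFFS, per order (deg),
#: multiplied by ``person_sd``.  Dominates trial-level variability, which is
#: what makes trajectory shapes cluster by person.
PERSON_COEFF_SD = np.array([2.2, 1.5, 1.0, 0.65, 0.4, 0.25, 0.15])

#: SD of per-trial motor (execution) variability, per order (deg).
MOTOR_COEFF_SD = np.array([1.2, 0.9, 0.6, 0.4, 0.25, 0.15, 0.1])

#: Coefficient shift added as weight_class * weight_effect * SHIFT (deg):
#: heavy trials get the tabulated sign.  Mostly low orders, proximal
#: channels strongest.
WEIGHT_COEFF_SHIFT = 0.6 * np.array([
    [ 0.15, -0.45,  0.30, -0.15, 0.0, 0.0, 0.0],
    [ 0.10, -0.25,  0.18, -0.10, 0.0, 0.0, 0.0],
    [ 0.08,  0.20, -0.15,  0.08, 0.0, 0.0, 0.0],
    [-0.15,  0.40, -0.25,  0.12, 0.0, 0.0, 0.0],
    [ 0.05, -0.15,  0.10, -0.05, 0.0, 0.0, 0.0],
    [-0.05,  0.12, -0.08,  0.05, 0.0, 0.0, 0.0],
    [ 0.08, -0.18,  0.10, -0.05, 0.0, 0.0, 0.0],
])

#: Weight-dependent time warp of the angle trajectories (per unit
#: weight_effect): a heavy object makes the arm movement unfold more
#: slowly mid-course, a light one faster, while start and end postures are
#: unchanged.  Expressed as the peak normalized-time shift of an
#: endpoint-preserving sinusoidal warp s -> s - w sin(pi s).
ANGLE_PHASE_WEIGHT_GAIN = 0.015

#: Execution-timing variability on the same warp direction: per-trial SD
#: and per-person bias SD (x person_sd) of the peak normalized-time shift.
WARP_JITTER_SD = 0.010
PERSON_WARP_SD = 0.008

#: SD of the person-specific weight-effect deviation (deg, orders 0..3),
#: scaled by person_sd * weight_effect.  This interaction is what degrades
#: transfer to unseen persons (person-wise CV) for the angle features.
PERSON_WEIGHT_INTERACTION_SD = 0.18

#: Start-position coefficient shifts (deg), scaled by ``start_effect``.
FAR_COEFF_SHIFT = np.array([
    [6.0, -3.0, 1.0, 0.5, 0.0, 0.0, 0.0],
    [1.5, -0.8, 0.3, 0.0, 0.0, 0.0, 0.0],
    [1.0,  0.5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [-5.0, 3.0, -1.0, 0.4, 0.0, 0.0, 0.0],
    [1.0, -0.5, 0.2, 0.0, 0.0, 0.0, 0.0],
    [-0.5, 0.3, 0.0, 0.0, 0.0, 0.0, 0.0],
    [0.8, -0.4, 0.0, 0.0, 0.0, 0.0, 0.0],
])
ELEVATED_COEFF_SHIFT = np.array([
    [3.0, -2.0, 0.6, 0.0, 0.0, 0.0, 0.0],
    [4.0, -2.0, 0.8, 0.3, 0.0, 0.0, 0.0],
    [0.8,  0.4, 0.0, 0.0, 0.0, 0.0, 0.0],
    [-2.0, 1.2, -0.4, 0.0, 0.0, 0.0, 0.0],
    [0.5, -0.3, 0.0, 0.0, 0.0, 0.0, 0.0],
    [0.3, -0.2, 0.0, 0.0, 0.0, 0.0, 0.0],
    [0.5, -0.2, 0.0, 0.0, 0.0, 0.0, 0.0],
])

#: Per-person anthropometric amplitude scale SD (unitless, x person_sd).
PERSON_AMPLITUDE_SD = 0.12

#: Small object-size amplitude factor (size adds weight-independent variance
#: only).
SIZE_AMPLITUDE = {"small": 0.98, "large": 1.02}


@dataclass(frozen=True)
class GeneratorConfig:
    """Design constants and effect scales of the synthetic study.

    Defaults reproduce the study design: 12 persons x 4 blocks x 20 trials,
    i.e. 10 repetitions of each of the 8 (start position, weight class)
    cells per person, sampled at 100 Hz with movement durations clipped to
    1090–2260 ms.
    """

    n_persons: int = 12
    blocks_per_person: int = 4
    trials_per_block: int = 20
    reps_per_condition: int = 10
    sample_rate: float = 100.0
    duration_range_ms: tuple[float, float] = (1090.0, 2260.0)
    person_sd: float = 1.0
    weight_effect: float = 1.0
    start_effect: float = 1.0
    noise_sd_angle_deg: float = 0.5
    noise_sd_pos_m: float = 0.002
    missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1 or self.blocks_per_person < 1 or self.trials_per_block < 1:
            raise ConfigError("design counts must be positive")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        lo, hi = self.duration_range_ms
        if lo <= 0 or hi <= lo:
            raise ConfigError("duration_range_ms must be positive and increasing")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ConfigError("missing_rate must be in [0, 0.5)")
        if self.person_sd < 0 or self.weight_effect < 0 or self.start_effect < 0:
            raise ConfigError("effect scales must be non-negative")
        n_cells = len(START_POSITIONS) * len(WEIGHT_CLASSES)
        if self.blocks_per_person * self.trials_per_block != n_cells * self.reps_per_condition:
            raise ConfigError(
                f"blocks_per_person*trials_per_block "
                f"({self.blocks_per_person * self.trials_per_block}) must equal "
                f"{n_cells} condition cells x reps_per_condition "
                f"({n_cells * self.reps_per_condition})"
            )

    @property
    def trials_per_person(self) -> int:
        return self.blocks_per_person * self.trials_per_block

    @property
    def n_trials(self) -> int:
        return self.n_persons * self.trials_per_person

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate


@dataclass(frozen=True)
class PersonParams:
    """Person-level random effects; a pure function of (config.seed, person_id)."""

    person_id: int
    baseline_coeffs: np.ndarray        # (7 channels, 7 orders), degrees
    amplitude_scale: float             # anthropometric scale on lift height
    duration_bias_ms: float
    warp_bias: float                   # person-mean execution-timing warp
    weight_interaction: np.ndarray     # (7, 7) deg, x weight_class*weight_effect
    object_size: str                   # "small" | "large"


@dataclass(frozen=True)
class Condition:
    start_position: str
    weight_class: int
    object_size: str

    def __post_init__(self) -> None:
        if self.start_position not in START_POSITIONS:
            raise ConfigError(f"unknown start position {self.start_position!r}")
        if self.weight_class not in WEIGHT_CLASSES:
            raise ConfigError(f"weight_class must be -1 (light) or +1 (heavy)")
        if self.object_size not in OBJECT_SIZES:
            raise ConfigError(f"unknown object size {self.object_size!r}")


@dataclass
class Trial:
    """One recorded pick-up-and-replacement trial.

    ``lift_onset_true`` / ``lift_end_true`` are generator-only ground truth:
    the first noise-free sample where object z exceeds its start level by
    the event resolution (10 mm), and the first noise-free sample from
    which z stays within that resolution of its final (placed) value.
    """

    person_id: int
    object_size: str
    weight_class: int
    start_position: str
    timestamps_ms: np.ndarray          # (n,), uniform dt
    angles: np.ndarray                 # (n, 7) degrees, NaN = missing
    object_position: np.ndarray        # (n, 3) metres, z vertical, NaN = missing
    lift_onset_true: int
    lift_end_true: int
    trial_index: int = 0               # within person
    block: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.timestamps_ms)


def _person_rng(config: GeneratorConfig, person_id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1, person_id))
    )


def _trial_rng(config: GeneratorConfig, person_id: int, trial_seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2, person_id, trial_seed))
    )


def sample_person_params(config: GeneratorConfig, person_id: int) -> PersonParams:
    """Draw a person's canonical trajectory shape and anthropometric factors.

    Deterministic in (config.seed, person_id); object size alternates so
    half the persons use the small object and half the large one.
    """
    if not 0 <= person_id < config.n_persons:
        raise IndexError(f"person_id {person_id} out of range [0, {config.n_persons})")
    rng = _person_rng(config, person_id)
    baseline = BASE_COEFFS + config.person_sd * PERSON_COEFF_SD * rng.standard_normal(
        (N_ANGLES, N_COEFF_ORDERS)
    )
    amplitude = float(
        np.exp(config.person_sd * PERSON_AMPLITUDE_SD * rng.standard_normal())
    )
    duration_bias = float(config.person_sd * PERSON_DURATION_SD_MS * rng.standard_normal())
    warp_bias = float(config.person_sd * PERSON_WARP_SD * rng.standard_normal())
    interaction = np.zeros((N_ANGLES, N_COEFF_ORDERS))
    interaction[:, :4] = (
        config.person_sd
        * PERSON_WEIGHT_INTERACTION_SD
        * rng.standard_normal((N_ANGLES, 4))
    )
    size = OBJECT_SIZES[0] if person_id < (config.n_persons + 1) // 2 else OBJECT_SIZES[1]
    return PersonParams(
        person_id=person_id,
        baseline_coeffs=baseline,
        amplitude_scale=amplitude,
        duration_bias_ms=duration_bias,
        warp_bias=warp_bias,
        weight_interaction=interaction,
        object_size=size,
    )


def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1] (0 -> 1, zero end velocities)."""
    s = np.clip(s, 0.0, 1.0)
    return 10.0 * s**3 - 15.0 * s**4 + 6.0 * s**5


def generate_trial(
    person: PersonParams,
    condition: Condition,
    config: GeneratorConfig,
    trial_seed: int,
) -> Trial:
    """Simulate one trial of the given person under the given condition.

    The label enters only through deterministic effect terms scaled by
    ``config.weight_effect``; the random draws are consumed in a fixed,
    label-independent order, so at ``weight_effect=0`` a light and a heavy
    trial with the same ``trial_seed`` are sample-for-sample identical.
    """
    rng = _trial_rng(config, person.person_id, trial_seed)
    wc = float(condition.weight_class)
    we = config.weight_effect
    dist, height = condition.start_position.split("_")

    # --- timing (fixed draw order) ---
    pre_ms = rng.uniform(*PRE_MOVEMENT_MS)
    tail_ms = rng.uniform(*TAIL_MS)
    duration_jitter = rng.uniform(-TRIAL_JITTER_MS, TRIAL_JITTER_MS)
    lift_frac_jitter = rng.standard_normal()
    lift_height_jitter = rng.standard_normal()
    warp_jitter = rng.standard_normal()
    motor = MOTOR_COEFF_SD * rng.standard_normal((N_ANGLES, N_COEFF_ORDERS))

    movement_ms = (
        BASE_MOVEMENT_MS
        + person.duration_bias_ms
        + (FAR_EXTRA_MS * config.start_effect if dist == "far" else 0.0)
        + WEIGHT_EXTRA_MS * we * wc
        + duration_jitter
    )
    movement_ms = float(np.clip(movement_ms, *config.duration_range_ms))

    dt = config.dt_ms
    n = int(round((pre_ms + movement_ms + tail_ms) / dt)) + 1
    t_ms = np.arange(n) * dt
    s = np.clip((t_ms - pre_ms) / movement_ms, 0.0, 1.0)

    # --- object trajectory (noise-free) ---
    x0, y0 = START_XY[dist]
    z0 = START_Z[height]
    xe, ye = END_XY

    lift_frac = LIFT_FRACTION * (1.0 + LIFT_FRACTION_WEIGHT_GAIN * we * wc)
    lift_frac *= 1.0 + LIFT_FRACTION_JITTER * lift_frac_jitter
    lift_frac = float(np.clip(lift_frac, 0.15, 0.50))
    desc_frac = DESCENT_FRACTION
    s1, s2 = lift_frac, 1.0 - desc_frac

    h = (
        LIFT_HEIGHT_M
        * person.amplitude_scale
        * SIZE_AMPLITUDE[condition.object_size]
        * (1.0 - LIFT_HEIGHT_WEIGHT_LOSS * we * wc)
        * (1.0 + LIFT_HEIGHT_JITTER * lift_height_jitter)
    )
    h = max(h, 0.05)
    z_carry = max(z0, END_Z) + h
    z_target = END_Z - SETDOWN_UNDERSHOOT_M

    z = np.empty(n)
    lift = s <= s1
    carry = (s > s1) & (s < s2)
    desc = s >= s2
    z[lift] = z0 + (z_carry - z0) * _minimum_jerk(s[lift] / s1)
    z[carry] = z_carry
    z[desc] = z_carry + (z_target - z_carry) * _minimum_jerk((s[desc] - s2) / desc_frac)
    np.maximum(z, END_Z, out=z)  # truncate planned undershoot at table contact

    x = x0 + (xe - x0) * _minimum_jerk(s)
    y = y0 + (ye - y0) * _minimum_jerk(s)
    pos_clean = np.column_stack([x, y, z])

    # --- ground-truth events at measurement resolution ---
    above = z > z0 + EVENT_RESOLUTION_M
    if not above.any():
        raise ConfigError("generated lift never exceeds the event resolution")
    onset_true = int(np.argmax(above))
    outside = np.abs(z - END_Z) > EVENT_RESOLUTION_M
    end_true = int(n - 1 - np.argmax(outside[::-1]) + 1)
    end_true = min(end_true, n - 1)

    # --- angle trajectories ---
    coeffs = (
        person.baseline_coeffs
        + config.start_effect
        * ((FAR_COEFF_SHIFT if dist == "far" else 0.0)
           + (ELEVATED_COEFF_SHIFT if height == "elevated" else 0.0))
        + wc * we * (WEIGHT_COEFF_SHIFT + person.weight_interaction)
        + motor
    )
    warp = (
        ANGLE_PHASE_WEIGHT_GAIN * we * wc
        + person.warp_bias
        + WARP_JITTER_SD * warp_jitter
    )
    s_angle = np.clip(s - warp * np.sin(np.pi * s), 0.0, 1.0)
    basis = np.cos(np.pi * np.outer(s_angle, np.arange(N_COEFF_ORDERS)))  # (n, 7)
    angles_clean = ANGLE_REST + basis @ coeffs.T                     # (n, 7)

    # --- measurement noise and missing samples (fixed draw order) ---
    angles = angles_clean + config.noise_sd_angle_deg * rng.standard_normal((n, N_ANGLES))
    pos = pos_clean + config.noise_sd_pos_m * rng.standard_normal((n, 3))
    if config.missing_rate > 0:
        miss = rng.random((n, N_ANGLES + 3)) < config.missing_rate
        angles[miss[:, :N_ANGLES]] = np.nan
        pos[miss[:, N_ANGLES:]] = np.nan

    return Trial(
        person_id=person.person_id,
        object_size=condition.object_size,
        weight_class=condition.weight_class,
        start_position=condition.start_position,
        timestamps_ms=t_ms,
        angles=angles,
        object_position=pos,
        lift_onset_true=onset_true,
        lift_end_true=end_true,
    )


def generate_dataset(config: GeneratorConfig) -> list[Trial]:
    """Generate the full balanced dataset.

    Per person, each (start position, weight class) cell appears exactly
    ``reps_per_condition`` times, pseudo-randomized across the person's
    blocks with a person-specific seeded shuffle.
    """
    trials: list[Trial] = []
    for pid in range(config.n_persons):
        person = sample_person_params(config, pid)
        cells = [
            (sp, wcl)
            for sp in START_POSITIONS
            for wcl in WEIGHT_CLASSES
            for _ in range(config.reps_per_condition)
        ]
        order_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(3, pid))
        )
        order_rng.shuffle(cells)
        for idx, (sp, wcl) in enumerate(cells):
            cond = Condition(start_position=sp, weight_class=wcl,
                             object_size=person.object_size)
            trial = generate_trial(person, cond, config, trial_seed=idx)
            trial.trial_index = idx
            trial.block = idx // config.trials_per_block
            trials.append(trial)
    return trials


def null_config(**overrides) -> GeneratorConfig:
    """Default design with the weight effect switched off (negative control)."""
    overrides.setdefault("weight_effect", 0.0)
    return GeneratorConfig(**overrides)
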