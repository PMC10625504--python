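# Methods

## The prediction pipeline

The quantity of interest is the binary weight class (light = −1,
heavy = +1) of an object in a pick-up-and-replacement trial, predicted
from either the 7 right-arm joint-angle time series or the 3 components
of the object's mid-point velocity.

**Cutting and windowing.** Object height defines the analysis interval.
Lift onset is the first sample exceeding the pre-movement baseline level
(mean of the first 10 samples) by a threshold; the lift end t_e is the
first sample from which the height stays within a settle tolerance of its
final value for 10 consecutive samples, where the final value is the mean
of the last 10 samples.  Both threshold and tolerance default to 10 mm —
five standard deviations of typical optical-capture position noise — so
single-sample crossing rules are robust to false triggers.  Two windows
feed the classifier: the first *T* samples after onset with the grid
normalized as (t_j − t_1)/(t_T − t_1), and the full interval onset..t_e
normalized to [0, 1].  Missing samples are interpolated linearly between
nearest observed neighbours (nearest-value extension at the edges, chosen
for determinism).  Object velocity is computed by central differences
(one-sided at the edges) without prior smoothing, because the basis fit
downstream is itself a smoother.  No preprocessing step reads the label.

**Feature compression.** Each windowed channel is projected onto the
half-period cosine basis {cos(πkt)}, k = 0..n−1, by least squares on the
segment's own normalized grid.  The half-period basis imposes no
periodicity at t = 1 and so approximates non-periodic movement traces
efficiently; n = 8 retains the visible structure of the channels while
discarding sample-level noise, and nearby choices of n do not change the
conclusions (the residual decreases monotonically in n, which the suite
checks).  Least squares at the segment grid is the normative definition
of the coefficients; because uniformly sampled trials always yield
uniform normalized grids, the implementation caches the design-matrix
pseudoinverse per (grid length, n), which is exact.  A DCT shortcut was
deliberately not used: with a truncated basis on a plain uniform grid the
DCT coefficients differ from the least-squares projection at interior
precision (the Gram matrix is only diagonal under endpoint half-weights).

**Classification.** Features of M trials form X ∈ R^{(nN)×M}; channels
are stacked in a fixed documented order (shoulder flex, abd, rot, elbow
flex, wrist flex, dev, rot; or vx, vy, vz), coefficient-major within
channel.  Standardization is per feature (row), fit on training columns
only (mean, sample SD); zero-variance features are centered and kept,
with a warning, so the feature dimension never changes silently.  The
classifier is an RBF-kernel soft-margin SVM with C = 1 and kernel scale
1/(n_features · Var) — the de-facto defaults of mainstream SVM libraries;
no inner hyperparameter tuning is performed by default (an inner-tuning
mode could be layered on, but the reported protocol does not use one).

**Cross-validation.** Both strategies repeat 10 times and report the
per-repetition test classification rate (unweighted accuracy; classes
are balanced by design), its mean and SD.

* *all-trials*: 80/20 splits stratified by the (person × start position ×
  weight class) design cell.  Stratification matters: an unstratified
  split of balanced chance-level data systematically biases the measured
  rate a few points below 50%, because the test set is the exact
  complement of the training set and a classifier leaning toward the
  training majority — globally or within a person's cluster — is
  anti-correlated with the test composition.  Each trial still enters the
  test set with probability 0.2.
* *person-wise*: the trials of 2 uniformly drawn participants are the
  test set.  Across the 10 repetitions the person pairs are sampled
  without replacement from the C(12,2) = 66 possible pairs; an exhaustive
  66-pair mode is available.

Trials too short for a given T window are excluded from that cell and
counted (never padded); a window infeasible for more than 10% of trials
is rejected as a configuration error.

**Baseline.** The universal-threshold baseline classifies by a single cut
on the per-trial maximum vertical object velocity, with the cut and its
orientation chosen by exhaustive search over midpoints of sorted adjacent
training values (optimal for a single cut).  The per-trial maximum is
taken from the n = 8 cosine reconstruction of v_z on the full window, so
it measures the movement rather than differentiated sensor noise.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: 12 persons
× 4 blocks × 20 trials, i.e. 10 repetitions of each (4 start positions ×
2 weight classes) cell per person, pseudo-randomized within person;
100 Hz sampling; object start positions varying in distance and in height
(3 cm vs 18 cm above the table, a 15 cm difference); half the persons use
a small and half a large object (size adds only weight-independent
amplitude variance).

**Object transport** follows minimum-jerk segments: a lift to carry
height, a constant-height carry, and a set-down aimed 12 mm below the
table and truncated at contact — so placement is a crisp crossing with
nonzero contact velocity, as in real set-downs, rather than an
asymptotically flat approach.  Ground-truth lift events are defined at
the 10 mm measurement resolution: onset = first noise-free sample more
than 10 mm above the start level, end = first noise-free sample from
which height stays within 10 mm of its final value.

**Angle trajectories** are truncated cosine series (orders 0–6) in
normalized movement time: a fixed canonical shape per channel, plus a
person-level deviation (SD 2.2° at order 0, decaying with order — the
dominant variance component, which makes trajectories cluster by person),
plus start-position shifts, plus per-trial motor variability (SD 1.2° at
order 0).

**The weight effect** (scaled by `weight_effect`, default 1; 0 = null
mode) has three signatures:

1. *velocity magnitude*: the lift phase is 12% shorter and the lift 6%
   higher per unit effect for light objects, so their expected peak
   vertical velocity is higher (≈0.43 vs 0.35 m/s at defaults) and
   occurs earlier;
2. *timing*: heavy trials last ~40 ms longer;
3. *angle shape*: small common coefficient shifts (0.1–0.3°) plus an
   endpoint-preserving sinusoidal time warp s → s − w·sin(πs) of the
   angle channels (w = 0.015 per unit effect; heavy unfolds more slowly
   mid-movement, start and end postures unchanged).  The warp direction
   also carries execution-timing noise (per-trial SD 0.010, per-person
   bias SD 0.008) so the weight signature competes with natural timing
   variability, and a per-person random component of the coefficient
   shift (SD 0.18°) limits transfer to unseen persons — the mechanism
   behind the all-trials vs person-wise gap for angle features.

Movement durations are 1800 ms ± person bias (SD 120 ms) ± trial jitter
(±180 ms), +130 ms for far starts, clipped to 1090–2260 ms; with
300–500 ms recorded baseline before the lift and 200–350 ms tail after
placement.  The detected cut lengths come out near 160 samples on
average.  Measurement noise is additive white Gaussian, SD 0.5°
(angles) and 2 mm (positions) — typical optical-capture magnitudes — and
samples are dropped uniformly at random (default 0.5%) to exercise the
interpolation path.

Effect magnitudes were fixed once, from motor-control plausibility, so
that the default dataset reproduces the qualitative regime the pipeline
is meant to exhibit: velocity features outperform angle features at every
window; all-trials CV overstates accuracy relative to person-wise CV for
angle features; a universal velocity threshold reaches roughly 60–80%
while the SVM on the same split reaches ~95%; and the null mode is
indistinguishable from chance.

**Seeding.** One master seed; person-level and trial-level generators are
derived through `SeedSequence` spawn keys, so datasets are bit-reproducible
and extensible without reshuffling earlier trials.  All label-independent
random draws are consumed in a fixed order, so with `weight_effect=0` a
light and a heavy trial with equal seeds are sample-for-sample identical
— the null mode is exact, not approximate.

## What the synthetic data does and does not show

Passing tests establish that the pipeline recovers programmed effects of
realistic magnitude under realistic noise, that its accounting (splits,
standardization, exclusions) is leakage-free, and that it reports chance
when there is nothing to find.  They do not establish accuracy values for
real human movement: real angle trajectories are not low-order cosine
series, real inter-person variability is richer than a coefficient
perturbation plus a time warp, and real weight effects need not decompose
into the three programmed signatures.  Absolute rates on the synthetic
data are properties of the generator's chosen effect sizes and should not
be quoted as expected performance on motion-capture recordings.

## Numerical choices and degenerate inputs

* Sample indexing is 0-based; first-T windows cover samples
  onset..onset+T−1 and full windows onset..t_e inclusive, both including
  the normalized endpoint 1.
* Interpolation requires ≥2 observed samples per channel; trials below
  that are unusable.  Flat height series raise "no lift detected";
  non-settling series raise "no placement detected"; both lead to logged
  exclusion.
* The cosine fit requires at least n samples and a full-rank design; a
  degenerate grid raises a diagnostic error rather than returning a
  minimum-norm solution.
* Ties in the baseline's threshold search resolve to the lowest cut with
  the light-above orientation first; an all-equal training vector falls
  back to the majority class with a warning.
* A single-class training split (possible only in tiny designs) is
  resplit with the next derived seed, with a logged warning; person-wise
  splits cannot be resplit and raise instead.
* Mean trial counts, window grids (default T ∈ {30, 50, 70, 100, 130,
  160} samples plus "full") and repetition counts are configuration
  parameters; the defaults match the emulated design.  The acceptance
  script and test suite run the full 960-trial design; a handful of
  checks use reduced designs (e.g. 4 persons × 16 trials) purely because
  the properties they test are size-independent.
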