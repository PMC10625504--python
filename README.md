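# kinloadclass

Predicting the weight class of a manipulated object from movement
kinematics.

When a person picks up and replaces an object, the object's weight shapes
their movement: light objects are lifted faster and with an earlier peak
vertical velocity, and the unfolding of the arm's joint-angle trajectories
shifts subtly.  This package implements a classification pipeline that
exploits those signatures, for researchers in motor control and
human–robot interaction who want to probe how early and how reliably an
observer (human or robot) could infer object weight from watching a
movement — together with a synthetic motion-capture generator that
emulates the statistical structure of such an experiment (person-level
clustering of movement styles, start-position variance, and a
weight-dependent velocity profile), since no public dataset of this kind
is available.

## The method

Each trial provides N channels sampled at 100 Hz: the 7 right-arm joint
angles (shoulder flexion/abduction/rotation, elbow flexion, wrist
flexion/deviation/rotation, degrees) or the 3 components of the object's
mid-point velocity (m/s).  The trial is cut at lift onset (first rise of
object height above baseline) and either truncated to its first *T*
samples or taken up to the placement time *t_e*; the window's time axis is
normalized to [0, 1].  Each channel α_i(t) is compressed into *n* = 8
coefficients of the half-period cosine basis,

    α_i(t) ≈ Σ_{k=0}^{n−1} a_k^(i) cos(πkt),

fit by least squares, which both smooths the measurement noise and reduces
a trial to n·N numbers.  The coefficients of M trials form a feature
matrix **X** ∈ R^{(nN)×M} with labels **y** ∈ {−1, +1}^M (−1 light,
+1 heavy).  Features are standardized with a Z-transformation *fit on the
training columns only* and applied unchanged to the test columns, then
classified with a soft-margin SVM (RBF kernel, C = 1).

Two cross-validation strategies are compared, 10 repetitions each:

* **all-trials** — random stratified 80/20 splits; the same person appears
  in train and test, so person-specific movement style helps the
  classifier;
* **person-wise** — the trials of 2 held-out participants form the test
  set; measures transfer to unseen people.

A non-learning baseline — a single universal cut on each trial's peak
vertical object velocity, chosen by exhaustive search on the training
split — quantifies what the machine-learning pipeline adds.

## Worked example

```python
from kinloadclass import GeneratorConfig, generate_dataset
from kinloadclass.evaluate import CVSpec, feature_table, run_cv

trials = generate_dataset(GeneratorConfig(seed=1))     # 12 persons x 80 trials
fm, n_excluded = feature_table(trials, "object_velocity", 100)
print(fm.X.shape)                                      # (24, 960)

res = run_cv(fm, CVSpec(strategy="all_trials", repetitions=10, seed=7))
print(f"all-trials  {res.mean:.3f} +- {res.sd:.3f}")
res = run_cv(fm, CVSpec(strategy="person_wise", repetitions=10, seed=7))
print(f"person-wise {res.mean:.3f} +- {res.sd:.3f}")
```

prints

```
(24, 960)
all-trials  0.975 +- 0.011
person-wise 0.972 +- 0.014
```

i.e. the object-velocity features of the first second of the lift predict
the weight class of ~97% of held-out trials, with almost no penalty for
testing on unseen persons — interpersonal differences matter little for
object velocity.  The same protocol on the 7 joint-angle features gives
lower rates and a marked all-trials vs person-wise gap, because angle
trajectories cluster strongly by person.

The same experiment from the shell:

```sh
kinloadclass generate --out data/ --seed 1
kinloadclass run --data data/ --T 30,50,70,100,130,160,full --out results/
kinloadclass report --in results/ --plot rates.png
```

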