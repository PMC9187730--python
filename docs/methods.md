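# Methods

## The problem and the representation

Facial expressions are among the most specific behavioural indicators of
pain in cats, but scoring them (grimace scales, facial action coding)
requires trained human raters and is prone to bias. This package
implements a fully geometric alternative: each face image is reduced to
48 anatomical landmarks (2-D pixel coordinates, placed relative to the
underlying facial musculature and cat-specific facial action units), and
pain/no-pain classification is performed on a fixed-length vector derived
from those landmarks alone. Labels come from the recording timepoint of a
controlled surgical (ovariohysterectomy) protocol: images taken one hour
after surgery and before rescue analgesia are `pain`; pre-surgery and
post-rescue-analgesia images are `no_pain`.

Subjects whose images carry only one class are removed wholesale before
evaluation — a cat that appears only as `pain` (or only as `no_pain`)
contributes nothing to a subject-exclusive protocol and would bias
fold-level metrics.

## Face alignment

Pose (in-plane rotation, scale, translation) is nuisance variation. It is
removed by a similarity transform anchored on the eyes:

* eye centers are the midpoints of landmark pairs 37/38 ("left") and
  41/42 ("right"); "left/right" name landmark IDs, not anatomical sides;
* the left-eye center is mapped to `(0.4·W, 0.4·H)` of a `W×H = 1000×1000`
  output frame; the right-eye center lands equidistant from the right
  edge, at the same height;
* therefore the rotation makes the eye line exactly horizontal, the
  isotropic scale fixes the inter-eye distance at `(1 − 2·0.4)·W = 200`
  px, and the translation puts the eye midpoint at `(500, 400)`.

The transform is solved in closed form: rotation by `−atan2(Δy, Δx)` of
the eye-center difference, scale `200 / ‖Δ‖`, translation chosen so the
eye midpoint hits its target. Coincident eye centers leave the scale
undefined and raise a degenerate-geometry error. Landmarks can be aligned
without any raster; when images are present they are warped with the same
transform (bilinear resampling, black fill — the usual defaults; nothing
in the protocol constrains them).

Three properties are enforced by tests: post-alignment eye-line
horizontality below 1e-6 px, inter-eye distance exactly `0.2·W` to float
tolerance, and idempotence (re-aligning an aligned face gives the
identity to 1e-6). Together they imply the feature representation below
is invariant to any similarity pose applied to the input.

## Multi-region vectorization

Four regions motivated by the Feline Grimace Scale partition the 48
landmarks (8 / 8 / 22 / 10):

| region | members | center |
|---|---|---|
| left eye | 4 5 6 7 8 37 38 39 | midpoint(37, 38) |
| right eye | 2 9 10 11 12 40 41 42 | midpoint(41, 42) |
| nose/mouth/whiskers | 1 3 13–22 33–36 43–48 | landmark 17 |
| forehead | 23–32 | midpoint(27, 28) |

Each landmark is replaced by its offset from its region center;
concatenated in landmark-ID order (x before y) this gives the
96-dimensional multi-region vector. Ordering by landmark ID rather than
by region is a deliberate choice: it is stable under any edit of the
region scheme, and any fixed permutation of input features is equivalent
for the classifier. Vectorization removes per-region translation only;
rotation and scale are the alignment step's job, and the partition
property (disjoint, covering 1..48) is asserted at scheme construction.
Given the four centers the map is exactly invertible.

## Noise-injection augmentation

New training samples are made by multiplying every coordinate of an
original feature vector by an independent draw from Normal(mean = 1,
sd = 0.0005). Defaults add one copy per original. Two documented
ambiguities are surfaced as configuration rather than resolved silently:

* noise per coordinate (default, matching "every coordinate … by a
  sampled value") vs. one scalar per sample (`per_sample_scalar`);
* fresh noise each epoch (default, matching per-epoch augmentation in
  the training loop) vs. a single draw per fit (`resample_each_epoch`).

Augmentation is applied only to training rows, after the fold split;
the training loop owns this, so leakage into validation or test
partitions is structurally impossible.

## Classifier and training protocol

A multilayer perceptron with input width 96, hidden ReLU layers of 100,
100 and 500 units, and a softmax over {no_pain, pain}. Training: 10
epochs of Adam mini-batch steps, learning rate 0.01, batch size 32,
cross-entropy loss. On each epoch the training rows are (re-)augmented,
standard-scaled with statistics fit on those rows only, and one pass of
gradient steps is run; validation rows are scaled with the training
statistics (never their own) and the validation loss is recorded. The
returned model is the checkpoint with minimal validation loss, earliest
epoch on ties. There is no early stopping beyond this budget-plus-
checkpoint rule.

The network is scikit-learn's `MLPClassifier` driven one epoch at a time
via `partial_fit`, which makes the per-epoch scaling/augmentation and the
checkpoint explicit. scikit-learn parameterizes the binary softmax head
as a single logistic output unit — mathematically identical to a 2-unit
softmax under cross-entropy. Weight initialization and shuffling order
follow the single run seed; results are deterministic given the seed, but
weight-level reproduction of any other implementation is not expected.
Prediction ties at probability exactly 0.5 resolve to `pain`, favouring
sensitivity (the welfare-relevant error is a missed painful cat).
Constant features get their scale replaced by 1 so scaling never divides
by zero.

## Evaluation

Leave-one-subject-out cross-validation with strict subject exclusivity:
each cat is the sole test subject exactly once; a fixed number of
validation subjects (default 6) is drawn seeded from the remainder
(per-fold seed = base seed + fold index, since the draw rule is otherwise
unconstrained); the rest train. At the canonical 26 subjects this is the
19/6/1 split. Metrics per fold, with `pain` positive:
`accuracy = (TP+TN)/total`, `precision = TP/(TP+FP)`,
`recall = TP/(TP+FN)`. Aggregates are the unweighted mean and sample
standard deviation (ddof = 1) across folds; pooled-confusion metrics are
reported alongside for transparency. Folds with an undefined metric
(zero denominator) are excluded from that metric's aggregate with a
logged count.

The standard FP/FN convention is used throughout (FP = no-pain image
predicted pain). Any verbal definition that swaps them is incompatible
with the precision/recall formulas above and is not followed.

## Synthetic data generator

The study's surgical footage cannot ship with a package, so tests and
demonstrations run on generated landmark data that reproduces the
statistical skeleton the pipeline assumes. Coordinates start from a
frozen 48-point template face (nominal 500×500 frame, version 1) whose
landmark roles match the region scheme. A pain image differs from a
no-pain image by a fixed deformation field scaled by `effect_size`:
eyelid landmarks move toward their eye center (eye narrowing), forehead
and ear landmarks drift laterally and downward (ear flattening), muzzle
landmarks tighten toward the nose tip — the displacement directions a
grimace scale codes. The field is unit-normalized per landmark, so
`effect_size` is the displacement in template pixels and the deformation
is exactly linear in it.

Per subject, a persistent Normal(0, `subject_sd`) offset of all 48
landmarks models facial idiosyncrasy; it is class-independent, so the
deformation field is the *only* class signal and chance-level accuracy at
`effect_size = 0` is a designed ground truth. Per image, Normal(0,
`obs_sd`) jitter models annotation noise, and a random similarity pose
(rotation, scale, translation) is applied to the whole landmark set.
Timepoints are assigned so labels follow the standard rule, with no-pain
images alternating between the two no-pain timepoints; optional
single-class subjects exercise the completeness filter.

Defaults, chosen once as a plausible regime for landmark data of this
kind: 26 subjects × 9 images per class (468 samples, mirroring the
464-image scale of a real study), `effect_size` 3 px against
`subject_sd` 2 px and `obs_sd` 1 px (pain displacement comparable to
inter-individual variation, annotation jitter smaller than both), pose
rotation ±25°, scale 0.8–1.2, translation ±50 px.

What the generator does *not* emulate: out-of-plane head rotation,
occlusion and landmark placement failure, breed/age/sex morphology
differences, correlated (non-isotropic) annotation error, and any
image-texture information. Passing tests therefore show the pipeline's
machinery is correct and recovers planted geometric signal under
realistic nuisance — not that real cat pain is classified at any
particular accuracy.

## Problem sizes and numerical choices

The full evaluation used in tests runs 26 folds on 468 samples and
completes in well under a minute per configuration on a single CPU; the
directional alignment comparison uses 10-subject datasets (10 folds)
paired across three seeds, a scarce-data regime in which pose cannot be
compensated by sheer data volume. At the default 26 subjects and
`effect_size` 3 the synthetic task is nearly saturated (accuracy ≈ 1.0
with or without alignment), so the benefit of alignment is demonstrated
where it is identifiable.

Other numerical choices: tolerances of 1e-6 px on alignment invariants
and pose-invariance of features (float64 arithmetic on ~1000 px
coordinates leaves ample margin); scaler guard threshold 1e-12;
aggregate dispersion is the sample standard deviation; fold validation
draws and all noise go through `numpy.random.default_rng` seeded
explicitly, so every result in a report is reproducible from the
recorded seeds and config hash.

## Known limitations

* Landmarks are inputs: automatic landmark detection on raw images is
  out of scope, as is the image-based deep-learning route.
* The MLP is deliberately small and the training budget fixed; no
  hyperparameter search is performed or supported.
* Class balancing is available as an explicit seeded operation but is not
  enforced; the completeness filter alone does not balance classes.
* Image warping supports in-plane similarity only; faces photographed at
  substantial out-of-plane angles violate the alignment model.
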