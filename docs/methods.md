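# Methods

This note documents the models, conventions and numerical choices behind
behavframe, what the synthetic data does and does not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Rasterization of event annotations

Annotation events are labeled half-open intervals `[start_s, end_s)` on a
channel (posture or intensity) of one video. Rasterization projects them
onto the 0-based second grid `[i, i+1)`:

* the **primary label** of a second is the code covering the strictly
  largest fraction of it; coverage by multiple events of the same code is
  summed;
* an exact 50/50 coverage tie is broken toward the **earlier-starting
  event** (then alphabetically), which is deterministic and stable under
  event reordering;
* a second is a **transition** when more than one distinct code intersects
  it with positive overlap on either channel (each `SecondRecord` carries
  one flag covering both channels);
* uncovered seconds receive the sentinel `unlabeled` and are excluded from
  class distributions and training by default — real logs are trimmed at
  session edges, so gaps are expected rather than fatal;
* interval arithmetic uses a 1 ns tolerance, so touching events do not
  register as overlapping.

Transition seconds count toward their primary label in all class
distributions; they are not excluded.

The on-disk event dialect is a minimal CSV
(`video_id,channel,label,start_s,end_s`, decimal seconds from video
start). Native exports of commercial annotation software are out of
scope; any tool's export can be reshaped to this dialect, and a column
mapping can be supplied at parse time.

## Taxonomies

T1 (sedentary vs. active) and T2 (activity type) read the posture channel:
sitting/reclining and lying down are sedentary; under T2, walk and
walk-with-load map to walking, running to running, and every other posture
or whole-body movement (standing, biking, stairs, stretching, strength and
sport movements, ...) to mixed movement. T3 reads the intensity channel
verbatim: the MET cutoffs (light < 3, moderate 3–5.99, vigorous ≥ 6)
govern the human annotation, not any computation here. Custom taxonomies
load from YAML (class list + code→class rule).

## Fold assignment

Whole videos are assigned to training/testing/evaluation folds because
consecutive frames of one video are visual near-duplicates: frame-level
splits let a classifier score well by memorization, not generalization.

A candidate assignment is scored by `Σ_fold w_fold · D(fold, pooled)` with
`D` the histogram χ² distance `½Σ(pᵢ−qᵢ)²/(pᵢ+qᵢ)` on class proportions
(symmetric, 0 iff equal proportions, 1 for disjoint one-hot supports).
Fold weights default to the target fractions (0.8, 0.1, 0.1): distribution
match matters most where most of the data lives. A Pearson
goodness-of-fit variant is provided for comparison; both are configurable.

Feasibility requires: no empty fold; every class present in at least
3 videos appears in every fold (classes in fewer videos cannot cover three
folds and are exempt); each fold's frame share within ±5 percentage points
(configurable) of its target. Tie-breaking on equal scores is the
lexicographically smallest fold tuple over sorted video ids, making the
optimizer fully deterministic.

Exhaustive enumeration covers all 3^N assignments up to a configurable cap
(default 3^12); beyond that a seeded random search draws assignments with
per-video fold probabilities equal to the target fractions and keeps the
best feasible draw. Random search can never beat the exhaustive optimum,
which the test suite verifies against an independent brute-force
enumeration.

## Frame preparation

One representative frame per labeled second, sampled at the second's
midpoint — the point maximally distant from boundary transitions; a higher
sampling rate subdivides the second uniformly. Letterboxing scales the
long edge to the target (224 or 384), rounds the short edge to the nearest
integer (≥ 1), centers the content and fills the rest with exactly the pad
value (black). Augmentations, applied with a caller-supplied seeded
generator: horizontal flip (p = 0.5), lightness scaling uniform in
[0.9, 1.1] applied on the HLS lightness channel with clipping (p = 0.5),
and a random crop retaining a uniform 80–100 % of the area at the input
aspect ratio, resized back (p = 0.5). All parameters are configurable;
centered padding and HLS lightness are conventions chosen here and
documented rather than mandated by any standard.

## Classification

The reference backend is gradient-boosted trees over pose-keypoint
features: 17 landmarks × (x, y, confidence), normalized to the unit
square, flattened to 51 features. Frames without a detected person carry
an all-zero vector and a `person_found` flag; they are kept in training so
the model can learn a "no person" response. Real skeletal extractors run
externally and enter via precomputed feature CSVs or the extractor
registry; the built-in `blob` extractor handles the synthetic stick-figure
frames only. Deep image backbones are registered as explicit stubs: their
value is pre-trained weights plus GPU fine-tuning, which this package does
not ship.

Training uses booster library defaults plus a fixed seed and a single
thread (`max_depth` 6, `eta` 0.3, softmax-probability objective), all
overridable in `ClassifierConfig`. Early stopping records the
testing-fold selection metric — averaged one-vs-rest AUC by default,
accuracy optionally — after every boosting round and stops after 10 rounds
without improvement, reverting to the best round. Because boosting is
additive (round t is independent of later rounds), the implementation
fits the maximum number of rounds once and truncates at the best round,
which is mathematically identical to halting the loop and keeps the full
per-round history in the model metadata. The returned model's test metric
at the best round therefore dominates every later recorded round by
construction.

A leakage audit runs inside `train_classifier` and again in the pipeline:
it tallies training rows by the fold of their source video and raises if
any row originates outside the training fold.

## Evaluation

Confusion matrices have true labels on rows. Precision is TP/(TP+FP)
(defined as 0 and flagged for never-predicted classes), recall
TP/(TP+FN), F1 their harmonic mean. Weighted aggregates are
support-weighted, under which weighted recall equals overall accuracy
identically — this is deliberate: alternative "weighted recall"
conventions that break this identity are not reproducible from a count
matrix alone, so the standard definition is used and the identity is
asserted in tests.

ROC curves sweep the unique scores (rank-based, so uncalibrated margins
are fine); AUC is trapezoidal and equals the Mann–Whitney pair statistic,
which the tests verify by exhaustive pair counting. Multiclass AUC is
one-vs-rest with optional class weights, normalized so scaling all weights
changes nothing; down-weighting a class (e.g. multiplying by 0.06 for a
94 % suppression) handles classes whose substitute data over-represents
them. Per-class substitution replaces one class's scores and labels with
another fold's — OVR evaluation is independent per class, so substitution
cannot affect other classes; substituted classes are annotated in the
report with their source. A class with single-class data in both primary
and substitute sources is excluded with a warning. The optimal decision
point minimizes FP + FN with ties broken toward the higher threshold.

Reports print ratios at 2 decimals and percentages at 1 decimal; JSON
output keeps full precision.

### Reference matrices

Three evaluation-phase confusion matrices from a published DO video study
ship as CSV fixtures. They serve as verification inputs: the package
re-derives every printed per-class value and the overall accuracies
(87.4 %, 63.1 %, 68.6 %) from raw counts. Their row sums are taken as
printed, even where companion tables in the same report disagree slightly.

## Synthetic sessions

The generator emulates the statistical structure the pipeline assumes:

* **Dynamics** — a semi-Markov chain over 7 free-living posture codes;
  next code from a transition matrix with destination mass proportional to
  a mostly-sedentary prevalence profile, dwell times geometric
  (memoryless, integer, ≥ 1 s; means 6–14 s per code, rounded-exponential
  optional). Integer-aligned gap-free events guarantee that rasterizing
  the generated events reproduces the stored ground truth exactly, which
  is asserted per video.
* **Intensity channel** — derived from posture via a lookup
  (sitting→sedentary, standing→light, walk→moderate, running→vigorous, …)
  with 5 % per-dwell noise shifting one MET level, so activity-type and
  intensity labels co-vary as in real behavior.
* **Imbalance** — per-video Dirichlet tilts of the transition matrix and
  heterogeneous durations.
* **Pose features** — class-conditional Gaussians in the unit square;
  class means use fixed sign patterns offset by `separation·σ/2` per
  coordinate (default separation 4, σ = 0.05), giving nearly separable
  clusters; confidences sit near 0.92.
* **Frames** — stick figures whose geometry is class-dependent (sedentary
  figures compact and low, locomotion tall, running leaning) with 5 %
  geometry jitter and pixel noise, for exercising letterboxing and the
  extractor interface.

What it does **not** emulate: camera motion, lighting, occlusion,
multi-person scenes, annotator disagreement beyond the one-level intensity
noise, or any visual realism. Passing tests therefore demonstrate that
the pipeline machinery is correct and honest (no leakage, correct
arithmetic, calibrated chance level), not that any particular accuracy is
attainable on real video.

### Benchmark fixture and problem sizes

The fixed benchmark is 6 videos of 400/300/100/60/50/50 s (960 labeled
seconds — small enough that the whole suite runs in well under a minute on
one CPU, large enough for every constraint to bind). Running is confined
to exactly 2 videos to exercise the rare-class exemption; every video
opens with one sedentary, one standing and one walking dwell so the common
classes appear everywhere and a feasible 80/10/10 assignment (e.g. frame
shares 0.833/0.115/0.052) exists by construction for every seed.

The chance-level control (shuffled labels → OVR AUC ≈ 0.5) uses a 10×
scaled version of this fixture (9 600 s) and averages three independent
shuffles: with ~1 000 evaluation frames the averaged null AUC has a
standard error near 0.015, so the ±0.05 acceptance band is a ≳3σ check
rather than a coin flip.

## Known limitations

* Fold assignment is per video; subject-level grouping (several videos of
  one person) is a realistic extension not implemented.
* Exhaustive fold search is exponential; beyond the cap only the seeded
  random search is available, which is approximate.
* The blob pose extractor is a geometric stand-in for a real skeletal
  model and is only meaningful on the synthetic renderer's output.
* Intensity-channel noise can scatter tiny slivers of a rare intensity
  class across many videos, making the every-fold presence constraint
  unsatisfiable for that taxonomy on small fixtures; the optimizer then
  reports the binding constraints rather than silently relaxing them.
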