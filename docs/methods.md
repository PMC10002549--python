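# Methods

This note documents the models, parameter choices and numerical
conventions behind `retinacoach`, and what the desk-scale tests do and do
not demonstrate.

## Taxonomy and curation

The condition taxonomy ships as a versioned CSV
(`src/retinacoach/data/taxonomy.csv`): 39 fine classes `C0`–`C38`, a
`retained` flag for the 22 classes that survive the small-class filter, an
`allocation_level` flag for the 19 retinal conditions (RCs) used for case
allocation (the four diabetic-retinopathy stages `C2`–`C5` collapse into
`DR` because one source dataset annotates DR as a single class), a
`supplementary_rare` flag for the 17 removed classes, and the topic
partition `T1`–`T6`. Tessellated fundus (`C9`) sits under the "Normal"
topic by design of the published topic table, even though it is a distinct
condition.

**Retention threshold.** The filter retains a class iff its total image
count is ≥ 50. The sources describing the filter disagree between "more
than 50" and "fewer than 50 removed"; we adopt retain-iff-≥ 50, which the
published per-class supports are consistent with (the smallest retained
class has 57 images, and one class has exactly 50 training images). The
threshold is exposed as `min_count`. The filter is applied to total
(train + test) counts. A side observation: the published per-class
supports sum to 9193 while the stated image total is 9693; nothing in this
package depends on that difference.

**Label mapping.** Raw labels match mapping rules exactly after
lowercasing and whitespace normalisation; the rule table enumerates every
published keyword variant (e.g. three epiretinal-membrane phrasings)
rather than using substring heuristics. Rows with no mapped label are
excluded — an image must belong to at least one selected class.

**Split.** The split procedure in the original work is not stated, only
the resulting counts, so we use greedy iterative multilabel
stratification (rarest label first, each image to the split with the
largest remaining per-label demand, ties by overall demand then a seeded
coin). No installed library provides multilabel stratification, so it is
implemented here; 100 single-label images at fraction 0.8 split exactly
80/20, and every retained class reaches the test set at realistic sizes.

**Synthetic source tables.** The generator's default class weights are
the published per-class supports; co-occurrence defaults to 0.15
(secondary label drawn from the same marginal), the single-category
dialect stays single-label, and each image is attributed to a dialect
that can express its primary class. Manual bad-quality exclusions are
not algorithmically reproducible and are represented as an optional
exclusion-list file.

## Imaging

Preprocessing: near-black border rows/columns (mean intensity
< 10/255) are trimmed; the eye area is found with a circular Hough
transform over radii between a quarter and half of the short side (Canny
edges, σ = 2); the image is cropped to the circle's bounding square;
CLAHE runs on the L channel of Lab space (clip limit 0.02, ~8×8 tiles) —
applied after cropping and before resizing to 224 px, so the equalisation
window sees only retina. If no circle is found (blank or degenerate
input) the center square is cropped and a warning logged.

Augmentations are restricted to label-preserving geometry because retinal
biomarkers can appear anywhere on the fundus: scale uniform in
[0.9, 1.1], independent horizontal/vertical flips (p = 0.5 each),
rotation uniform in [−180°, 180°] (the rotation range is not stated in
the source; free rotation is safe for position-free biomarkers), and
grayscale conversion with p = 0.2 (probability likewise a package
default). All knobs are arguments; setting every probability to zero and
the ranges to identity returns the input array unchanged.

The synthetic fundus renderer draws a reddish disc, an offset optic
disc, dark vessel walks, and small per-class biomarkers (bright dots for
drusen-like classes, dark dots scaling with DR stage, sectoral dark
wedges for vein occlusions, an enlarged cup for glaucoma-like classes,
and so on). It deliberately emulates only coarse, linearly separable
appearance cues: it has no camera noise model, no anatomical variation,
no inter-grader ambiguity. Desk-scale classification results on it
demonstrate that the pipeline learns and routes signal correctly — not
that the model would reach any particular accuracy on real photographs.

## Contrastive classifier

The multilabel SupCon loss uses the positives-outside-log (L_out) form
with the positive set P(i) = {j ≠ i : labels_j ∩ labels_i ≠ ∅}. Anchors
with an empty positive set contribute nothing and are counted in the
training log. Temperature defaults to 0.1 and the initial learning rate
to 5e-4, the production recipe's stated values; desk-scale tests use a
larger rate (0.01) appropriate to the tiny head. Two views per image
(the raw image plus one augmented copy) are precomputed per training
run — a fixed-view approximation of per-epoch augmentation that keeps
desk-scale training under a second.

The desk-scale encoder (`tiny-pool`) is a deterministic pooled-feature
extractor: the image is resized to 64 px and four channels (R, G, B,
gray-gradient magnitude) are mean-pooled over an 8×8 grid (256
features, standardised on the training set). The projection head (dense
64 → ReLU → linear 128, L2-normalised) is trained with Adam on analytic
gradients of the loss; the gradient passes the normalisation as
dL/dh = (g − (g·z)z)/‖h‖ and is verified against finite differences in
the tests. A full-scale deep encoder is a named configuration slot
(`resnext50_32x4d`) sharing the same head and loss contract; full-scale
training and the published per-class precision/recall are out of scope
here.

Stage 2 freezes the representation and fits one logistic (sigmoid)
classifier per class on the clean-view embeddings, yielding independent
probabilities with no sum-to-one constraint; membership is p_C ≥ 0.5. A
class present in every (or no) training sample degenerates to a constant
probability.

## Difficulty

prob_difficulty treats p_C = 0.5 as predicted (membership rule p ≥ 0.5),
so the two sums partition the classes and the boundary is counted once.
The neighbor component partitions the k = 9 nearest reference images
(cosine distance, 1 − similarity; ties broken by stable reference order)
into NC (sharing at least one predicted class) and per-foreign-class
groups NC_j — a multilabel foreign neighbor counts under each of its
classes. Degenerate neighborhoods are pinned to the metric's extremes:
all neighbors share a class → −k, none do → +k, and an all-zero-distance
neighborhood returns 0 (no separation information). If the reference
holds fewer than k images, all are used with a warning.

Normalisation is global min–max over a declared calibration set (by
default the reference test-set difficulty values), with bounds persisted
to JSON so new cases score stably; out-of-range values clip. Bands use
half-open intervals on the [0, 2] total: [0, 0.5] easy, (0.5, 1.5]
medium, (1.5, 2] difficult, scored 1/3/5.

## OSCE scoring, grades and teaching files

A checklist is sections of one-point boxes; a wrong diagnosis scores 0
regardless of boxes. The exact real-valued percentage is banded with
closed upper bounds at 20/40/60/80 (29/37 = 78.4 % → 4, reproducing the
published worked example; the shipped diabetic-retinopathy template has
37 boxes). Grade = performance + difficulty, 0 stays 0, so grades lie in
{0} ∪ [2, 10] and the per-condition goal grade of 7 is attainable at
performance 4 on a medium case.

Teaching files record per-RC counts, grades and last-encounter day (a
calendar index; recency comparisons use it directly). Cases are filed
under the expert-validated condition — a misclassified presumptive label
leaves no trace. Goal 3 uses the best grade per condition (any encounter
≥ 7), matching the "until grade ≥ 7" stopping semantics of the
allocation rules; an average-grade reading was considered and rejected
as inconsistent with those rules. Virtual cases are graded identically
to real ones, including difficulty — supported by the grade-based
stopping rule for virtual assignments.

## Allocation engine

Rule priority is realised as monotone candidate-set refinement with
early exit on a singleton — the contract equivalent of salience-ordered
production rules; no rule-language runtime is reproduced. The
"assign one case of each RC" and "fewest up to 3" rules are a single
refinement step (minimum per-RC count while that minimum is below 3),
logged as r3 when the minimum is 0 and r4 otherwise, and likewise
r3v/r4v for virtual cases. Recency (r6) is applied before topic and
count loads (r7–r9), following the published rule order, although both
can discriminate. "Fewest seen cases that day" (r3b) is read as fewest
total assignments today. Remaining ties break uniformly at random from
the engine's seeded generator, and every decision logs its rule chain.

The per-resident daily cap defaults to 2 (⌈expected daily arrivals /
residents⌉ + 1 for 1000 arrivals, 240 days, 10 residents). On rare
arrival spikes where every resident is at the cap, the cap is relaxed
for that case with a warning and a `cap_relaxed` entry in the rule
chain — conservation (every real case gets exactly one examiner) is
treated as stronger than the cap. Months 1–2 are the initiation period:
no allocations, no evaluations; the engine's calendar starts at month 3.

Supplementary staging: after months 5/7/9, a resident missing goal
1/2/3 receives one extra virtual case per day (the condition chosen by
the same virtual cascade, which automatically targets the deficit).
Residents with all three goals met receive one "supplementary rare"
virtual case daily — an ungraded, difficulty-free showing of one of the
17 removed classes — until each has been seen once. Out-of-scope real
cases are examined ungraded and broadcast as ungraded virtual copies to
all other residents.

## Clinic simulator

The study conditions are the defaults: 10 residents, an expectation of
1000 patients/year arriving Poisson with mean 1000/240 per day over 240
allocation days (24-day months — the working year implied by "at least
240 patients/year" at one case per day), condition frequencies
proportional to the published test-set supports, difficulty uniform over
easy/medium/difficult, and a 5 % out-of-scope probability (not stated in
the source; chosen as a plausible clinic rate and exposed in config).

Resident behavior is deliberately simple: per-RC skill ~ N(0.5, 0.8²);
P(correct diagnosis) = logistic(1 + skill − penalty) with band penalties
0/0.7/1.4; checked-box fraction ~ Beta with mean 0.55 + 0.10·skill
(concentration 25); skill gains 0.15 per encounter with feedback and
decays 0.004 per idle day, applied lazily at the next encounter. The
`always_correct` switch models a perfect resident (diagnosis always
right, every box checked) for boundary analyses. The behavior model
exists to exercise the allocation rules; it makes no claim about real
resident learning curves.

Difficulty is sampled in simulation rather than computed from images —
the image → difficulty path has its own module and tests — and an
integrated mode can wire the classifier and difficulty scorer in for
end-to-end smoke tests via the CLI.

Problem sizes used throughout the reports and tests (240 days, 10
residents, ~1000 arrivals) complete in a few seconds; a full run emits
~2800 logged decisions.

## Known limitations

* The synthetic fundus images are linearly separable by construction;
  desk-scale accuracy does not transfer to real CFPs.
* Difficulty-band thresholds act on min–max-normalised components, so
  band assignments depend on the calibration set.
* The simulator has no waiting-room or attending-capacity model, no
  per-eye laterality, and no within-day ordering effects beyond arrival
  order.
* Fixed two-view augmentation (rather than fresh views per epoch) can
  slightly understate contrastive regularisation at larger scales.
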