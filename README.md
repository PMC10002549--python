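# retinacoach

Tooling for AI-assisted, personalised ophthalmology residency training
during the medical-retina rotation. Patients visiting a retina clinic have
a color fundus photograph (CFP) taken; a multilabel classifier proposes a
presumptive diagnosis and an automatic difficulty score; a rule-based
allocation engine then matches the case to the resident who would benefit
most from it, based on their teaching file (per-condition case counts,
OSCE grades, and recency). The package is aimed at medical-education
researchers and engineers who want to study or extend this kind of
precision-education pipeline; every component runs at desk scale from
built-in synthetic data, with no image downloads or GPUs required.

## What is inside

* **Condition taxonomy** — 39 fine CFP classes (`C0`–`C38`) merged from
  three public-dataset annotation dialects, 22 retained by a ≥ 50-image
  filter, collapsed to 19 allocation-level retinal conditions (the four
  diabetic-retinopathy stages group into `DR`), partitioned into 6
  educational topics.
* **Curation** — dialect-aware label mapping (keywords, one-hot columns,
  category names), the small-class filter, and iterative multilabel
  stratified train/test splitting, plus a synthetic source-table
  generator.
* **Imaging** — border crop, Hough-circle eye-area detection, CLAHE,
  label-preserving augmentations, and a deterministic synthetic fundus
  renderer with per-class biomarkers.
* **Contrastive classifier** — a supervised contrastive (SupCon) loss
  adapted to multilabel batches: for an anchor with class set {Cᵢ}, every
  sample sharing any class is a positive, and with unit projections z and
  temperature τ,

      L = mean over anchors i of  -(1/|P(i)|) Σ_{p∈P(i)}
          log[ exp(zᵢ·z_p/τ) / Σ_{a≠i} exp(zᵢ·z_a/τ) ]

  followed by a frozen per-class sigmoid classifier giving independent
  probabilities p_C(x).
* **Difficulty** — prob_difficulty = several + Σ_{p_C≥0.5}(1−p_C) +
  Σ_{p_C<0.5} p_C, plus a silhouette-style neighbor component
  −(|NC|·b − |NC_min|·a)/(|NC_min|·max(a,b)) over the k = 9 nearest
  reference embeddings; both normalised to [0, 1], summed, and banded
  easy/medium/difficult → score 1/3/5.
* **Teaching records** — OSCE checklist scoring (wrong diagnosis = 0;
  else 20-percent bands → performance 1–5), grade = performance +
  difficulty, per-resident teaching files, and the three educational-goal
  predicates (1, 3, and grade-≥ 7 cases per condition).
* **Allocation engine** — a forward-chaining, priority-ordered cascade
  (fewest cases of the condition up to 3 → lowest best grade below 7 →
  oldest encounter → topic load → condition load → total load → seeded
  random), with out-of-scope broadcast, daily one-case floors, staged
  supplementary virtual cases after months 5/7/9, and full decision
  tracing.
* **Clinic simulator** — Poisson arrivals (1000 patients/year over 240
  allocation days), 10 residents with logistic skill/difficulty response
  and learning/forgetting dynamics, producing coverage, fairness and
  goal-attainment reports.

## Worked example

```python
from retinacoach import SimConfig, run_year

report, decisions = run_year(SimConfig(seed=7))
print("min/max cases per resident:", report.min_total, report.max_total)
print("min encounters per (resident, condition):", report.min_rc_count)
print("min best grade per (resident, condition):", report.min_best_grade)
```

prints

```
min/max cases per resident: 276 289
min encounters per (resident, condition): 8
min best grade per (resident, condition): 7
```

i.e. over a simulated 240-day allocation period every one of the 10
residents examined at least 276 cases (the one-case-per-day floor plus
their share of ~1000 real arrivals), every resident saw every one of the
19 retinal conditions at least 8 times (comfortably above the 3-case
educational goal), and every resident reached the goal grade of ≥ 7
(performance ≥ 4 on a case of at least medium difficulty) on every
condition.

The same pipeline is scriptable from the shell:

```bash
retinacoach simulate --out-dir out/          # report + decision log
retinacoach curate --out resident.csv        # synthetic curation run
retinacoach synth-images --labels C14 --n 4 --out-dir imgs/
```

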