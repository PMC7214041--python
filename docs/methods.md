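# Methods

## The labeling model

Polar labeling treats a patient's count of a disease's diagnostic billing
code as a noisy repeated measurement of disease status. Its only
distributional assumption is that log-transformed counts of true cases and
true non-cases form *distinct but overlapping* unimodal (approximately
log-normal) distributions, with the case distribution shifted right. Under
that assumption the right tail of the pooled distribution is enriched for
true cases and the zero/one-count mass for true non-cases, so thresholding
at the poles yields labels whose purity can be traded against volume
through a single factor α.

The pole statistics are computed over *potential silver positives* (count
≥ 1) only: zero-count patients say nothing about how intensely a true case
is coded, and including them would drag the mean toward zero in proportion
to prevalence, making the high pole incomparable across diseases.

Negative balancing (step 6) subsamples the silver-negative set to
`round(|SN|·|SP|/|PSP|)`. Reading the formula's "silver set" as the
silver-*negative* set makes the balanced set's positive fraction equal
`|PSP|/(|PSP|+|SN|)`, i.e. the share of code-carrying patients in the
pole-labeled population — which is the stated purpose of the step (the
balanced set mirrors the cohort's class mix). The alternative reading
(positive ∪ negative) has no such fixed point and was rejected.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.5 | high pole at `mean + alpha·sd` of PSP log counts; larger → fewer, purer positives |
| `train_size` | 8000 | requested size of the emitted balanced silver subset |
| `log_base` | natural | base of `log(count+1)`; base10 available |
| `low_pole_cutoff` | 1.0 | low pole position on the log-normalized axis |
| `sd_mode` | population | divisor n for the PSP sd; `sample` (n−1) available |
| `strict_train_size` | false | error instead of clamp when the balanced set is smaller than `train_size` |

Numerical choices that the algorithm statement leaves open, fixed here:

- **Log base.** Natural log, matching the ubiquitous `log1p` idiom; the
  choice only rescales the axis and cancels in `mean + α·sd`, except for
  the fixed low pole (below). Configurable.
- **Low pole reading.** The 1.0 cut-off is interpreted on the
  log-normalized axis. With natural log this coincides with "count ≤ 1"
  (ln 2 ≈ 0.693 ≤ 1.0 < ln 3 ≈ 1.099); with base10 the two readings
  diverge, and the axis reading is kept.
- **Rounding of the balancing size.** Half-away-from-zero, clamped to at
  least one negative when any exist, so a training set can never silently
  become all-positive.
- **Boundary ties.** Both pole comparisons are inclusive. If a strongly
  negative α pushes the high pole at or below the low pole, positive
  assignment takes precedence and negatives are drawn from the remainder.
- **Zero variance.** A PSP set with identical log counts gets sd exactly 0
  (no floating-point dust), so the high pole coincides with the common
  value and every PSP patient is silver positive at any α.
- **Randomness.** One master seed per labeling call; the negative-balancing
  draw and the final train-size subsample consume independent sub-streams
  (`SeedSequence.spawn`), so changing the train size does not perturb which
  negatives survive balancing.
- **Degenerate cohorts.** A cohort with no count ≥ 1, or an α that no
  patient reaches, raises an empty-pole error rather than returning an
  empty label set: silence here would propagate an untrainable set.

## Classifier protocol

Random forest: 1000 trees, Gini splits; depth, features-per-split and
bootstrap at the common defaults (unlimited, sqrt, on). Logistic
regression: L2 penalty, strength selected by stratified 5-fold CV
maximizing AUROC over 9 log-spaced values `1e-4 … 1e4` (the grid is a
convention; the protocol fixes only the penalty, CV and scoring), optimizer
capped at 10 000 iterations. The solver is Newton–Cholesky, chosen because
the feature matrices are tall, thin and deliberately unscaled raw counts —
absolute counts are part of the method's contract — which conditions
first-order solvers poorly but is immaterial to exact Hessian solves.
Scores are class-1 probabilities for both families.

AUROC is the Mann–Whitney pair probability (ties one half), computed via
`sklearn.metrics.roc_auc_score` and cross-checked in the tests against an
exhaustive pairwise counter. The gold-vs-silver t-test is **paired** across
runs, since both arms share each run's validation half; an unpaired Welch
variant is available behind a flag. With fewer than two runs the t-test is
reported as not computable. The 0.05 significance threshold is echoed in
reports as metadata and gates nothing.

In the repeated-split harness the silver standard is regenerated each run
with a run-derived seed, so the run-to-run spread includes PL's own
sampling variability rather than conditioning on one fixed silver draw.
Splits are simple random halves (sizes differing by at most one) with a
redraw guard ensuring both classes appear in both halves; P/U chart labels
are excluded before splitting.

The sensitivity sweep intentionally departs from the harness: each (α,
train size) cell trains on a fresh silver standard and evaluates against
the *entire* chart-reviewed Y/N set with no splitting, since the gold
labels there serve purely as a fixed yardstick. Default grid: α from −3.0
to +3.0 in 0.5 steps and train sizes {300, 1000, 2000, 4000, 8000} — the
endpoints are the studied range; the intermediate sizes are this package's
choice. Cells whose PL step raises a domain error are recorded as
infeasible with the reason, never with a fabricated value. Per-cell seeds
derive deterministically from (master seed, α index, size index, rep), so
any cell can be recomputed in isolation.

## Synthetic cohorts

The generator emulates the features of coded hospital data that the method
depends on, with defaults describing a common chronic disease in a
general-hospital population:

- disease status ~ Bernoulli(prevalence); presets cover prevalences 0.079
  (common respiratory disease), 0.29 (very common cardiovascular disease)
  and 0.005 (rare cancer);
- case disease-code counts: rounded log-normal, log-scale mean 3.0 and sd
  1.0 (median ≈ 20 codes — a plausible multi-year coding intensity for a
  chronic disease); control counts: zero with probability 0.85, otherwise
  a rounded log-normal with log-mean 0.7 and log-sd 0.8 (median ≈ 2
  miscodes). Rounded log-normals are used precisely because the labeling
  model assumes log-normal count shapes; the overlap of the two
  distributions is what makes the middle ambiguous;
- 20 auxiliary concepts (medication-like) at Poisson rates uniform in
  0.5–3, multiplied by 3 for cases — the correlated side-channel that lets
  a classifier outperform the disease code itself;
- background diagnosis/procedure concepts fill each record toward a total
  event density of mean 1330 and sd 1902 events per patient (log-normal
  totals; the shape is an assumption, only the moments are targeted);
- chart review: a uniform sample (default 2.7% of patients) or the
  enriched scheme (100 code-positive, 365 with another diagnosis, 75 fully
  random — 540 in all); labels flip against truth with probability 0.02
  and are replaced by P/U with probability 0.03, uniformly.

What the generator does **not** emulate: visit-level timing, code
vocabularies and hierarchies, correlated miscoding (a patient whose
comorbidities inflate both the disease code and auxiliary concepts),
informative missingness, or inter-annotator disagreement. Tests passing on
these cohorts therefore show that the pipeline implements its model
correctly and that the method behaves as designed *when its distributional
premise holds* — not that it will enrich equally well on any real EHR.

## Scales used in the shipped checks

The acceptance checks and `scripts/acceptance.py` run on 20 000-patient
cohorts with a 540-patient enriched chart-review sample, 15 evaluation
splits, silver train size 4000, and 5 repetitions per sensitivity cell —
sizes at which the compared quantities are stable to well inside the
asserted margins while the whole suite stays desk-scale. The logistic arm
carries the model comparisons; the random-forest path is exercised by its
own unit tests.

## Known limitations

- PL requires absolute counts; records pooled across sites with different
  coding intensities violate the single-distribution assumption.
- Models trained on polar sets are biased toward heavily coded,
  high-utilization patients and may be insensitive to newly diagnosed ones.
- One disease per invocation; no joint multi-disease labeling.
- The t-test treats per-run AUROCs as exchangeable observations; runs share
  training data and are not independent, so p-values are descriptive.
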