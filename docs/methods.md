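# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the places where a genuinely open design choice was made.

## Synthetic multi-cohort generator

Host-response diagnostic panels are trained on compendia pooling dozens of
heterogeneous cohorts (different platforms, countries, age groups, care
settings) into three diagnostic classes: bacterial infection, viral
infection, noninfected.  The generator reproduces the statistical skeleton
of such a compendium.  For sample *s* of class *c* in cohort *g*, marker *m*:

    copies[s, m] = max(floor, 2^(b_m + δ_{c,m} + u_{g,m} + ε_s))

- `b_m ~ N(μ_b, sd_b)` — per-marker log2 baseline abundance.  Defaults
  μ_b = 10 (≈ 1024 copies) and sd_b = 1.5, spanning roughly 2.5 decades of
  baseline abundance across markers, compatible with the copy-number scale
  at which a 400-copy abundance rule is meaningful.
- `δ_{c,m}` — class effect (log2 fold change vs. the noninfected class),
  materialized from coded directions.  The source panel tables code
  direction and relative strength (↑↑, ↑, ↓, ↓↓) but not numeric
  magnitudes; the default map ↑↑ = +1.5, ↑ = +0.75 (and mirrored for down)
  is configuration chosen so that markers are clearly informative but not
  trivially separable.  Housekeeping markers have zero effect in every
  contrast, and sit exactly at the common baseline so normalization is
  stable.
- `u_{g,m} ~ N(0, 0.35)` — additive cohort batch shift per marker,
  emulating platform/site effects.  It is shared by all classes within a
  cohort, so class contrasts are unbiased within cohorts but pooled
  marginal distributions are overdispersed — the property that makes
  cohort-grouped cross-validation the right evaluation design.
- `ε ~ N(0, 0.7)` — residual log2 biological noise.  0.7 log2 units gives
  within-class coefficients of variation around 50–60%, typical of whole
  blood expression.
- `floor = 1` copy — limit-of-detection clamping.

Default design: 8 cohorts × 25 samples per class per cohort (600 samples),
with the last quarter of cohorts held out as a validation split; all sizes
are configurable.  Seeding uses one root `SeedSequence` with one spawned
substream per cohort plus one for marker-level parameters, so runs are
reproducible and cohorts are exchangeable (relabeling cohorts permutes
substreams without changing pooled distributions).

What the generator does **not** emulate: platform-specific chemistry
(probe efficiencies, amplification curves), count overdispersion families
other than log-normal, missingness, class-imbalanced cohorts with
systematically confounded batch effects, or label noise.  Tests passing on
this generator therefore demonstrate correctness of the algorithms and
their statistical calibration under a clean multiplicative-noise model, not
clinical performance on real cohorts.

`planted_design` builds studies with known ground truth: a few informative
markers with distinct effect patterns (bacterial-only, viral-only,
down-regulated, discordant), cycled so every planted marker carries
non-redundant class information, among pure-noise markers.

## Normalization

Relative quantification against reference transcripts uses the standard
geometric-mean convention on the log2 scale:

    norm[s, m] = log2(copies[s, m] + pc) − mean_h log2(copies[s, h] + pc)

with pseudocount pc = 1 copy so the transform is defined at the detection
floor.  This is invariant to per-sample global scaling as pc → 0.  The
abundance/dynamic-range screen runs on **raw copies** (the 400-copy rule is
stated in copy space); selection and classification run on normalized
values.

## Marker screen

Percentiles use linear interpolation between order statistics, pooled over
all training samples regardless of class (at least 20 samples required).
Boundary semantics are strict and literal: exclude iff `p95 < 400`; exclude
iff `p95/p5 < 4`; Tier 1 iff `p95/p5 ≥ 5`.  A marker with `p5 = 0` gets
infinite dynamic range (a marker spanning zero to high copies is maximally
dynamic); whether it is usable is decided by the abundance rule.  The gDNA
screen is a wet-lab input flag, applied after tiering.  The candidate pool
orders survivors by (tier, descending dynamic range, name) so it is unique
and reproducible.

## Forward selection

Per step, every remaining candidate is scored by (i) training
cross-validation mAUROC after a seeded hyperparameter search and (ii)
validation mAUROC of the tuned model refit on the full training set.  The
chosen candidate maximizes validation mAUROC among candidates whose
training CV mAUROC is within ε = 0.01 of the step's best; exact ties break
lexicographically.  This ε-rule is a deterministic stand-in for expert
judgement over the per-step train/validation scatter; it is recorded in the
trace so the choice can be re-audited post hoc.

- Cross-validation: 5-fold by default, stratified by class; when cohort
  labels are supplied, whole cohorts stay within one fold
  (`StratifiedGroupKFold`), since generalization to unseen cohorts is the
  target quantity.  Every class must be present in every fold.
- Phase I: multinomial logistic regression (inputs standardized), random
  search over L2 strength `C ∈ [1e-2, 1e2]` (log-uniform), default budget
  20 evaluations.
- Phase II: one- or two-layer perceptron (width 8–64, learning rate and
  weight decay log-uniform), Bayesian search (below), default budget 30.
- The hyperparameter search is re-run per candidate (not once per step);
  this is configurable in cost via the budget.

### Bayesian search backend

No sequential model-based optimization library is a dependency; the package
ships a small seeded optimizer: random initialization (max(3, dims+1)
points), then a Gaussian-process surrogate (Matern ν = 2.5, fixed length
scale 0.3 on the unit cube, no kernel optimization — cheap and exactly
reproducible) proposing the expected-improvement maximizer over a seeded
256-point candidate cloud.  With budget ≤ the initialization count it
degrades to pure random search, so tests do not depend on surrogate
internals.

## Classifier and band metrics

The final classifier is an ensemble of MLPs differing only in derived
sub-seeds; the probability triplet is the renormalized mean of member
outputs.  An RBF-SVM baseline sits behind the same interface so an original
panel and a re-selected panel can be compared on identical metric code.

Training metrics are computed on out-of-fold cross-validation scores;
band thresholds are fitted on those same training scores and then frozen;
validation metrics reuse the frozen thresholds with the model refit on the
full training set.  This mirrors the train-CV / held-out-validation
structure of clinical metric tables.

Band semantics: band 1 = rule-out call, band 4 = rule-in call; "band-1
sensitivity" is the sensitivity of the *not-band-1* call and "band-4
specificity" the specificity of the *not-band-4* call — the only reading
under which the prevalence identity

    fraction_b = 100 · [π · P(band b | pos) + (1 − π) · P(band b | neg)]

reproduces published metric tables (it holds exactly on any finite dataset
and is asserted in tests).  `LR+` is reported as infinity when no negative
occupies band 4.  When band-1 sensitivity is 100%, `LR−` is exactly 0.

Threshold fitting: t1 is the largest candidate threshold (midpoints between
adjacent observed scores, plus outer sentinels) keeping band-1 sensitivity
at or above its target; t3 the smallest keeping band-4 specificity at or
above its target; t2 their midpoint.  These two extremes *cross* precisely
when the score separates classes well — maximal rule-out and rule-in
regions then overlap.  In that case both thresholds are pulled to the
midpoint of the crossed interval: by monotonicity any smaller t1 / larger
t3 still satisfies its target, so both targets remain met while the
intermediate zone lands in the empty margin between classes.  An error is
raised only in the degenerate case where no rule-out/rule-in split exists.
Default targets (98% band-1 sensitivity, 92% band-4 specificity) sit in the
range of published rule-out/rule-in operating points.

## Enrichment

Hypergeometric upper-tail p-values over an annotated-genes-only universe
(default: union of the GMT collection), Benjamini–Hochberg adjusted.  BH is
used rather than graph-aware corrections that require a live,
ancestor-structured annotation service; results are therefore exactly
reproducible from the GMT file alone.  Default significance cut-off in
reporting: FDR < 0.01.

## Experiment drivers and problem sizes

`selection_recovery_experiment` runs 20 replicates of a 50-marker study
(5 planted informative markers with |log2FC| = 1.5, 45 noise markers, 300
samples per class over 5 cohorts, last cohort held out) and 5 forward
steps under the Phase-I configuration with a small search budget (2) and
3-fold cohort-grouped CV — sizes chosen so the whole experiment runs in a
few minutes on one CPU while keeping per-class counts large enough for
stable AUCs.  `null_calibration_experiment` uses 600 samples split
half/half with moderate band targets (80% / 75%) so both extreme bands stay
well populated and likelihood-ratio estimates have low variance under the
null.

## Known limitations

- Log-normal noise only; no count-model overdispersion or dropout.
- The ε-rule formalization of the train/validation trade-off is one
  defensible reading; different ε give different panels on near-ties.
- The GP search backend is intentionally minimal (fixed kernel, no
  hyperparameter marginalization); it is a search heuristic, not a
  posterior model.
- Band thresholds are global, not per-cohort.
- Enrichment ignores annotation evidence codes and term hierarchy.
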