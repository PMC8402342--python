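# hostpanel

Tools for optimizing and evaluating **host-response diagnostic gene panels** —
compact sets of blood mRNA markers whose joint expression pattern
discriminates bacterial infection, viral infection and noninfectious
inflammation.  The package implements the full desk-side workflow used when a
locked panel must be re-selected for a new assay platform (e.g. moving from a
hybridization counter to rapid isothermal amplification, where some targets
become unmeasurable): simulate realistic multi-cohort training data, screen
candidate markers for assay feasibility, greedily rebuild the panel by
machine-learning feature selection, and score the result with the clinical
metrics used for rule-in / rule-out diagnostics.

It is written for computational biologists and diagnostics developers who
want a tested, seed-deterministic reference implementation of this workflow,
usable as a library of scikit-learn-style estimators or as a command-line
pipeline.

## What it computes

**Marker QC (two-step exclusion screen).** For each marker, the 5th / 50th /
95th percentiles of copy-number abundance are pooled across the sample bank.
A marker is excluded if `p95 < 400` copies (a 100-copy detection minimum
times the required 4-fold resolution) and then if its dynamic range
`p95 / p5 < 4`.  Survivors rank **Tier 1** (`p95/p5 ≥ 5`) or Tier 2, and
markers whose assay amplifies genomic DNA are removed.  Screened original
and alternative markers merge into an ordered candidate pool.

**Two-phase greedy forward selection.** Starting from the empty panel, each
step adds the candidate marker maximizing held-out validation mAUROC among
those whose training cross-validation mAUROC is within ε (default 0.01) of
the best — a deterministic reading of the train/validation trade-off
scatter.  Phase I (default 19 picks) uses multinomial logistic regression
with random hyperparameter search; Phase II (to the target size, default 29)
uses a multi-layer perceptron with Bayesian (Gaussian-process
expected-improvement) search.  Cross-validation is stratified by class and
grouped by cohort, so scores measure generalization across cohorts.  Here

```
mAUROC = mean of the three one-vs-rest AUROCs,
AUROC  = Mann–Whitney U / (n⁺ · n⁻)     (midranks for ties)
```

**4-band likelihood-ratio metrics.** A trained classifier emits per-sample
probability triplets `(P(bacterial), P(viral), P(noninfected))`.  Per class,
thresholds `t1 < t2 < t3` cut the score into band 1 (rule-out), bands 2–3
(intermediate) and band 4 (rule-in), and the package reports AUROC,
`LR− = P(band1|pos)/P(band1|neg)`, `LR+ = P(band4|pos)/P(band4|neg)`,
band-1 sensitivity, band-4 specificity, and the fraction of all samples in
each extreme band.  Band fractions obey the exact prevalence identity

```
fraction_b = 100 · [π · P(band b | pos) + (1 − π) · P(band b | neg)]
```

**Hypergeometric enrichment.** Panel genes are tested for
over-representation in GMT gene-set collections (`p = P(X ≥ k)` for
`X ~ Hypergeom(N, K, n)` over an annotated-genes-only universe), with
Benjamini–Hochberg FDR control.

**Synthetic cohorts.** A seed-deterministic generator produces
copy-number-scale matrices `2^(baseline + class effect + cohort batch +
noise)`, floored at a detection limit, from a table of coded per-marker
effect directions (↑↑/↑/↓/↓↓) in the bacterial-vs-control and
viral-vs-control contrasts.  The built-in 29-marker manifest carries the
direction codes of a published host-response panel.

## Worked example

```python
import hostpanel as hp
from hostpanel.simcohort import SimConfig, build_effect_table, default_panel_manifest, simulate_study

manifest = default_panel_manifest()                  # 29 markers + 3 housekeepers
effects = build_effect_table(manifest)               # coded arrows -> log2 fold changes
cfg = SimConfig(n_cohorts=6, samples_per_class_per_cohort=20, n_noise_markers=8, seed=7)
matrix, annotation = simulate_study(cfg, effects)
print("matrix:", matrix.shape, "| splits:", annotation["split"].value_counts().to_dict())

train_ids = annotation.loc[annotation.split == "train", "sample_id"]
stats = hp.compute_marker_stats(matrix.loc[train_ids])
result = hp.apply_two_step_exclusion(stats.drop(index=["HKG1", "HKG2", "HKG3"]))
print(result[["p5", "p95", "dynamic_range", "tier", "excluded_reason"]].head(6).round(1))
```

prints

```
matrix: (360, 40) | splits: {'train': 300, 'validation': 60}
             p5      p95  dynamic_range  tier excluded_reason
marker
ARG1      289.0   2933.2           10.1     1            none
BATF     2648.3  27433.9           10.4     1            none
C3AR1     390.7   4231.3           10.8     1            none
CD163    5576.5  42979.2            7.7     1            none
CEACAM1  1883.3  15992.5            8.5     1            none
CTSB     1392.5   9916.4            7.1     1            none
```

i.e. 360 samples (five training cohorts, one held-out validation cohort)
over 40 markers; the screened markers here all clear the 400-copy abundance
rule and the 4-fold dynamic-range rule, most with Tier-1 (≥ 5-fold) dynamic
range.  The prevalence identity connects published metric cells directly:
with training prevalence π = 1028/3159, `LR+ = 7.5` and band-4 specificity
95.0%,

```python
from hostpanel.classify_eval import band_fraction_from_likelihood_ratio
band_fraction_from_likelihood_ratio(1028/3159, 7.5, 0.05)   # -> 15.58 (% of samples in band 4)
```

The full pipeline (simulate → normalize → QC → select → evaluate → enrich)
runs from a YAML config:

```bash
hostpanel run-all --config config.yaml --out-dir out --seed 7
```

writing the matrix, QC verdicts, candidate pool, selection trace, panel,
metric table, per-sample score triplets and a run manifest with per-artifact
checksums (reruns with the same seed are byte-identical).

## Layout

- `hostpanel.simcohort` — effect tables and the multi-cohort generator
- `hostpanel.expression_io` — matrix/annotation IO, `HousekeeperNormalizer`
- `hostpanel.marker_qc` — percentile stats, two-step screen, `MarkerQCFilter`
- `hostpanel.panel_select` — CV mAUROC, forward steps, `ForwardPanelSelector`
- `hostpanel.classify_eval` — `MLPEnsembleClassifier`, band metrics
- `hostpanel.optim` — seeded random / GP expected-improvement search
- `hostpanel.enrich` — GMT IO and hypergeometric over-representation
- `hostpanel.experiments` — recovery and null-calibration experiment drivers
- `hostpanel.cli` — `hostpanel` command with `simulate`, `qc`, `enrich`, `run-all`

See `docs/methods.md` for the model, parameter defaults and design choices.
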