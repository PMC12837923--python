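# catpattern

Analysis toolkit for comparing human and machine categorisation behaviour in
forced-choice and free-naming object-recognition experiments — at the group
level (accuracy, agreement, Bayes factors) and at the individual level
(ordinal performance patterns).

## The problem

When a neural network "matches human accuracy" on a categorisation task, that
says little about whether it behaves like a human: two systems can reach the
same mean accuracy with entirely different per-category profiles, error
patterns and trial-by-trial decisions — and the human "average" itself hides
substantial individual variability. `catpattern` implements the statistical
toolchain for a fair comparison from long-format response tables (one row per
trial: who, which stimulus, which condition, which answer):

* **Accuracy aggregation** — per rater × session × condition × category
  correct/total counts and exact proportions, with first/second-presentation
  splits for carryover checks in repeated designs.
* **Chance-corrected agreement** — unweighted Cohen's kappa between any two
  raters, κ = (p_o − p_e)/(1 − p_e), with the Fleiss–Cohen–Everitt
  large-sample standard error, Wald confidence intervals and Landis–Koch
  qualitative bands (≤0 none, ≤0.20 slight, ≤0.40 fair, ≤0.60 moderate,
  ≤0.80 substantial, ≤1 almost perfect). Covers inter-rater matrices and
  per-participant test–retest (intra-rater) reliability.
* **JZS Bayes-factor t-tests** — paired, one-sample and two-sample, with a
  Cauchy(0, r) prior on the standardised effect size (default r = √2/2),
  computed by numerical quadrature of the Jeffreys–Zellner–Siow integral in
  log space. Evidence is graded on Jeffreys-style bands with the BF > 3 / 10
  / 100 significance-mark convention.
* **Ordinal-pattern discretisation** — each rater's per-category accuracies
  reduce to a triangular matrix of qualitative pairwise relations
  {<, >, ≃}, encoded as a string signature. The toolkit enumerates unique
  patterns across a cohort, finds the modal pattern, measures cross-session
  pattern consistency, and matches a model's pattern against the human modal
  pattern (exact match, cell overlap, frequency rank). Two equality
  criteria: a fixed band |p_i − p_j| ≤ τ (default τ = 0.1) or overlap of
  Wilson score intervals.
* **Synthetic cohorts** — a generator of counterbalanced trial schedules and
  two-session cohorts with known ground truth: latent subgroups with
  per-category accuracy profiles, configurable confusion kernels for wrong
  answers, and a test–retest stability mechanism. It stands in for
  restricted human data and gives every estimator a recoverable planted
  structure to be validated against.

## Worked example

Plant a cohort of 398 participants in which 65% share a flat ("all categories
equal") accuracy profile and the rest fall into four structured variant
subgroups, run the two-session nine-category design, and recover the planted
structure:

```python
from catpattern import (
    cohen_kappa, jzs_bf_one_sample, plant_modal_scenario, default_retest_design,
    generate_cohort, compute_accuracy, DiscretisationCriterion, modal_pattern,
)
from catpattern.patterns import discretise_accuracy_table, session_consistency

spec = plant_modal_scenario(n_participants=398, modal_weight=0.65,
                            n_variant_subgroups=4, seed=1)
design = default_retest_design(seed=1)
cohort = generate_cohort(spec, design)          # 398 x 540 trials
acc = compute_accuracy(cohort, group_by=["rater_id", "session", "true_category"])
pats = discretise_accuracy_table(acc, design.categories,
                                 DiscretisationCriterion(tolerance=0.1),
                                 group_cols=("rater_id", "session"))
test, retest = (pats[pats.session == s] for s in ("test", "retest"))
winners, prop = modal_pattern(list(test.pattern))
print("modal signature:", winners[0].signature)
print(f"modal proportion: {prop:.3f}")
```

```
modal signature: ====================================
modal proportion: 0.628
```

The modal signature is the all-equal pattern (36 `=` cells for 9 categories),
carried by 62.8% of the cohort — within sampling error of the planted 65%
weight. The same objects feed the other analyses:

```python
cons, _, _ = session_consistency(dict(zip(test.rater_id, test.pattern)),
                                 dict(zip(retest.rater_id, retest.pattern)))
print(f"cross-session consistency: {cons:.3f}")

one = cohort[(cohort.rater_id == "p001") & (cohort.session == "test")]
two = cohort[(cohort.rater_id == "p001") & (cohort.session == "retest")]
res = cohen_kappa(one.sort_values("stimulus_id").response_category,
                  two.sort_values("stimulus_id").response_category)
print(f"kappa: {res.kappa:.3f} [{res.ci_low:.3f}, {res.ci_high:.3f}] ({res.band})")

per = acc[acc.session == "test"].groupby("rater_id")[["n_correct", "n_trials"]].sum()
bf = jzs_bf_one_sample(per.n_correct / per.n_trials, mu0=0.92)
print(f"BF10 humans vs a 92%-accurate model: {bf.bf10:.3g} ({bf.grade} {bf.marks})")
```

```
cross-session consistency: 0.606
kappa: 0.625 [0.563, 0.686] (substantial)
BF10 humans vs a 92%-accurate model: 1.21e+139 (extreme_h1 ***)
```

Consistency 0.606 recovers the planted session stability of 0.6; participant
`p001`'s test–retest kappa lands in the "substantial" band; and the
one-sample JZS test yields overwhelming evidence that this near-ceiling
cohort's accuracy differs from a hypothetical model fixed at 92%.

## Command line

```bash
catpattern simulate  --seed 1 --participants 398 --out responses.csv
catpattern accuracy  --input responses.csv --out accuracy.csv
catpattern agreement --input responses.csv --out-dir agreement/
catpattern bayes     --human acc_humans.csv --model acc_models.csv --out bf.csv
catpattern patterns  --input accuracy.csv --tau 0.1 --out-dir patterns/
catpattern report    --seed 1 --out-dir report/       # full pipeline bundle
```

`report` produces accuracy tables, reliability and agreement summaries,
Bayes-factor comparisons, pattern reports and a manifest; reruns with the
same seed are byte-identical.

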