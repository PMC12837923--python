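# Methods

## Data model

The unit of observation is one trial: a rater (human participant or machine
model) sees a stimulus belonging to one of k categories under a viewing
condition (presentation duration, isolated vs. full image) and answers with
a label. Tables are long-format CSV with a fixed column order
(`rater_id, rater_kind, session, presentation, image_condition, block,
trial_index, stimulus_id, true_category, response_label, response_category`).
Free-naming answers are mapped to the category set case- and
whitespace-insensitively, first by literal match and then through a
configurable alias table; anything unmapped becomes the sentinel `UNKNOWN`,
which is carried through agreement analysis as a category of its own so that
open-vocabulary raters remain comparable to fixed-vocabulary ones. Accuracy
tables store exact count ratios (`n_correct / n_trials`); nothing is rounded
before downstream use, and empty cells are reported with `n_trials = 0`
rather than dropped.

## Synthetic cohorts

The generator emulates the *input structure* of a two-session
brief-presentation categorisation study: by default 398 participants, nine
categories × 30 images, one 50 ms presentation of each of the 270 images
per session, six blocks of 45 trials, and a retest session with the same
images in a new fixed order. The companion two-duration design (ten
categories × 60 images at 50 and 200 ms) counterbalances category–duration
bindings across the two halves of its eight blocks (1200 trials, 150 per
block), which the schedule generator reproduces exactly.

The response model is a binomial mixture. Each participant draws a latent
subgroup with probability equal to its mixture weight; the subgroup supplies
a per-category accuracy profile p ∈ [0,1]^k. On each trial the participant
answers correctly with probability p[category]; otherwise a wrong label is
drawn from that category's confusion kernel (uniform over the other
categories by default, configurable per category — including mass on
`UNKNOWN` for free-naming simulations — so that "same accuracy, different
errors" scenarios are expressible). At retest a participant keeps their test
profile with probability `session_stability`; otherwise every category's
accuracy is independently perturbed on the logit scale with SD
`profile_jitter` (logit-scale jitter keeps profiles inside [0,1] without
truncation artefacts). An optional `carryover_boost` adds a fixed accuracy
increment to the second within-session occurrence of a stimulus; it defaults
to 0 (no repetition benefit). One master seed drives everything;
per-participant substreams are derived by stable hashing of the rater id, so
cohorts are bit-reproducible and order-independent.

The default cohort (`default_cohort_spec`) mirrors a realistic human
population: a dominant broadly-even subgroup (weight 0.60) with per-category
accuracies from 0.78 (Helmet) to 0.93 (Banana), a helmet-weak subgroup
(0.20), a hard-category-weak subgroup (0.10) and a high-performing subgroup
(0.10), giving a cohort mean accuracy near 86% with Helmet weakest (~74%).

**What the generator does not model.** Responses are conditionally
independent given the profile: there are no per-image difficulty effects, no
item memory across sessions, no fatigue or attention drift, and no
perceptual mechanism (masking dynamics, feature overlap). Two consequences
matter for interpretation. First, simulated test–retest kappas are bounded
by what profile-level consistency alone can produce (a participant at
accuracy a agrees with themselves at chance-corrected rates driven by a²
plus confusion-kernel coincidences), so real cohorts — where the same hard
image tends to be missed twice — can show *higher* intra-rater agreement
than the simulation at the same accuracy. Second, passing recovery tests
shows the estimators are correct and the pipeline faithful, not that any
particular human population has the planted structure.

## Cohen's kappa

Unweighted kappa is computed from the two raters' contingency table over the
union of observed labels: κ = (p_o − p_e)/(1 − p_e), with p_o the observed
agreement rate and p_e the product-marginal chance rate. p_o and p_e are
formed from integer count sums so exact cases (perfect agreement) are exact
in floating point. The standard error is the classical
Fleiss–Cohen–Everitt large-sample estimator,

    Var(κ̂) = [ Σ_i p_ii ((1−p_e) − (p_i·+p_·i)(1−p_o))²
              + (1−p_o)² Σ_{i≠j} p_ij (p_·i+p_j·)²
              − (p_o p_e − 2p_e + p_o)² ] / ( n (1−p_e)⁴ ),

with Wald confidence intervals clipped to [−1, 1]; the estimator choice is
recorded in every result object. Degenerate marginals are resolved
explicitly: two constant identical sequences give κ = 1 (flagged), two
constant different sequences κ = 0 (flagged). Qualitative interpretation
uses the Landis–Koch bands with a 1e-9 tolerance at the boundaries so float
noise cannot flip a band. Cohort-level inter-rater agreement is summarised
two ways — the distribution (median/mean) of per-pair kappas and a pooled
kappa over the summed per-pair contingency tables — because either
convention appears in practice; pooling over unordered pairs symmetrises the
table, making the pooled value invariant to rater ordering. A vectorised
matrix path computes all-pairs point estimates for cohorts of hundreds of
raters in seconds and is verified against the scalar path.

## JZS Bayes factors

The Bayesian t-tests use the Jeffreys–Zellner–Siow default prior: Cauchy(0, r)
on the standardised effect, r = √2/2 unless overridden. BF10 is the
one-dimensional integral over the prior-variance multiplier g with
inverse-gamma(1/2, r²/2) mixing density; the integrand is formed as the
likelihood *ratio* to the null and integrated by adaptive quadrature over
log g (tolerances 1e-12 absolute / 1e-10 relative), with a grid-located mode
and log-space shifting. This keeps the computation bounded for arbitrarily
large |t| and degrees of freedom — at extreme evidence the log marginals
remain exact even when BF10 itself overflows to `inf`. Effective sample
size is n for paired/one-sample designs and n₁n₂/(n₁+n₂) with
ν = n₁+n₂−2 for two-sample ones. The implementation is validated against an
independent fine-grid Simpson quadrature under a different change of
variable, and against an external implementation.

Human-vs-model accuracy comparisons default to a one-sample test of
participant-level accuracies against the model's accuracy treated as a known
constant (a single network's response set has no sampling distribution over
participants); a two-sample variant treating model raters as a second sample
is available, and every output row records which was used. Evidence grades
use Jeffreys-style bands symmetric around BF = 1 (anecdotal / moderate /
strong / very strong / extreme, for H1 above 1 and for H0 below it; exactly
1 is inconclusive), with `*`, `**`, `***` marks at BF > 3, 10, 100.

## Ordinal discretisation

For each rater, per-category accuracies are reduced to a strictly
lower-triangular matrix of pairwise relations over the configured category
order; cell (i, j) reads "category i versus category j" and holds `<`, `>`
or `=`. The cells in row-major order form the signature string (k(k−1)/2
characters), which is bijective with the pattern given the category order;
signatures are deliberately **not** canonicalised under category
permutation — the order is part of the frame of reference, as in a published
triangular-matrix figure.

Equality is decided *before* sign: in threshold mode a pair is `=` iff
|p_i − p_j| ≤ τ (inclusive), even when the difference is nonzero. The
default τ = 0.1 equals 3 images out of 30 — a band wide enough that
qualitative rank structure, not raw sampling noise, drives the pattern, yet
narrow enough that planted subgroup separations of ≥ 0.2 are preserved.
τ = 0 degenerates to exact equality of proportions, and raising τ never
converts an `=` cell back to `<`/`>` (monotone coarsening); both properties
are enforced by tests. The alternative `ci_overlap` criterion declares a
pair equal iff the two Wilson score intervals overlap (Wilson rather than
Wald for its behaviour near proportions of 0 and 1); its band adapts to the
trial count, so it is the natural choice when per-category trial counts are
small relative to the accuracy differences of interest. On the default
~86%-accuracy cohort with 30 trials per category, the fixed τ = 0.1 band
yields almost one unique pattern per participant (binomial noise spans the
band), whereas `ci_overlap` concentrates the cohort on the all-equal
pattern; any report records the criterion used. Frequency tables rank
signatures by count with lexicographic tie-break; modal-pattern queries
return all tied winners.

## Identifiability of the planted scenarios

`plant_modal_scenario` exists to give end-to-end recovery tests a ground
truth that is actually recoverable at the study's trial counts, and its two
defaults implement explicit design requirements:

* **Flat profile near ceiling (0.99).** With 30 trials per category and
  τ = 0.1, the all-equal signature requires the *sampled* proportions of
  all 9 categories to fall within a 0.1 band. At p = 0.86 the binomial range
  noise across nine categories exceeds the band for most participants, so no
  mid-range flat profile can be recovered at its planted frequency; at
  p = 0.99 the per-category count distribution concentrates on {27..30}/30
  and a flat participant produces the all-equal signature with probability
  ≈ 0.99. Variant subgroups depress distinct category subsets by 0.45 —
  more than 2τ plus noise — so they neither collapse into the flat pattern
  nor lose their own signatures.
* **Retest jitter SD 6.** Observed cross-session consistency equals
  s·m_same + (1−s)·m_jit, where s is the planted stability, m_same the
  probability a kept profile reproduces its signature (≈ 0.99² here) and
  m_jit the probability a perturbed profile does. Recovery of s requires
  m_jit ≈ 0: the jitter SD must make at least one category's accuracy leave
  the effective equality band almost surely. At SD 6 on the logit scale the
  normal-tail bound gives P(no category drops below the effective band)⁹
  ≈ 0.03, which measurement confirms; at SD 4 the same bound leaves
  m_jit ≈ 0.13 and consistency would over-estimate low stabilities.

These are statements about the estimator and the design, not about human
populations; the study-mirroring default cohort keeps its realistic ~86%
profiles.

## Carryover analysis

`split_halves` partitions a repeated-presentation session by stimulus
occurrence: within each (rater, session, image condition, stimulus) group
the earlier trial goes to the first set. Presentation duration is
deliberately excluded from the key — in a counterbalanced two-duration
design the two occurrences of an image differ in duration, and the carryover
question is about exposure order. Stimuli seen once go to the first set
(partial data must not crash the analysis); three or more occurrences are an
integrity error. The carryover check then computes each participant's
overall accuracy separately over first and second occurrences per duration
and applies the paired JZS test. The validation simulations use 25
participants on a scaled counterbalanced design (6 categories × 20 images
× 2 durations, 240 trials per participant) with a flat 0.8 profile,
200 replicates per condition: under the null generator the Bayes factor
favours the null (BF < 1) in the large majority of replicates, and a planted
+0.15 second-occurrence boost is detected (BF > 3) essentially always.

## Pipeline and reproducibility

The `report` pipeline runs simulate → accuracy → reliability → agreement →
Bayes comparisons → patterns under one configuration, writing plain CSV/JSON
plus a manifest (seed, package version, criterion, prior scale, toggles).
Only test-session data enter human–machine comparisons; the retest session
feeds reliability and pattern-consistency analyses alone. The manifest
records no timestamps, so a rerun with the same seed reproduces every output
byte-for-byte — a property the acceptance checks assert on the full default
bundle. Stage progress and wall times go to standard error.

## Known limitations

* The agreement module implements unweighted two-rater kappa only (no
  weighted kappa, Fleiss multi-rater kappa or Krippendorff's alpha).
* Bayes factors cover t-type contrasts; multi-factor Bayesian ANOVA is out
  of scope, and per-category paired tests are reported where an omnibus
  interaction test might otherwise be used.
* The generator's conditional-independence assumption understates real
  test–retest agreement at matched accuracy (see above); per-image
  difficulty would require an item-effects extension.
* Wald intervals for kappa can be anti-conservative for very small item
  counts; per-participant reliability in the default design uses 270 items,
  where the large-sample approximation is comfortable.
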