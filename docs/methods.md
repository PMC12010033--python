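# Methods

## The risk index

`bkarisk` implements an additive point score for adults undergoing
non-traumatic below-knee amputation.  Four factor groups contribute integer
points, and the total S is their sum:

| Component | 0 points | 1 point | 2 points |
|---|---|---|---|
| Age | < 65 y | 65–79 y | ≥ 80 y |
| Preoperative systemic disease | — | 1 per condition (max 6) | — |
| Postoperative mobilization | early (≤ 24 h) | late (> 24 h) | bedridden |
| Early complication | — | 1 each for hypoxia, metabolic disorder | — |

The comorbidity set is closed: COPD, hypertension, diabetes mellitus, prior
myocardial infarction, prior stroke, prior lower-extremity infection.
S ranges over 0–12, is total on its 2,304-point input lattice, and is
monotone in every factor (worsening any one factor never lowers S) — both
properties are verified exhaustively in the test suite.  Ages are whole
years; no sub-year resolution is defined.  Functional independence uses the
Katz ADL count (0–6 of bathing, dressing, toileting, transferring, personal
care, feeding performed independently); only scores 6 (full independence),
4 (moderate) and ≤ 2 (severe impairment) carry clinical labels, so 3 and 5
are reported as "intermediate" rather than inventing labels.

## Statistical procedures

The three validation statistics are implemented from first principles; the
scipy equivalents appear only as independent cross-checks in the tests.

**Mann–Whitney U.**  U for the first group is its count of pairwise wins
(ties half), computed from midrank sums.  The exact two-sided p-value is
the permutation probability, over all C(n1+n2, n1) relabelings of the
pooled sample, of a U at least as far from n1·n2/2 as observed.  Rather
than enumerating labelings, the permutation distribution is obtained with a
subset-sum dynamic program over doubled midranks (doubling makes them
integers), which is exact with ties and costs O(n1 · n2 · Σranks) — small
enough that the pipeline uses the exact p at n = 30 routinely.  Exact
computation is refused above a pooled size of 60 (int64 subset counts stay
exact up to C(60,30)); `auto` uses the exact distribution up to a pooled
size of 14 and a tie-corrected normal approximation with a ±0.5 continuity
correction beyond.  The signed deviate z carries the sign of (mean rank of
group A − mean rank of group B); published tables sometimes print this z in
a column labeled "U", so reports show both.

**ROC/AUC.**  The empirical ROC steps through every distinct score
threshold.  The AUC is computed in pair-counting form U/(n₊·n₋) — the
probability a random positive outranks a random negative, ties half — and
the trapezoidal area of the reported curve is asserted to agree to 1e-12.
Orientation (whether high or low scores flag the event) is an explicit
parameter and the complementary AUC is always reported, because a
small-cohort score can plausibly discriminate in either direction; the
flipped orientation returns exactly 1 − AUC by construction.

**Spearman correlation.**  r is the Pearson correlation of midranks.  The
p-value is an exact permutation p for n ≤ 8 (all n! orderings) and the
usual t-approximation with n − 2 degrees of freedom above.  Descriptive
bands partition |r| with half-open intervals closed on the left —
[0, 0.10) negligible, [0.10, 0.40) weak, [0.40, 0.70) moderate,
[0.70, 0.90) strong, [0.90, 1] very strong — so every |r| maps to exactly
one band.

## Analysis pipeline conventions

* Group comparisons report n, median and 25th–75th percentiles per outcome
  level; quartiles use linear interpolation between order statistics, a
  convention that matters at n ≈ 15 and is therefore stated in the report
  footer.
* The Katz correlation excludes patients who died within the first three
  months, operationalized as `days_to_death < 90`; 3-month survivors
  without Katz data are counted separately, never imputed.
* p-values are two-sided, printed to 3 decimals with `<0.001` flooring, and
  unadjusted for multiple testing (no adjustment is part of the analysis
  plan; the report says so).
* Sections that are undefined on a given cohort (a single-level outcome,
  fewer than 3 analyzable Katz records) degrade to a "not computable" note
  instead of failing the report.

## The synthetic-cohort generator

No patient-level data accompany the study this package models, so the
simulator provides cohorts with the same structure.  The generative model
is deliberately the simplest one producing the qualitative pattern the
analysis assumes (higher score → more deaths, lower Katz); it is a
simulator convention, not a claim about the source cohort:

* age ~ Normal(μ, σ) truncated at 17.5 and rounded to whole years;
* six independent Bernoulli comorbidities;
* mobilization drawn per age band (defaults: early mobilization
  concentrated under 65, immobilization dominant over 79);
* independent Bernoulli hypoxia and metabolic disorder;
* death within one year ~ Bernoulli(expit(β₀ + β₁·S)); the day of death is
  uniform on [0, 364];
* 3-month Katz = round(κ₀ − κ₁·S + Normal(0, σ_K)) clamped to [0, 6],
  materialized as the first k activities independent; patients dead before
  day 90 were never assessed and carry no Katz data;
* three independent Bernoulli secondary outcomes.

One seeded NumPy generator drives all draws in a fixed per-record field
order, so a (config, seed) pair reproduces a cohort bit-for-bit and the
CLI pipeline is byte-deterministic.

### Default study conditions (`paper_like_config`)

n = 30 and mean age 71.7 y match the reported cohort.  The reported "±1.26"
dispersion does not state whether it is an SD or an SEM, so the age SD is a
free parameter defaulting to 10 y, a realistic spread for a dysvascular
amputation cohort.  Comorbidity prevalences (diabetes 0.50, hypertension
0.40, limb infection 0.30, COPD 0.12, MI 0.12, stroke 0.08) and
complication probabilities (0.25 each, ≈ 44% with at least one, close to
14/30) are chosen once as typical of such cohorts and to put the mean
score near the reported 3.73.  Secondary-outcome probabilities are the
reported frequencies (10/30, 11/30, 19/30; for wound complications the
outcome table's 19/30 is used over the narrative's 11/30).  β₁ = 0.45
encodes the stated direction (mortality rises with the score); β₀ is then
*solved*, not tuned: the exact PMF of S implied by the config is computed
by convolution (mixing over age bands, since mobilization depends on the
band) and β₀ is found by root-finding so the marginal death probability is
exactly 0.5, matching 15/30 deaths.  κ = (6.5, 0.8, 0.8) gives the strong
negative score–Katz correlation among 3-month survivors that the analysis
is meant to exhibit.

### What the simulator does and does not emulate

It reproduces the cohort's marginal structure and the two monotone links
the analysis probes.  It does not emulate correlations among comorbidities,
age-dependent comorbidity burden, informative censoring, secondary
outcomes that depend on the score, or the (internally ambiguous) direction
of the real cohort's score–mortality association.  Passing tests therefore
demonstrate that the pipeline recovers what a known generative model puts
in — not that the score is clinically valid.

## Verification strategy and problem sizes

* Scoring: exhaustive over all 2,304 combinations plus all 64 Katz tuples.
* Statistics: oracle equivalence against brute-force label enumeration
  (100 small tied datasets), explicit pair counting and the U-identity
  (1000 tied datasets, 1e-12), midrank-Pearson and scipy cross-checks
  (1000 tied datasets, 1e-12), plus symmetry/invariance property tests.
* Simulator: per-score death rates within 3 Monte-Carlo SEs of the
  configured logistic at n = 20,000; chance-level AUC (0.5 ± 3 SE) when
  β₁ = 0; Spearman ≤ −0.7 under a strong Katz linkage (κ₁ = 1.2,
  σ_K = 0.3) at n = 20,000.
* Pipeline: with β₁ = 0, the exact survival-comparison p over 1000
  replicate 30-patient cohorts rejects at α = 0.05 within 3 binomial SEs
  of 5% (the exact test is conservative under discreteness, which the
  band tolerates); and the simulate→analyze CLI path is byte-identical
  across runs.

These sizes (20,000-patient recovery cohorts, 1000 replicates) were chosen
as the smallest giving Monte-Carlo standard errors well below the effect
sizes being checked.

## Known limitations

* The exact Mann–Whitney p uses the distance-from-mean definition of
  "two-sided"; other tie-handling definitions (e.g. doubling the smaller
  tail) can differ on asymmetric permutation distributions.
* The Spearman t-approximation is inaccurate for n just above 8 with heavy
  ties; the exact-permutation cutoff of 8 is a cost bound (8! orderings).
* The simulator's Katz components are materialized deterministically from
  the Katz total (first k activities independent), so per-activity patterns
  carry no information beyond the total.
* Whole-year ages make the 65 and 80 band edges sharp; a patient's band is
  undefined between birthdays only to the extent the input data are.
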