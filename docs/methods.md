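# Methods

## Problem setting

Two administrative registers are linked on maternal attributes: a births
register where each record carries the mother's name, age, residence
municipality/state and (from 2011 on) her date of birth, and a
social-registry cohort baseline with one record per person (name, date
of birth, sex, family code, residence codes, socio-demographic
covariates).  There is no shared unique identifier; a fraction of births
have no counterpart in the cohort at all, so the method must both *find*
the right record when it exists and *abstain* when it does not.

## Linkage model

### Blocking

The cohort is held in an inverted index keyed by name tokens, the full
standardized name, municipality code, state code and date of birth.
Each birth probes it with up to three attributes — name, municipality,
and mother DOB when present — through a cascade of decreasing
strictness:

* **exact**: postings intersection over all supplied attributes (name
  compared as the full ordered token sequence — the strictest reading of
  attribute equality);
* **semi-fuzzy**: union of leave-one-attribute-out intersections minus
  the exact tier, i.e. candidates disagreeing on exactly one attribute;
* **fuzzy**: candidates sharing ≥ 1 name token, ranked by
  (shared-token count, normalized Damerau-Levenshtein similarity of the
  full name, id) and discarded at similarity ≤ 0.5.

The cascade concatenates tiers in order, deduplicates keeping the
highest tier, and truncates to `k = 1000`.  Only the name field is
fuzzy-matched; municipality and DOB are relaxed by omission in the
semi-fuzzy tier.  All tie-breaks are lexicographic and deterministic.

### Scoring

Per-attribute similarities: Jaro-Winkler on names (prefix scale 0.1,
max prefix 4; transpositions counted as half the number of matched
characters in different order); `1 − hamming/8` on compact `YYYYMMDD`
dates; 0/1 equality on municipality and state codes (they are
administrative codes, not strings).  The combined score is the
weight-normalized mean over *available* attributes with weights
name 1.0, DOB-or-age 1.0, municipality 0.16, state 0.008.
Renormalizing over available attributes — rather than scoring missing
comparisons as 0 — keeps scores on [0, 1] and comparable across the
pre-2011 regime (mother DOB structurally absent) and the post-2011
regime, which is what makes a single decision threshold meaningful
across eras.

When the birth record lacks a mother DOB, candidates first pass an
exact-equality gate: maternal age derived from the candidate's DOB and
the child's DOB (completed years by calendar arithmetic — year
difference minus one if the child's month/day precedes the mother's
birthday; never day-counts divided by 365.25, since an exact-match gate
is sensitive to off-by-one ages) must equal the recorded age.  Survivors
contribute similarity 1 on the age attribute.  The alternative — gating
without contributing weight — would make era-1 scores systematically
higher (fewer attributes in the denominator with the same numerator
structure) and was rejected for cross-era comparability.

The Damerau-Levenshtein distance is the restricted
(optimal-string-alignment) variant, standard in linkage tooling.  It
differs from the unrestricted distance on rare inputs (e.g.
`BCA → CABA`: 3 restricted, 2 unrestricted); the test suite's
brute-force oracle enumerates edit sequences under the same restriction.

### Assignment and threshold

All scored pairs enter a single globally greedy one-to-one assignment:
sorted by (score desc, birth id, cohort id), a pair is accepted iff
neither side is taken.  Global ordering makes the result independent of
input order; the id tie-break is arbitrary but deterministic and is
exercised by a permutation test.

The operating threshold comes from a score-stratified sample of assigned
pairs (default 2000; strata < 0.90, [0.90, 0.95] closed, > 0.95 — the
boundary inclusivity is a convention, configurable), allocated
proportionally with a floor of 10 per non-empty stratum so thin strata
are always examined.  Labels come from the truth table on synthetic data
or from a review file otherwise.  The ROC is built over all distinct
score cuts (AUC by trapezoidal integration, which equals the
Mann-Whitney tie-adjusted probability); the threshold maximizes
Youden's J with ties resolved toward the higher cut (favoring
specificity).  Links are `score ≥ threshold` (≥, not >, by convention).
A single-class labeled sample (possible on noise-free data) has no
defined ROC; the threshold then degenerates to the minimum assigned
score and is flagged.

### Offspring search

After a mother links, her child is sought among the cohort members of
her family with equal date of birth and sex.  A unique hit is returned;
same-sex twins sharing a DOB are flagged ambiguous and left unassigned.

## Synthetic register generator

The generator emulates the two registers' error structure: typographic
name errors (one of substitution / deletion / insertion / adjacent
transposition / token drop, uniformly, at a per-name rate), the pre-2011
absence of mother DOB on the birth form (births before 2011 never carry
it; later births lose it at a configurable rate), residence-code
disagreement between registers, covariate missingness as an explicit
category, and an overlap fraction fixing exactly
`round(overlap_fraction × n_births)` births with a true cohort mother.
Mothers' DOBs are placed so that maternal age at delivery is 15–42
completed years; recorded age can be perturbed ±1 year at a configurable
rate to exercise the exact-age gate's failure mode.  Children of
overlapping mothers are planted as cohort members of the mother's
family.  Names are drawn from bundled lists of ~260 given names and
~230 surnames with optional connective particles (2–4 tokens); the
lists are a synthetic stand-in, since no public reference list of valid
names exists.

Default conditions (used throughout the tests): 1,000 cohort persons,
600 births, overlap 0.6, typo rate 0.05, post-2011 DOB missingness 0.2,
municipality mismatch 0.05, covariate missingness 0.05, years
2001–2015.  Real attribute error rates are not publicly quantified;
these defaults are illustrative choices of plausible administrative
data quality, chosen once.

What the generator does *not* model — and what passing tests therefore
do not show about real data: realistic name-frequency skew (real
registers have far heavier name collisions), household co-residence
structure, duplicated cohort records, within-person attribute drift
across snapshot years, and municipality population sizes.  Synthetic
recall and accuracy numbers are upper bounds on what identical settings
would achieve on real registers.

## Study conditions for the reported quantities

Problem sizes are chosen so every check runs comfortably on a laptop:
blocking recall on 1,000 cohort / 600 overlapping births; zero-noise
recovery and the brute-force assignment equivalence on 500 / 300;
overlap recovery on 800 / 500 across five seeds; the ablation on
600 / 400.  The ablation's conditions (typo 0.15, age perturbation 0.25,
no DOB missingness, years 2011–2015) are the regime where the DOB
attribute genuinely dominates the age route: recorded age carries
errors, so the exact-age gate drops true mothers, while the directly
recorded DOB stays clean — precisely the operational argument for adding
the attribute to the birth form.  With error-free ages the gate is as
informative as the DOB and the AUC direction can tie either way.

## Numerical conventions and degenerate inputs

* Dates are ISO-8601 text; Hamming comparisons use the 8-digit compact
  form and reject width mismatches rather than truncating.
* Report percentages are rounded half-up to 2 decimals (`Decimal`
  arithmetic, matching how printed administrative tables round).
* Normalized DL similarity of two empty strings is 1; Jaro of an empty
  string against anything non-identical is 0.
* Name standardization replaces punctuation by spaces (so hyphenated
  compounds split into tokens), folds accents, and is idempotent; a name
  that standardizes to the empty string is flagged invalid, never
  silently dropped.
* Pair-level confusion accounting: a birth linked to the wrong record
  while having a true mother counts as both a false positive and a
  missed true pair; `sensitivity + missed-match rate = 1` and
  `false-match rate = 1 − PPV` hold by construction.
* With synthetic truth available, the non-linked group can be split into
  missed matches and true non-members; the headline bias report keeps
  the two-column linked/non-linked shape of operational audits.

## Known limitations

The inverted index is in-memory and single-node; the semi-fuzzy tier can
admit an entire municipality block, which is acceptable at these scales
but would need relevance ranking at national scale.  The fuzzy tier only
relaxes the name field.  Greedy one-to-one assignment is not optimal
matching (a maximum-weight matching could differ on tied conflicts).
The clerical-review stage is modeled as a decisions file; no interactive
review exists.  Threshold selection samples post-assignment potential
links, so pre-assignment candidate pairs never enter the labeled sample.
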