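# Methods

## Problem setting

The package targets case identification for systemic sclerosis (SSc) in a
de-identified structured EHR extract. The subject universe is defined by a
chart-review label file with a four-way taxonomy: *case*, *not case*,
*uncertain*, *missing documentation*. The default label policy counts
uncertain diagnoses as non-cases and drops missing-documentation subjects
from every analysis; it is pluggable (`LabelPolicy`), but all reported
metrics are computed under the default. Label resolution is applied before
any complete-case eligibility rule, so an uncertain subject with missing ANA
is first counted as a non-case and then excluded from ANA-bearing algorithms
like any other subject.

## Features

**Distinct-day code counts.** Billing-code occurrences are collapsed to
distinct calendar days per code system: a clinic visit, lab encounter and
radiology code on one day contribute one day. ICD-9 SSc is the exact code
710.1; ICD-10-CM SSc is the M34\* prefix family, *including* M34.2
(drug/chemical-induced) since the definition is stated as the whole family.
Matching is case- and dot-insensitive ("M34.1" ≡ "M341"); codes are matched
in their own system only, with no GEM crosswalking.

**ANA.** Titer strings parse by a small grammar: `1:N`, bare `N`, optional
`>=`/`≥` (lower bound) or `<`/`≤` (upper bound) prefixes. Positivity is "any
result ever with denominator ≥ 80" — the maximum-titer reading, matching
screening intent; the threshold and the any-vs-last convention are
configurable. An upper-bound result (`<1:80`) can never certify positivity.
A present-but-unparseable result (e.g. "negative") counts as *performed*: it
keeps the subject out of the missing category but cannot make them positive.
Subjects never tested are *missing* and are excluded from any algorithm with
an ANA clause (complete-case rule).

**Raynaud's keyword.** The published work confirmed keyword hits by manual
chart review; the package substitutes an explicit mechanized rule. Default
lexicon is the single stem `raynaud` (covers "Raynaud's", "Raynauds",
"Raynaud phenomenon"); a match is negated when a trigger from a fixed list
("no", "denies", "denied", "negative for", "without", "not have") ends
within 6 tokens before the match, inside the same sentence. Sentences split
on `[.?!;]` and newlines — deterministic, no ML splitter. All of stem list,
trigger list and window are configurable (`KeywordConfig`). RP is always
evaluable: empty notes yield *false*, not *missing* — the complete-case rule
applies only to ANA and ICD-10-era eligibility.

**Follow-up.** Years between first and last billing code of *any* condition
across both systems, (max − min)/365.25; zero with fewer than two distinct
dates.

## Rule algorithms

`AlgorithmSpec` is declarative (JSON-serializable): code logic
(`icd9_only` / `icd10_only` / `icd9_or_icd10`), thresholds, ANA clause, RP
clause. Two deliberately resolved ambiguities:

- **"≥ k counts of the ICD-9 or ICD-10-CM codes"** defaults to the
  *either-count* reading (either system's distinct-day count reaches k),
  because the two code systems cover alternative calendar eras; the summed
  reading is available via `count_mode="sum"` so the question stays testable.
- **"AND ANA OR RP"** parses as `count AND (ANA OR RP)` — the three
  components are listed as a single family, which only makes sense with the
  count as the outer conjunct.

Any algorithm that uses ICD-10 counts requires the subject to carry at least
one ICD-10-CM code of any condition (otherwise they predate the ICD-10 era
and the rule is unevaluable for them); any algorithm touching ANA requires
the test to have been performed. There is no ICD-10 AND RP family: the
source cohort had too few ICD-10-era subjects with note data to evaluate it,
and the grid preserves that omission.

Sensitivity-analysis utilities mirror the published procedures: stratifying
by first-SSc-code date into half-open year intervals, and excluding subjects
by a second code set (default systemic lupus erythematosus, ICD-9 710.0 /
ICD-10-CM M32\*).

## Evaluation

PPV, sensitivity and F are percents over eligible subjects only; every
excluded subject is recorded with a reason. An algorithm that flags nobody
has an *undefined* PPV (reported as missing, never 0) so F-score sweeps are
not corrupted. Reporting rounds half-up to integer percent; raw values are
always retained. Of the 32 published grid rows, 24 have a printed F equal to
the half-up-rounded harmonic mean of their own printed PPV and sensitivity;
the other 8 do not (they are consistent with F computed from unrounded raw
values and rounded independently, which cannot be reproduced from printed
inputs). The test suite checks the 24 and freezes the 8 as excluded.

Cohort comparison uses the Mann-Whitney U test for continuous variables and
the Pearson chi-square **without** continuity correction for categorical ones
(this convention reproduces the published Female p-value of 0.19 on the
86-vs-94 2×2 table; with Yates correction it would be 0.27), falling back to
Fisher's exact test when any expected cell is below 5. Two-sided throughout;
the 0.05 threshold is reported, never used to drop variables.

Training/validation splits draw the training sample first and validation from
the remainder, so for a fixed seed the training set does not depend on the
validation size.

## Machine-learning models

CART is a single `DecisionTreeClassifier`; the random forest defaults to 500
trees with 2 candidate variables per split. ANA enters one-hot with an
explicit *missing* level by default (no silent imputation; all subjects
usable); a complete-case mode mirrors the rule-based ANA exclusion. Feature
importance is Gini mean-decrease-in-impurity by default (permutation
importance behind a flag — Gini is cheaper and suffices for the qualitative
ranking checks). Tuning, when a grid is supplied, selects by cross-validated
F-score on seeded class-stratified folds. Predicted probability must exceed
0.5 to flag a subject, so a tied forest vote resolves to non-case, favoring
PPV. Note that forest *predictions* are a property of the learning problem,
not of the RNG stream: refitting with permuted feature columns at the same
seed changes individual tree draws, so the suite asserts high prediction
agreement rather than bitwise equality for that invariance.

## Synthetic cohort generator

The generator emulates a 200-subject chart-reviewed training set of
code-positive potential SSc subjects: 85 cases, 70 non-cases, 24 uncertain,
21 missing-documentation (uncertain and missing share the non-case data
profile; one published table head counts 86 cases where the text says 85 —
the generator follows the text, and `n` is configurable). Class profiles:

| parameter | cases | non-cases |
|---|---|---|
| ICD-9 distinct days (mean ± sd) | 10 ± 16 | 2 ± 5 |
| ICD-10 distinct days | 6 ± 7 | 2 ± 8 |
| age, years | 68 ± 14 | 59 ± 20 |
| follow-up, years | 7 ± 6 | 10 ± 7 |
| female fraction | 0.83 | 0.89 |
| RP present | 0.95 | 0.20 |
| ANA positive (if tested) | 0.90 | 0.55 |
| ANA never tested | 0.15 | 0.30 |
| any ICD-10 code | 0.90 | 0.90 |

The count and demographic moments are published values; RP-present 0.95 in
cases reflects the clinical fact that over 95% of SSc patients have
Raynaud's. The remaining rows (ANA prevalence and missingness, non-case RP
0.20, ICD-10-era fraction, the 0.5 negated-mention probability among
RP-absent subjects) are not published; they were fixed once at clinically
plausible values and are plain config fields.

**Count model.** The published count summaries have sd > mean, which no
normal distribution on nonnegative integers can realize. Default is
round-then-clip-at-zero normal; clipping shifts the realized mean upward by
an exactly computable bias (`truncated_round_normal_mean`, a closed-form sum
of normal CDF differences — for the case ICD-9 profile the clipped mean is
12.59 against the configured 10). Moment-recovery checks subtract this bias.
A moment-matched negative binomial (`count_model="negative_binomial"`) is the
transparent overdispersed alternative. The record span widens when a drawn
count exceeds the drawn follow-up window (a record must be at least as long
as its distinct code days), so counts are never silently capped.

Event days are drawn uniformly without replacement inside the subject's
window; anchor codes at the window edges make follow-up well defined;
same-day duplicate codes are injected with probability 0.2 per code day to
exercise distinct-day collapsing. Note text is template-based — a small bank
of present / negated / filler sentences — sufficient for keyword and negation
logic, with no pretense of real clinical language. A fixed nine-subject
edge-case panel (`inject_edge_cases`) covers same-day triple coding, ANA
never tested, negated and present mentions, ICD-10-era-only records,
single-event follow-up, unparseable and upper-bound titers.

**What passing tests do and do not show.** The simulator reproduces the
class-conditional marginals and file formats, not real EHR phenomena:
no correlation between features within a subject beyond class membership, no
care-pattern seasonality, no coding-era boundary (SSc ICD-10 codes may appear
at any date), no real note language. Pipeline correctness and metric
bookkeeping transfer to real data; absolute PPV/sensitivity values on
simulated cohorts do not.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale sizes chosen to keep the suite fast
while leaving Monte-Carlo error well inside the asserted bands: 200-subject
cohorts for pipeline and monotonicity checks (100 seeds for the nesting
sweep), 10,000 cases for moment recovery (3-standard-error acceptance), 10
seeded runs for the forest-importance ranking check. Percent rounding is
half-up everywhere. Dates parse strictly as ISO 8601 by default with an
opt-in MM/DD/YYYY fallback. Seeds: every stochastic stage takes an explicit
integer seed and the CLI writes it to the run manifest.

## Known limitations

- Keyword negation is a fixed-window trigger rule; scoped negation
  ("no evidence of X or Y"), history/family-history sections, and hypothetical
  mentions are out of scope, as is any concept normalization.
- The ANA parser handles ratio titers only; ELISA units or pattern-only
  results are treated as performed-but-unparseable.
- The published cohort's raw data are access-controlled, so published PPVs
  and sensitivities are reproduced only where they are arithmetic functions
  of other published numbers; on synthetic cohorts only qualitative orderings
  are asserted.
- `exclude_by_code` drops whole subjects (the published sensitivity analysis),
  not individual codes.
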