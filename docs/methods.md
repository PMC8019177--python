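# Methods

This note documents the models, conventions and numerical choices
behind `dqframe`, and what the synthetic-study tests do and do not
demonstrate about real data.

## Indicator model

Every check reports a uniform `IndicatorResult`: an indicator ID from
the 34-entry registry, a variable (or `study-level`), the count of
issues `N`, the denominator of assessed elements, the percentage
`100·N/denominator` (undefined when the denominator is zero), the
`(record_id, var_name)` coordinates of flagged cells, and a grading
in `{ok, issue, not-applicable}`. Output that carries no
machine-readable decision — histograms, ECDFs, smoothed residual
series, participation patterns — travels in the `descriptor` field
and is meant for human inspection; aggregation pipelines can ignore
it wholesale. Seven registry entries (standardized-vocabulary and
precision checks, the three association indicators, intra-class
reliability and gold-standard agreement) are registered but not
implemented; they grade `not-applicable` by construction and keep the
registry a complete map of the framework rather than of the code.

Grading is deliberately binary: `issue` iff `N > 0` for deterministic
checks, and iff the statistical decision rule fires for accuracy
checks. Thresholded traffic-light summaries are a reporting-layer
concern and depend on each study's quality targets, so the engine
does not hard-code them.

Record coordinates are always `(record_id, var_name)`, never
positional indices, so results survive row reordering of the study
table.

## Metadata conventions

Metadata is a flat item-level table: one row per variable, columns
`VAR_NAMES, LABEL, DATA_TYPE, HARD_LIMITS, SOFT_LIMITS,
DETECTION_LIMITS, VALUE_LABELS, MISSING_LIST, JUMP_LIST,
STUDY_SEGMENT, KEY_OBSERVER, KEY_DATETIME` plus optional `ROLE,
SOURCE_TABLE, DISTRIBUTION, DECIMALS`. Code maps use `code = label`
pairs separated by `|`; codes are integers (by convention ≥ 99900 for
qualified missing codes, but any integer is accepted) so that codes
can be distinguished from measurements mechanically. Interval
literals use `;` as the separator (`[60;300]`, `(0;Inf)`,
`[1997-01-01;2002-12-31]`) to avoid any ambiguity with decimal
commas; bracket characters encode endpoint closedness exactly, and
limit checks respect it exactly (for `[0;200)`, the value 200 is
flagged, 0 is not).

Validation enforces: unique variable names; soft limits contained in
hard limits; code maps disjoint from admissible categories. A
variable's role is either declared (`ROLE`) or inferred: variables
referenced by any `KEY_OBSERVER` / `KEY_DATETIME` entry become
process variables, everything else defaults to `measurement`.

## Integrity

All checks operate on the raw textual cell values, because type
probing on already-coerced columns would hide exactly the problems
integrity is supposed to find. Type probing is ordered and
conservative — integer → float → datetime → string — and a column is
"observed integer" only if every non-missing, non-coded value
converts losslessly (`"1.5"` is not an integer; `"2001-02-30"` is not
a date). Datetime parsing accepts ISO-8601 only by default; silent
locale guessing is itself a data-quality hazard. A variable's column
verdict is a mismatch when the unconvertible fraction exceeds a
configurable threshold whose default is 0: any unconvertible cell.

Integrity operations never raise on malformed study data — deficient
data is their subject matter, so they report it. A variable that
fails the type check has all its downstream (typed) checks marked
`type-mismatch` in the applicability matrix, and the orchestrator
skips them: a limit check on an unparseable column would produce
noise, not information.

## Completeness

Missing data is staged. Reasons for a unit never entering the study
differ from reasons for skipping one examination segment, which
differ again from single unanswered items, and each stage should be
counted only where the earlier stages have not already explained the
absence. Concretely: unit-missing units (every measurement variable
missing, system or coded; identifier and process variables do not
count as data) are excluded from all item denominators, and for each
variable the units missing its whole segment are excluded too. The
per-variable decomposition
`observed + system-missing + Σ per-code + Σ per-jump = expected`
is asserted as an invariant on every input.

Jump codes mark values legitimately skipped by questionnaire routing
(e.g. contraceptive intake is not asked of men). They appear in the
breakdown and in the qualified tabulations, but they are not counted
as crude missing-value defects and do not trigger an `issue` grading:
a correctly routed skip is evidence the instrument worked.

Qualified unit-level rates need a roster of eligible units
(one-column CSV). Non-response counts rostered units for which no
information could be obtained; a unit of all-refusals *did* respond —
the refusal itself is information — so it counts toward the refusal
rate instead (refusal codes are recognised by their label containing
"refus", configurable). Drop-out requires a declared segment order
and means a non-empty, non-full *prefix* of completed segments;
intermittent missingness (skip B, complete C) is never drop-out. The
refusal denominator is the roster; whether contacted-only units would
be the better denominator depends on the study's field protocol and
is left configurable.

## Consistency

Hard limits mark inadmissible values, soft limits improbable ones
(counted only inside the hard range, so the two sets are disjoint),
and detection limits mark device censoring — reported separately and
not graded as inadmissibility, since censoring is a property of the
instrument, not an error in the value. Counts are split above/below
the range. Qualified codes are stripped before any limit or category
comparison; a refusal code is not a range violation.

The contradiction catalog contains exactly 16 two-variable predicate
templates: each side of a rule tests one of {membership in a category
set, membership in a numeric interval, membership in a datetime
interval, being qualified-missing}, giving 4×4 combinations. A rule
fires for a unit when both sides hold. Value-membership sides are
false wherever the cell is system- or qualified-missing, so missing
data never produces spurious contradictions; the `miss` side exists
precisely to make missingness logic expressible. The catalog spans
categorical, numeric, temporal and missingness logic; rules with more
than two variables are out of scope. Counting is per unit per rule —
a unit can contribute to several rules. This 4×4 reading of the
catalog is a design decision of this package.

## Accuracy

**Univariate outliers.** Four rules, combinable by a consensus
threshold (default: one rule suffices):

- Tukey: outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`;
- six sigma: outside `mean ± 3·SD` (sample SD, total width six
  sigma);
- Hubert: skewness-adjusted fences
  `[Q1 − 1.5·e^(−4·MC)·IQR, Q3 + 1.5·e^(3·MC)·IQR]` for medcouple
  MC ≥ 0, exponents mirrored for MC < 0, with the medcouple computed
  by the exact O(n²) kernel (statsmodels implementation,
  cross-checked in the tests against a literal kernel evaluation);
- MAD rule: outside `median ± 3·1.4826·MAD`.

Quantiles use linear interpolation (type 7) everywhere so that fences
are bit-reproducible across implementations. Codes and hard-limit
violations are removed before outlier screening (an inadmissible
value is a consistency finding, not an outlier), and fewer than 10
values make the check not-applicable. On exactly symmetric samples
the Hubert fences coincide with Tukey's (MC = 0 ⇒ e⁰ = 1).

**Multivariate outliers.** Mahalanobis distances of complete cases
from the sample mean (sample covariance, ddof 1), screened with the
univariate rules in the high direction only. Distances are affine
invariant, which the tests assert. A singular covariance matrix is an
error that names the most collinear variable pair.

**Shape tests.** The declared family (normal, gamma, uniform) is fit
by the method of moments unless parameters are fixed in metadata;
observed counts on 10 equal-probability bins of the fitted
distribution are compared with expected counts by Pearson χ² with
`df = bins − 1 − #estimated parameters`. Equal-probability bins keep
expected counts equal and the χ² approximation stable. The rootogram
residuals `√observed − √expected` per bin are exported as a
descriptor. End-digit preference extracts the final integer digit
after rounding to the metadata-declared precision (default 0
decimals) and tests against uniformity with χ² on df 9.

**Examiner effects (margins).** The model `response ~ covariates +
class` is fit with the family chosen by response type (continuous →
linear, binary → logistic, small-count → Poisson), and the adjusted
marginal mean of each class is evaluated at the covariate means. A
class is flagged when its 95% CI excludes the overall adjusted mean,
defined as the class-size-weighted average of the per-class adjusted
means. With no covariates the adjusted means reduce to raw class
means (linear case). Classes below the minimum size (default 10) are
dropped; a non-converging fit grades not-applicable with a
diagnostic instead of failing the run. Adjusting at covariate means
rather than at reference levels, and CI-versus-overall-mean rather
than pairwise contrasts, are design decisions; contrast-based
flagging would be a natural extension.

**Variance components.** A random-intercept model (REML) decomposes
the response variance; ICC = σ²ᵦ/(σ²ᵦ + σ²_w), clipped to [0, 1],
flagged above a threshold defaulting to 0.05 — at that level one
twentieth of the measurement variance is attributable to who measured
rather than what was measured, which in an examination survey
warrants review.

**Time trends.** Covariate-adjusted residuals are smoothed over time
per class with a locally *linear* LOESS (span 0.75) evaluated on a
100-point grid. A locally quadratic smoother would track curvature
slightly better; the linear one is used as the package's smoothing
choice and is adequate for drift screening. The output is a pure
descriptor.

Calibration of the statistical detectors is verified by seeded
simulation: the margins screen keeps its per-class false-flag rate
under 7.5% at nominal 5% over 200 null data sets (5 examiners × 100,
age-adjusted) and flags a +1 SD shifted examiner in ≥ 95% of
replicates; ICC recovery is checked at 20 classes × 50 observations
against realised components pinned to σ²ᵦ = 1, σ²_w = 4 (ICC 0.2);
the end-digit test's null rejection rate stays inside the 99%
binomial interval around 0.05. These sizes keep the whole simulation
suite comfortably fast while leaving the binomial checks sharp
enough to catch calibration errors of a few percentage points.

## Synthetic studies and the defect ledger

The generator emulates the *structure* of a population-based
examination survey: 2154 units; somatometry (height, weight, waist
circumference), blood pressure (systolic/diastolic, linked to 5
examiners and an examination date) and an interview (smoking, marital
status, contraceptive intake with routing by sex and age); ISO-8601
dates; integer category codes with labels; qualified missing codes
99980/99981 and jump code 99983. Clean measurements are truncated
normals inside the soft limits, so a zero-defect draw yields zero
deterministic flags and the fixture can serve as a negative control.

`inject_issues` then plants defects at specified rates — type
mismatches, system- and coded-missing cells, hard and soft limit
violations (drawn strictly inside the violating region, so detection
is guaranteed, not probabilistic), inadmissible categories,
contradiction combinations, 6σ outliers, examiner shifts, end-digit
rounding and linear drift — and logs every touched cell in a defect
ledger with its true value. Two invariants make the ledger a valid
acceptance surface: every entry is detectable by the targeted
deterministic check, and cells not in the ledger match the clean draw
byte-for-byte. Seeding is counter-based per variable and defect
stream, so adding a stream never reshuffles the others and regression
tests stay stable.

What passing against this generator does **not** show: agreement with
any real survey's marginal distributions or missingness mechanisms
(no attempt is made to match them), robustness to file-encoding chaos
beyond what the raw-string pipeline handles, or the behaviour of the
statistical detectors under confounding structures more adversarial
than the simulated ones (e.g. examiner assignment correlated with
covariates).

## Determinism

Identical inputs, configuration and seed produce byte-identical JSON
exports; timestamps are injected externally (default epoch) rather
than read from the clock. All stochastic tests use fixed, documented
seeds.

## Known limitations

- No imputation and no missing-at-random diagnostics; thresholds for
  acceptable missingness belong to the analysis plan, not the engine.
- Record matching across tables is exact on the identifier; no fuzzy
  linkage.
- Contradiction rules are binary (two variables) by design.
- The margins screen's multiple-comparison behaviour is controlled
  only implicitly (per-class CIs against the overall mean); studies
  with many examiners may prefer a joint test first.
- Standardized-vocabulary checks, precision checks, association
  strength/direction/form and repeated-measurement agreement are
  registered in the indicator registry but not implemented.
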