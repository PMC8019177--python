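# dqframe

Metadata-driven data quality assessment for tabular data from
observational health studies (cohorts, surveys, designed research
collections).

## The problem

Before any substantive analysis of study data — and continuously while
a study is being conducted — data managers and biostatisticians need
to answer four questions:

1. **Integrity** — does the data conform to its structural and
   technical requirements (expected variables, expected types,
   no duplicates, homogeneous value formats)?
2. **Completeness** — are the expected data values present, and *why*
   are the absent ones absent (unit non-response, segment
   non-participation, item refusal, questionnaire routing)?
3. **Consistency** — are single values admissible (hard limits,
   category sets), plausible (soft limits), and free of contradictory
   combinations across variables?
4. **Accuracy** — do distributions and associations behave as
   expected, or do outliers, end-digit preference, examiner/device
   effects and time drift point at measurement problems?

`dqframe` implements a registry of 34 data quality indicators
(`DQI-1001` … `DQI-4012`) across these four dimensions and computes
them from two inputs: the study table(s) and an **item-level metadata
table** that declares, per variable, the expected data type, hard /
soft / detection limits (interval literals such as `[60;300]`),
admissible categories, qualified missing and jump codes, segment
membership and process-variable links (examiner, examination date).
Checks run only where the metadata makes them applicable; the
applicability matrix is itself the first diagnostic.

## Statistical core

- **Missingness** is staged: unit → segment → item. Item-level
  denominators exclude units already explained at the unit or segment
  stage, and every variable's decomposition satisfies the conservation
  identity `observed + system-missing + Σ coded + Σ jump = expected`.
- **Contradictions** use a catalog of 16 two-variable predicate
  templates (each side tests membership in a category set, a numeric
  interval, a datetime interval, or the qualified-missing state).
- **Univariate outliers** combine four rules: Tukey fences
  `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`, six sigma `x̄ ± 3s`, Hubert's
  skewness-adjusted fences `[Q1 − 1.5e^{−4MC}·IQR, Q3 + 1.5e^{3MC}·IQR]`
  (medcouple MC ≥ 0; exponents mirrored for MC < 0) and a robust MAD
  rule `median ± 3·1.4826·MAD`. Multivariate outliers apply the same
  rules to Mahalanobis distances.
- **Examiner/device effects**: covariate-adjusted marginal means per
  class (linear / logistic / Poisson by response type; a class is
  flagged when its 95% CI excludes the overall adjusted mean) and a
  random-intercept variance decomposition with
  ICC = σ²ᵦ / (σ²ᵦ + σ²\_w).
- **Distributional shape**: Pearson χ² against a declared family
  (normal / gamma / uniform) on equal-probability bins with hanging
  rootogram residuals; end-digit preference via χ² goodness-of-fit
  against uniform digits (df = 9).

A built-in synthetic-study generator emulates a population-survey
structure (somatometry, blood pressure, interview; 2154 units,
5 examiners) and injects defects with a ground-truth **defect
ledger**, so every indicator is testable without access to real data.

## Worked example

```python
from dqframe import dq_report, RunConfig
from dqframe.fixtures import generate_study

study, metadata, rules, ledger = generate_study(seed=1)
report = dq_report(study, metadata, rules, RunConfig(), seed=1)
print(f"{len(ledger)} defects injected into n={len(study)} units")
for r in report.results:
    if r.n_flagged and r.indicator_id in ("DQI-1006", "DQI-3001",
                                          "DQI-3006", "DQI-3003",
                                          "DQI-3008", "DQI-3009"):
        print(f"{r.indicator_id}  {r.variable:<12} {r.n_flagged:>4}"
              f" / {r.denominator:<5} {r.percent:.1f}%")
```

prints

```
384 defects injected into n=2154 units
DQI-1006  study-level     1 / 13    7.7%
DQI-3001  sbp            12 / 2068  0.6%
DQI-3006  sbp            21 / 2068  1.0%
DQI-3001  dbp            10 / 2115  0.5%
DQI-3006  dbp            29 / 2115  1.4%
DQI-3003  smoking        20 / 2116  0.9%
DQI-3008  study-level     7 / 2154  0.3%
DQI-3009  study-level     5 / 2154  0.2%
```

One variable (`waist`) fails the data type check (DQI-1006) because
unconvertible strings were planted in it, so downstream numeric checks
for it are skipped; the systolic blood pressure column has 12
inadmissible values outside the hard limits `[60;300]` (DQI-3001) and
21 improbable values outside the soft limits (DQI-3006); 7 units show
the logically impossible combination "male with contraceptive intake"
(DQI-3008). Each count equals the generator's ledger exactly.

The same workflow is available from a shell:

```sh
dqframe simulate --seed 1 --out sim/
dqframe report --study sim/study.csv --metadata sim/metadata.csv \
               --rules sim/rules.csv --out report/
dqframe check limit_deviations --study sim/study.csv \
               --metadata sim/metadata.csv --variable sbp
```

`dqframe report` writes `report.html`, machine-readable
`report.json`, CSV tables, plot images and a flag-annotated copy of
the study data (one `<var>_dq_flags` column per flagged variable).

## Documentation

`docs/methods.md` describes the model assumptions, the parameter
defaults and their rationale, what the synthetic generator does and
does not emulate, and known limitations.
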